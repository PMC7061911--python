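"""Protein Block assignment, Neq/ΔPB statistics, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhhkit import alphabet, structure_io, synthetic


def brute_force_assign(window):
    """Independent nearest-prototype oracle: explicit loops, no vectorising."""
    best_label, best_score = None, None
    for label in alphabet.PB_LABELS:
        proto = alphabet.PB_REFERENCE_ANGLES[label]
        total = 0.0
        for k in range(8):
            d = window[k] - proto[k]
            while d > 180.0:
                d -= 360.0
            while d <= -180.0:
                d += 360.0
            total += d * d
        score = (total / 8.0) ** 0.5
        if best_score is None or score < best_score:
            best_label, best_score = label, score
    return best_label


def uniform16():
    return np.full(16, 1.0 / 16.0)


def onehot(letter):
    f = np.zeros(16)
    f[alphabet.PB_LABELS.index(letter)] = 1.0
    return f


class TestNeq:
    def test_single_block_gives_one(self):
        assert alphabet.neq(onehot("d")) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_gives_sixteen(self):
        assert alphabet.neq(uniform16()) == pytest.approx(16.0, abs=1e-12)

    def test_two_state_gives_two(self):
        f = (onehot("d") + onehot("m")) / 2
        assert alphabet.neq(f) == pytest.approx(2.0, abs=1e-12)

    def test_unnormalised_vector_rejected(self):
        with pytest.raises(ValueError):
            alphabet.neq(np.full(16, 0.05))

    @given(st.permutations(list(range(16))))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(16))
        assert alphabet.neq(f[np.array(perm)]) == pytest.approx(
            alphabet.neq(f))

    def test_mixing_never_drops_below_minimum(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            f1 = rng.dirichlet(np.ones(16))
            f2 = rng.dirichlet(np.ones(16))
            lam = rng.random()
            mixed = alphabet.neq(lam * f1 + (1 - lam) * f2)
            assert mixed >= min(alphabet.neq(f1), alphabet.neq(f2)) - 1e-9


class TestDeltaPB:
    def test_identical_distributions_give_zero(self):
        assert alphabet.delta_pb(onehot("d"), onehot("d")) == pytest.approx(
            0.0, abs=1e-12)

    def test_disjoint_supports_give_two(self):
        assert alphabet.delta_pb(onehot("d"), onehot("m")) == pytest.approx(
            2.0, abs=1e-12)

    def test_half_overlap_gives_one(self):
        f2 = (onehot("d") + onehot("m")) / 2
        assert alphabet.delta_pb(onehot("d"), f2) == pytest.approx(1.0)

    def test_l1_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            f1, f2, f3 = (rng.dirichlet(np.ones(16)) for _ in range(3))
            d12 = alphabet.delta_pb(f1, f2)
            assert d12 == pytest.approx(alphabet.delta_pb(f2, f1))
            assert 0.0 <= d12 <= 2.0
            assert d12 <= (alphabet.delta_pb(f1, f3)
                           + alphabet.delta_pb(f3, f2) + 1e-12)

    def test_delta_neq(self):
        assert alphabet.delta_neq(1, 1) == 0
        assert alphabet.delta_neq(16, 1) == 15
        assert alphabet.delta_neq(2, 3.5) == pytest.approx(1.5)


class TestReferenceTable:
    def test_sixteen_labels_with_eight_angles_each(self):
        assert len(alphabet.PB_LABELS) == 16
        for label in alphabet.PB_LABELS:
            angles = alphabet.PB_REFERENCE_ANGLES[label]
            assert len(angles) == 8
            assert all(-180.0 < a <= 180.0 for a in angles)

    def test_checksum_pins_table(self):
        assert alphabet.table_checksum() == alphabet.PB_TABLE_SHA256


class TestAssignment:
    def test_prototype_d_self_assigns(self):
        chain = synthetic.build_backbone_from_pb_string("d" * 20)
        pbs = alphabet.assign_pbs(structure_io.compute_dihedrals(chain))
        assert pbs == "ZZ" + "d" * 16 + "ZZ"

    def test_ideal_helix_assigns_m(self):
        chain = synthetic._build_chain_from_torsions(
            np.full(20, -57.0), np.full(20, -47.0))
        pbs = alphabet.assign_pbs(structure_io.compute_dihedrals(chain))
        assert pbs == "ZZ" + "m" * 16 + "ZZ"

    def test_noisy_strand_mostly_recovers_d(self):
        cfg = synthetic.GeneratorConfig(seed=11, noise_sigma_deg=5.0)
        chain = synthetic.build_backbone_from_pb_string("d" * 40, cfg)
        dih = structure_io.compute_dihedrals(chain)
        pbs = alphabet.assign_pbs(dih)
        inner = pbs[2:-2]
        assert sum(c == "d" for c in inner) / len(inner) >= 0.95
        # and agrees with the brute-force oracle window by window
        win = alphabet._windows(dih)
        for i, c in enumerate(pbs):
            if c != "Z":
                assert c == brute_force_assign(win[i])

    def test_matches_brute_force_oracle_on_random_windows(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            w = rng.uniform(-180.0, 180.0, 8)
            dist = alphabet._rmsda(w)
            fast = alphabet.PB_LABELS[int(np.argmin(dist))]
            assert fast == brute_force_assign(w)

    def test_short_chain_warns_and_returns_all_z(self):
        chain = synthetic.build_backbone_from_pb_string("d" * 8)
        stub = structure_io.BackboneChain(chain_id="A",
                                          residues=chain.residues[:4])
        with pytest.warns(UserWarning):
            assert alphabet.assign_pbs(
                structure_io.compute_dihedrals(stub)) == "ZZZZ"


class TestFrequencies:
    def test_identical_sequences_concentrate_mass(self):
        freq = alphabet.pb_frequencies(["ZZdddZZ"] * 10)
        assert freq.support[3] == 10
        assert freq.freq[3, alphabet.PB_LABELS.index("d")] == 1.0

    def test_two_state_position_splits_mass(self):
        freq = alphabet.pb_frequencies(["ZZdddZZ", "ZZdmdZZ"])
        i = alphabet.PB_LABELS.index
        assert freq.freq[3, i("d")] == pytest.approx(0.5)
        assert freq.freq[3, i("m")] == pytest.approx(0.5)

    def test_all_z_position_has_no_support(self):
        freq = alphabet.pb_frequencies(["ZZdddZZ"] * 3)
        assert freq.support[0] == 0
        assert np.all(freq.freq[0] == 0.0)

    def test_unequal_lengths_require_column_map(self):
        with pytest.raises(ValueError):
            alphabet.pb_frequencies(["ZZdddZZ", "ZZddZZ"])


class TestProfileComparison:
    def test_identical_sets_give_zero(self):
        seqs = ["ZZddmmddZZ"] * 5
        comp = alphabet.profile_comparison(seqs, list(seqs))
        defined = ~np.isnan(comp.delta_pb)
        assert np.allclose(comp.delta_pb[defined], 0.0)
        assert np.allclose(comp.delta_neq[defined], 0.0)

    def test_disjoint_sets_give_two(self):
        comp = alphabet.profile_comparison(["ZZddddZZ"] * 3,
                                           ["ZZmmmmZZ"] * 3)
        defined = ~np.isnan(comp.delta_pb)
        assert np.allclose(comp.delta_pb[defined], 2.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            alphabet.profile_comparison([], ["ZZddZZ"])

    def test_matches_manual_composition(self):
        rng = np.random.default_rng(4)
        letters = alphabet.PB_LABELS
        make = lambda: "".join(
            letters[rng.integers(16)] for _ in range(12))
        set_a = [make() for _ in range(6)]
        set_b = [make() for _ in range(4)]
        comp = alphabet.profile_comparison(set_a, set_b)
        fa = alphabet.pb_frequencies(set_a)
        fb = alphabet.pb_frequencies(set_b)
        for i in range(12):
            expected_dpb = alphabet.delta_pb(fa.freq[i], fb.freq[i])
            expected_dneq = alphabet.delta_neq(alphabet.neq(fa.freq[i]),
                                               alphabet.neq(fb.freq[i]))
            assert comp.delta_pb[i] == pytest.approx(expected_dpb)
            assert comp.delta_neq[i] == pytest.approx(expected_dneq)


class TestRoundTrip:
    @pytest.mark.parametrize("letter", ["d", "m"])
    def test_repetitive_homopolymer_exact(self, letter):
        s = letter * 15
        chain = synthetic.build_backbone_from_pb_string(s)
        pbs = alphabet.assign_pbs(structure_io.compute_dihedrals(chain))
        assert pbs[2:-2] == s[2:-2]

    def test_cdr1_signature_word_recovers(self):
        s = "ddddehiafklpccdddddd"
        chain = synthetic.build_backbone_from_pb_string(s)
        pbs = alphabet.assign_pbs(structure_io.compute_dihedrals(chain))
        inner = range(2, len(s) - 2)
        recovery = sum(pbs[i] == s[i] for i in inner) / len(list(inner))
        assert recovery >= 0.9

    def test_transition_walks_recover(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = synthetic.random_pb_string(30, rng, kind="transitions")
            chain = synthetic.build_backbone_from_pb_string(s)
            pbs = alphabet.assign_pbs(structure_io.compute_dihedrals(chain))
            recovery = sum(pbs[i] == s[i] for i in range(2, 28)) / 26
            assert recovery >= 0.9

    def test_pb_fasta_round_trip(self):
        records = [("a1", "ZZddddZZ"), ("a2", "ZZmmmmZZ")]
        assert alphabet.read_pb_fasta(alphabet.pb_fasta(records)) == records
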