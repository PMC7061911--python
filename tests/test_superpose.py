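"""Superposition optimality, per-region/per-residue deviations, GDT-TS."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vhhkit import regions, structure_io, superpose, synthetic

from conftest import apply_rigid, random_rigid_transform


def grid_rotations(n_per_axis=14):
    """Deterministic rotation grid for the brute-force oracle."""
    angles = np.linspace(-180, 180, n_per_axis, endpoint=False)
    mats = []
    for a in angles:
        for b in np.linspace(-90, 90, n_per_axis // 2):
            for c in angles:
                mats.append(Rotation.from_euler(
                    "zyz", [a, b, c], degrees=True).as_matrix())
    return np.array(mats)


def oracle_rmsd(A, B, rotations):
    """Best RMSD over a rotation grid after centring (brute force)."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    rotated = np.einsum("rij,nj->rni", rotations, B0)
    d = rotated - A0[None]
    return float(np.sqrt((d ** 2).sum(axis=2).mean(axis=1)).min())


def random_chain(rng, n=20):
    s = synthetic.random_pb_string(n, rng)
    cfg = synthetic.GeneratorConfig(seed=int(rng.integers(2 ** 31)),
                                    noise_sigma_deg=10.0)
    return synthetic.build_backbone_from_pb_string(s, cfg)


class TestSuperpose:
    def test_rigid_copy_has_zero_rmsd(self, strand_chain, rng):
        R, t = random_rigid_transform(rng)
        moved = apply_rigid(strand_chain, R, t)
        res = superpose.superpose(strand_chain, moved)
        assert res.rmsd_global <= 1e-6
        assert res.gdt_ts == 100.0
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_kabsch_beats_rotation_grid_oracle(self, rng):
        rotations = grid_rotations(10)
        for _ in range(5):
            a = random_chain(rng)
            b = random_chain(rng)
            res = superpose.superpose(a, b)
            grid = oracle_rmsd(a.coords("CA"), b.coords("CA"), rotations)
            assert res.rmsd_global <= grid + 0.01

    def test_kabsch_not_above_random_rotations(self, rng):
        a = random_chain(rng)
        b = random_chain(rng)
        res = superpose.superpose(a, b)
        A0 = a.coords("CA") - a.coords("CA").mean(axis=0)
        B0 = b.coords("CA") - b.coords("CA").mean(axis=0)
        for _ in range(200):
            R, _ = random_rigid_transform(rng)
            rmsd_r = np.sqrt(((B0 @ R.T - A0) ** 2).sum(axis=1).mean())
            assert res.rmsd_global <= rmsd_r + 1e-9

    def test_rmsd_invariant_under_rigid_motion_of_either_input(
            self, rng):
        a = random_chain(rng)
        b = random_chain(rng)
        base = superpose.superpose(a, b).rmsd_global
        for _ in range(3):
            R, t = random_rigid_transform(rng)
            assert superpose.superpose(
                apply_rigid(a, R, t), b).rmsd_global == pytest.approx(
                    base, abs=1e-9)
            assert superpose.superpose(
                a, apply_rigid(b, R, t)).rmsd_global == pytest.approx(
                    base, abs=1e-9)

    def test_too_few_pairs_rejected(self, strand_chain):
        with pytest.raises(ValueError):
            superpose.superpose(
                strand_chain, strand_chain,
                superpose.AtomMapping(((0, 0), (1, 1))))

    def test_non_monotone_mapping_rejected(self):
        with pytest.raises(ValueError):
            superpose.AtomMapping(((0, 1), (1, 1), (2, 2)))


def _imgt_numbered_chain(pb_string="d" * 118, seed=0):
    """Backbone whose residue numbers follow the family layout."""
    labels = []
    for _name, start, count in synthetic.DEFAULT_REGION_LAYOUT:
        labels.extend(range(start, start + count))
    cfg = synthetic.GeneratorConfig(seed=seed, noise_sigma_deg=3.0)
    chain = synthetic.build_backbone_from_pb_string(pb_string, cfg)
    renum = [structure_io.Residue(
        number=lab, icode="", name=r.name, n=r.n, ca=r.ca, c=r.c)
        for lab, r in zip(labels, chain.residues)]
    return structure_io.BackboneChain(chain_id="A", residues=renum)


class TestRegionRMSD:
    def test_identical_chains_zero_everywhere(self):
        chain = _imgt_numbered_chain()
        res = superpose.superpose(chain, chain,
                                  regions_a=regions.RegionMap.imgt())
        for entry in res.rmsd_per_region.values():
            if entry["global_fit"] is not None:
                assert entry["global_fit"] <= 1e-9

    def test_displaced_cdr3_shows_up_in_mode_a(self):
        chain = _imgt_numbered_chain()
        rmap = regions.RegionMap.imgt()
        moved = []
        for r in chain.residues:
            shift = (np.array([5.0, 0, 0])
                     if rmap.region_of(r.number) == "CDR3" else 0.0)
            moved.append(structure_io.Residue(
                number=r.number, icode="", name=r.name,
                n=r.n + shift, ca=r.ca + shift, c=r.c + shift))
        chain_b = structure_io.BackboneChain(chain_id="A", residues=moved)
        res = superpose.superpose(chain, chain_b, regions_a=rmap)
        per = res.rmsd_per_region
        # the 12 displaced residues dominate their own profile; the global
        # fit absorbs part of the 5 Å shift (rotation + translation share)
        assert 3.5 <= per["CDR3"]["global_fit"] <= 5.5
        assert per["CDR3"]["global_fit"] == max(
            v["global_fit"] for v in per.values())
        # nearby frameworks see only the fit's residual
        assert per["FR1"]["global_fit"] < 1.0
        assert per["FR2"]["global_fit"] < 1.0
        # refitting CDR3 alone recovers the rigid displacement exactly
        assert per["CDR3"]["refit"] <= 1e-6

    def test_tiny_region_refit_undefined(self):
        chain = _imgt_numbered_chain()
        rmap = regions.RegionMap({"FR1": (1, 40), "TINY": (40, 42),
                                  "REST": (42, 200)})
        res = superpose.superpose(chain, chain, regions_a=rmap)
        assert res.rmsd_per_region["TINY"]["refit"] is None
        assert res.rmsd_per_region["TINY"]["global_fit"] is not None


class TestResiduewiseDeviation:
    def test_self_comparison_is_zero(self, strand_chain):
        dev = superpose.residuewise_deviation(strand_chain, strand_chain)
        assert np.all(dev <= 1e-9)

    def test_single_displaced_residue_scale(self):
        chain = _imgt_numbered_chain()
        k = 60
        moved = [structure_io.Residue(
            number=r.number, icode="", name=r.name,
            n=r.n + (15.0 if i == k else 0.0) * np.array([0, 0, 1.0]),
            ca=r.ca + (15.0 if i == k else 0.0) * np.array([0, 0, 1.0]),
            c=r.c + (15.0 if i == k else 0.0) * np.array([0, 0, 1.0]))
            for i, r in enumerate(chain.residues)]
        chain_b = structure_io.BackboneChain(chain_id="A", residues=moved)
        dev = superpose.residuewise_deviation(chain, chain_b)
        assert 13.0 <= dev[k] <= 15.5
        assert np.median(dev) < 1.0

    def test_profile_invariant_under_rigid_motion(self, rng):
        a = _imgt_numbered_chain()
        b = _imgt_numbered_chain(seed=1)
        base = superpose.residuewise_deviation(a, b)
        R, t = random_rigid_transform(rng)
        again = superpose.residuewise_deviation(a, apply_rigid(b, R, t))
        assert np.allclose(base, again, atol=1e-6)

    def test_length_mismatch_rejected(self, strand_chain):
        short = structure_io.BackboneChain(
            chain_id="A", residues=strand_chain.residues[:-1])
        with pytest.raises(ValueError):
            superpose.residuewise_deviation(strand_chain, short)


class TestGDT:
    def test_identical_gives_100(self):
        assert superpose.gdt_ts_from_deviations(np.zeros(10)) == 100.0

    def test_all_beyond_8_gives_0(self):
        assert superpose.gdt_ts_from_deviations(np.full(10, 9.0)) == 0.0

    def test_hand_enumerated_mixed_case(self):
        # thresholds 1/2/4/8 pass 1,2,3,3 of 4 pairs -> mean(25,50,75,75)
        dev = np.array([0.5, 1.5, 3.0, 9.0])
        assert superpose.gdt_ts_from_deviations(dev) == pytest.approx(56.25)

    def test_monotone_in_each_deviation(self, rng):
        dev = rng.uniform(0, 10, 20)
        base = superpose.gdt_ts_from_deviations(dev)
        for _ in range(20):
            worse = dev.copy()
            worse[rng.integers(len(dev))] += rng.uniform(0, 5)
            assert superpose.gdt_ts_from_deviations(worse) <= base + 1e-12
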