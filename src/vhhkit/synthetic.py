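"""Synthetic fixtures: backbones, model ensembles, sequence families, Cys pairs.

Every generator is a pure function of its configuration (seed included), so
identical configs give byte-identical output. The generators emulate the
kinds of data the analytics consume in production — crystallographic/model
backbones, aligned VHH families, disulfide geometries — with planted ground
truth recorded alongside, so every analysis stage can be tested against a
known answer without downloading anything.

Backbones are built in internal coordinates (NeRF) with ideal bond lengths
and angles and trans peptides; only the φ/ψ torsions vary, which is exactly
the degrees of freedom the Protein Block alphabet reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from . import alphabet
from .geometry import circular_mean_deg, place_atom, wrap_angle
from .structure_io import BackboneChain, Residue, compute_dihedrals

# Engh-Huber-style ideal backbone geometry.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
# cysteine side chain
BOND_CA_CB = 1.530
BOND_CB_SG = 1.808
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_SG = 114.4
ANGLE_CB_SG_SG = 104.2

#: IMGT-style region layout used by the family generator: (label span start,
#: residue count). FR lengths follow the observed VHH medians (25/17/37/11),
#: CDR1/CDR2 their 8-residue medians, CDR3 the 12-residue case-study length
#: so that CDR3 labels stay inside the IMGT 105-117 span.
DEFAULT_REGION_LAYOUT = (
    ("FR1", 2, 25), ("CDR1", 27, 8), ("FR2", 39, 17), ("CDR2", 56, 8),
    ("FR3", 68, 37), ("CDR3", 105, 12), ("FR4", 118, 11),
)

#: Median pairwise identity targets (%) per region, as observed for VHH
#: families: conserved frameworks, hypervariable CDRs.
DEFAULT_IDENTITY_TARGETS = {
    "FR1": 84.0, "FR2": 72.0, "FR3": 81.0, "FR4": 90.0,
    "CDR1": 28.0, "CDR2": 25.0, "CDR3": 18.0,
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Successor table of frequent PB transitions, read off the recurrent
#: structural words of the immunoglobulin fold (strand runs ``dddd``,
#: the loop words ``dehia``/``dehjf``, ``fklpc``, ``cdddd``, helix ``mmmm``).
FREQUENT_TRANSITIONS = {
    "d": "de", "e": "h", "h": "ij", "i": "a", "j": "f", "a": "f",
    "f": "k", "k": "l", "l": "p", "p": "c", "c": "cd", "m": "m",
}

#: Maximum circular deviation (degrees) among a prototype's four φ (and
#: four ψ) window slots for the prototype to count as repetitive, i.e.
#: realisable as an arbitrarily long homopolymer.
_REPETITIVE_SPREAD_DEG = 15.0


def repetitive_pbs() -> str:
    """PB letters whose window prescriptions are self-consistent.

    A prototype prescribes φ and ψ at four window offsets; only when those
    prescriptions agree (within a small spread) can a homopolymeric run of
    that letter be realised by any torsion series. For the reference table
    this yields exactly 'd' and 'm' — the central-strand and α-helix
    prototypes, the alphabet's only repetitive structures. The remaining
    14 letters are caps/coils and are realisable only in short runs.
    """
    out = []
    for x in alphabet.PB_LABELS:
        w = alphabet.PB_REFERENCE_ANGLES[x]
        ok = True
        for slots in ((w[1], w[3], w[5], w[7]), (w[0], w[2], w[4], w[6])):
            m = circular_mean_deg(slots)
            dev = max(abs(wrap_angle(s - m)) for s in slots)
            if dev > _REPETITIVE_SPREAD_DEG:
                ok = False
        if ok:
            out.append(x)
    return "".join(out)


def random_pb_string(length: int, rng: np.random.Generator,
                     kind: str = "transitions") -> str:
    """Random realisable PB string.

    ``kind='homopolymer'`` repeats one repetitive prototype; ``kind=
    'transitions'`` walks the frequent-transition graph, capping runs of
    non-repetitive letters at two (longer runs are not realisable).
    """
    if length < 5:
        raise ValueError("PB strings must have length >= 5")
    if kind == "homopolymer":
        reps = repetitive_pbs()
        return reps[rng.integers(len(reps))] * length
    if kind != "transitions":
        raise ValueError("kind must be 'homopolymer' or 'transitions'")
    reps = repetitive_pbs()
    s = "d" if rng.random() < 0.8 else "m"
    while len(s) < length:
        succ = FREQUENT_TRANSITIONS[s[-1]]
        c = succ[rng.integers(len(succ))]
        if c not in reps and len(s) >= 2 and s[-1] == c and s[-2] == c:
            alts = [x for x in succ if x != c]
            c = alts[0] if alts else "d"
        s += c
    return s


@dataclass
class GeneratorConfig:
    seed: int = 0
    omega: float = 180.0
    noise_sigma_deg: float = 0.0
    n_sequences: int = 50
    identity_targets: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_TARGETS))
    region_layout: tuple = DEFAULT_REGION_LAYOUT
    extra_cys: Optional[str] = None   # None | "type1" | "type2" | "intra_cdr3"
    vhh_hallmarks: bool = True

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# -- backbone construction -------------------------------------------------

def _build_chain_from_torsions(phi: np.ndarray, psi: np.ndarray,
                               omega: float = 180.0,
                               resnames: Optional[Sequence[str]] = None,
                               numbers: Optional[Sequence[int]] = None,
                               chain_id: str = "A") -> BackboneChain:
    """NeRF chain build; phi[0] and psi[-1] are ignored (undefined)."""
    n = len(phi)
    if resnames is None:
        resnames = ["ALA"] * n
    if numbers is None:
        numbers = list(range(1, n + 1))
    atoms = []  # flat list of backbone atoms N, CA, C per residue
    # seed the first three atoms in a plane
    N0 = np.zeros(3)
    CA0 = N0 + np.array([BOND_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    atoms.extend([N0, CA0, C0])
    for i in range(1, n):
        pN, pCA, pC = atoms[-3], atoms[-2], atoms[-1]
        Ni = place_atom(pN, pCA, pC, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CAi = place_atom(pCA, pC, Ni, BOND_N_CA, ANGLE_C_N_CA, omega)
        Ci = place_atom(pC, Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        atoms.extend([Ni, CAi, Ci])
    residues = []
    for i in range(n):
        N, CA, C = atoms[3 * i], atoms[3 * i + 1], atoms[3 * i + 2]
        residues.append(Residue(number=int(numbers[i]), icode="",
                                name=resnames[i], n=N, ca=CA, c=C))
    return BackboneChain(chain_id=chain_id, residues=residues)


def pb_string_torsions(pbs: str):
    """Per-residue φ/ψ implied by a PB string.

    Each residue's PB prescribes dihedrals for a 5-residue window, so
    overlapping prototypes give up to four prescriptions per torsion; these
    are reconciled by circular mean. Exact for homopolymeric strings (all
    prescriptions agree); approximate across prototype transitions.
    """
    bad = set(pbs) - set(alphabet.PB_LABELS)
    if bad:
        raise ValueError(f"invalid PB label(s): {sorted(bad)}")
    n = len(pbs)
    if n < 5:
        raise ValueError("PB string must have length >= 5")
    proto = alphabet.PB_REFERENCE_ANGLES
    phi_votes = [[] for _ in range(n)]
    psi_votes = [[] for _ in range(n)]
    for j, x in enumerate(pbs):
        w = proto[x]
        # window of residue j: psi[j-2], phi[j-1], psi[j-1], phi[j], psi[j],
        # phi[j+1], psi[j+1], phi[j+2]
        for off, val in ((-2, ("psi", w[0])), (-1, ("phi", w[1])),
                         (-1, ("psi", w[2])), (0, ("phi", w[3])),
                         (0, ("psi", w[4])), (1, ("phi", w[5])),
                         (1, ("psi", w[6])), (2, ("phi", w[7]))):
            i = j + off
            if 0 <= i < n:
                (phi_votes if val[0] == "phi" else psi_votes)[i].append(val[1])
    phi = np.array([circular_mean_deg(v) if v else -120.0 for v in phi_votes])
    psi = np.array([circular_mean_deg(v) if v else 140.0 for v in psi_votes])
    return phi, psi


def build_backbone_from_pb_string(pbs: str,
                                  config: Optional[GeneratorConfig] = None,
                                  chain_id: str = "A") -> BackboneChain:
    """Build an ideal-geometry backbone whose torsions follow a PB string."""
    config = config or GeneratorConfig()
    phi, psi = pb_string_torsions(pbs)
    if config.noise_sigma_deg > 0:
        rng = config.rng()
        phi = wrap_angle(phi + rng.normal(0, config.noise_sigma_deg, len(phi)))
        psi = wrap_angle(psi + rng.normal(0, config.noise_sigma_deg, len(psi)))
    return _build_chain_from_torsions(phi, psi, omega=config.omega,
                                      chain_id=chain_id)


def rebuild_with_torsions(chain: BackboneChain, phi, psi,
                          omega: float = 180.0) -> BackboneChain:
    """New chain with this chain's residue labels but the given torsions."""
    return _build_chain_from_torsions(
        np.asarray(phi, float), np.asarray(psi, float), omega=omega,
        resnames=[r.name for r in chain.residues],
        numbers=[r.number for r in chain.residues],
        chain_id=chain.chain_id)


def perturb_ensemble(chain: BackboneChain, n_models: int,
                     sigma_deg: float = 0.0,
                     hotspots: Optional[dict] = None,
                     config: Optional[GeneratorConfig] = None) -> list:
    """Rebuild ``n_models`` copies with torsion noise; returns chains.

    ``hotspots`` maps residue index -> extra Gaussian sigma (degrees) added
    on top of the global noise at that residue's φ and ψ.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if sigma_deg < 0:
        raise ValueError("sigma must be non-negative")
    config = config or GeneratorConfig()
    rng = config.rng()
    hotspots = hotspots or {}
    for extra in hotspots.values():
        if float(extra) < 0:
            raise ValueError("hotspot sigma must be non-negative")
    base = compute_dihedrals(chain)
    phi0 = np.where(np.isnan(base.phi), -120.0, base.phi)
    psi0 = np.where(np.isnan(base.psi), 140.0, base.psi)
    models = []
    for _ in range(n_models):
        phi = phi0 + (rng.normal(0, sigma_deg, len(phi0)) if sigma_deg > 0
                      else 0.0)
        psi = psi0 + (rng.normal(0, sigma_deg, len(psi0)) if sigma_deg > 0
                      else 0.0)
        for pos, extra in hotspots.items():
            if float(extra) > 0:
                phi[pos] += rng.normal(0, float(extra))
                psi[pos] += rng.normal(0, float(extra))
        models.append(rebuild_with_torsions(
            chain, wrap_angle(phi), wrap_angle(psi)))
    return models


def two_state_ensemble(pb_string: str, n_models: int,
                       flips: dict, sigma_deg: float = 0.0,
                       config: Optional[GeneratorConfig] = None):
    """Ensemble mixing two local conformations at planted hotspot(s).

    ``flips`` maps a start index to ``(pb_word, prob)``: in a fraction
    ``prob`` of the models (exact quota, membership randomised by seed)
    the PB prescription at ``[start, start + len(word))`` is replaced by
    the word before the backbone is built. A single torsion offset does
    not change the assigned block — the strand/helix basins are wide — so
    local conformational flips are planted at the PB level, which is also
    what distinct modelling templates produce.

    Returns ``(models, truth)`` where ``truth`` maps each start index to
    the sorted indices of the flipped models.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if sigma_deg < 0:
        raise ValueError("sigma must be non-negative")
    config = config or GeneratorConfig()
    rng = config.rng()
    flipped_models = {}
    for start, (word, prob) in flips.items():
        if not 0 <= prob <= 1:
            raise ValueError("flip probability must be in [0, 1]")
        if start + len(word) > len(pb_string):
            raise ValueError("flip word extends past the PB string")
        k = int(round(prob * n_models))
        flipped_models[start] = set(
            int(i) for i in rng.permutation(n_models)[:k])
    models = []
    for imodel in range(n_models):
        s = pb_string
        for start, (word, _prob) in flips.items():
            if imodel in flipped_models[start]:
                s = s[:start] + word + s[start + len(word):]
        phi, psi = pb_string_torsions(s)
        if sigma_deg > 0:
            phi = wrap_angle(phi + rng.normal(0, sigma_deg, len(phi)))
            psi = wrap_angle(psi + rng.normal(0, sigma_deg, len(psi)))
        models.append(_build_chain_from_torsions(phi, psi))
    truth = {start: sorted(idx) for start, idx in flipped_models.items()}
    return models, truth


# -- sequence family -------------------------------------------------------

def _mutation_rate(target_identity_pct: float, n_protected: int,
                   length: int) -> float:
    """Per-site mutation probability giving the target expected pairwise
    identity, with ``n_protected`` sites never mutated.

    Two sequences mutated independently from one root match at a free site
    with probability m = (1-p)^2 + p^2/18 (mutations uniform over the 18
    non-root, non-Cys alternatives; cysteines are planted, never drawn).
    Protected sites always match.
    """
    m_region = target_identity_pct / 100.0
    free = length - n_protected
    if free <= 0:
        return 0.0
    m_free = (m_region * length - n_protected) / free
    if m_free >= 1.0:
        return 0.0
    floor = 1.0 / 18.0  # identity of two independent random mutants
    if m_free < floor:
        raise ValueError(
            f"target identity {target_identity_pct}% infeasible: below the "
            "random-composition baseline for this region")
    # solve (19/18) p^2 - 2 p + 1 - m_free = 0 for the root in [0, 1]
    a, b, c = 19.0 / 18.0, -2.0, 1.0 - m_free
    p = (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return float(np.clip(p, 0.0, 1.0))


def generate_sequence_family(config: Optional[GeneratorConfig] = None):
    """Aligned VHH-like family with controlled per-region identity.

    Returns ``(records, region_map, truth)`` where records are
    ``(id, sequence)`` with all sequences the same length (a gap-free
    alignment), region_map covers the alignment columns, and truth records
    every planted feature (hallmarks, cysteines, per-region rates).
    """
    from .regions import RegionMap

    config = config or GeneratorConfig()
    rng = config.rng()

    columns = []        # IMGT-style label per alignment column
    region_of = []      # region name per column
    for name, start, count in config.region_layout:
        for k in range(count):
            columns.append(start + k)
            region_of.append(name)
    length = len(columns)
    col_of_label = {lab: i for i, lab in enumerate(columns)}

    # root sequence; cysteines only where planted
    non_cys = [a for a in _AA20 if a != "C"]
    root = rng.choice(non_cys, size=length)
    planted = {}
    def plant(label, aa):
        if label in col_of_label:
            root[col_of_label[label]] = aa
            planted[label] = aa

    plant(23, "C"); plant(104, "C"); plant(41, "W")
    if config.vhh_hallmarks:
        plant(42, "F"); plant(49, "E"); plant(50, "R"); plant(52, "G")
        plant(11, "S")
    else:
        plant(42, "V"); plant(49, "G"); plant(50, "L"); plant(52, "W")
        plant(11, "L")
    extra_pairs = {"type1": (30, 110), "type2": (45, 112),
                   "intra_cdr3": (107, 114)}
    if config.extra_cys:
        a, b = extra_pairs[config.extra_cys]
        plant(a, "C"); plant(b, "C")

    protected_cols = {col_of_label[lab] for lab in planted}
    # per-region mutation rates from the identity targets
    rates = {}
    for name in {r for r in region_of}:
        cols = [i for i, r in enumerate(region_of) if r == name]
        n_prot = sum(1 for i in cols if i in protected_cols)
        target = config.identity_targets.get(name, 80.0)
        rates[name] = _mutation_rate(target, n_prot, len(cols))

    # fixed per-sequence mutation counts (Bernoulli-rounded) keep realised
    # pairwise identities tightly centred on the targets
    free_cols = {name: [i for i, r in enumerate(region_of)
                        if r == name and i not in protected_cols]
                 for name in rates}
    records = []
    for k in range(config.n_sequences):
        seq = root.copy()
        for name, p in rates.items():
            cols = free_cols[name]
            expected = p * len(cols)
            n_mut = int(expected) + (rng.random() < expected - int(expected))
            n_mut = min(n_mut, len(cols))
            for i in rng.choice(len(cols), size=n_mut, replace=False):
                col = cols[int(i)]
                alternatives = [a for a in non_cys if a != root[col]]
                seq[col] = alternatives[rng.integers(len(alternatives))]
        records.append((f"seq{k + 1:03d}", "".join(seq)))

    # the layout's labels all fall inside the canonical IMGT spans, so the
    # standard contiguous region map applies directly
    region_map = RegionMap.imgt()
    truth = {
        "planted": dict(planted),
        "rates": rates,
        "targets": dict(config.identity_targets),
        "columns": list(columns),
        "region_of_column": list(region_of),
        "extra_cys": config.extra_cys,
        "root": "".join(root),
    }
    return records, region_map, truth


# -- cysteine pair geometry ------------------------------------------------

def generate_cys_pair(dihedrals: Sequence[float], ss_distance: float = 2.05,
                      config: Optional[GeneratorConfig] = None,
                      numbers=(23, 104)) -> BackboneChain:
    """Two-cysteine fragment realising prescribed disulfide dihedrals.

    ``dihedrals`` = (χ1, χ2, χ3, χ'2, χ'1) in Cα→Cα path order along
    N-CA-CB-SG...SG'-CB'-CA'-N'. Atoms are placed by NeRF along that path,
    so re-measuring recovers each prescription to numerical precision.
    """
    if ss_distance <= 0:
        raise ValueError("S-S distance must be positive")
    chi1, chi2, chi3, chi2p, chi1p = (float(x) for x in dihedrals)
    for v in (chi1, chi2, chi3, chi2p, chi1p):
        if not (-180.0 < v <= 180.0):
            raise ValueError("dihedrals must lie in (-180, 180]")

    # residue A backbone + side chain
    N1 = np.zeros(3)
    CA1 = np.array([BOND_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - ANGLE_N_CA_CB)
    CB1 = CA1 + BOND_CA_CB * np.array([np.cos(th), np.sin(th), 0.0])
    SG1 = place_atom(N1, CA1, CB1, BOND_CB_SG, ANGLE_CA_CB_SG, chi1)
    SG2 = place_atom(CA1, CB1, SG1, ss_distance, ANGLE_CB_SG_SG, chi2)
    CB2 = place_atom(CB1, SG1, SG2, BOND_CB_SG, ANGLE_CB_SG_SG, chi3)
    CA2 = place_atom(SG1, SG2, CB2, BOND_CA_CB, ANGLE_CA_CB_SG, chi2p)
    N2 = place_atom(SG2, CB2, CA2, BOND_N_CA, ANGLE_N_CA_CB, chi1p)
    # complete both backbones with C so the residues parse as full residues
    C1 = place_atom(CB1, N1, CA1, BOND_CA_C, ANGLE_N_CA_C, -120.0)
    C2 = place_atom(CB2, N2, CA2, BOND_CA_C, ANGLE_N_CA_C, -120.0)

    res_a = Residue(number=int(numbers[0]), icode="", name="CYS",
                    n=N1, ca=CA1, c=C1, cb=CB1, sg=SG1)
    res_b = Residue(number=int(numbers[1]), icode="", name="CYS",
                    n=N2, ca=CA2, c=C2, cb=CB2, sg=SG2)
    return BackboneChain(chain_id="A", residues=[res_a, res_b])
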