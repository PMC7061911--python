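"""Rigid-body superposition and similarity scores (RMSD, GDT-TS).

The optimal proper rotation is the least-squares (Kabsch) fit, obtained
from scipy's ``Rotation.align_vectors`` (which never returns a reflection).
RMSD is the root mean square distance over the mapped atom pairs after the
fit; equivalence of atoms is always explicit via an AtomMapping — segments
of different length are never force-mapped. GDT-TS is computed from the
single global superposition (a documented approximation of the full
per-threshold search) as the mean over 1/2/4/8 Å of the percentage of
mapped Cα pairs within each threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .regions import RegionMap
from .structure_io import BackboneChain

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class AtomMapping:
    """Explicit residue-pair equivalence with an atom-set selector."""

    pairs: Tuple[Tuple[int, int], ...]   # (index in A, index in B)
    atoms: str = "ca"                    # "ca" | "backbone"

    def __post_init__(self):
        if self.atoms not in ("ca", "backbone"):
            raise ValueError("atoms must be 'ca' or 'backbone'")
        ia = [a for a, _ in self.pairs]
        ib = [b for _, b in self.pairs]
        if sorted(set(ia)) != ia or sorted(set(ib)) != ib:
            raise ValueError(
                "mapping pairs must be unique and monotone in both chains")

    @classmethod
    def identity(cls, n: int, atoms: str = "ca") -> "AtomMapping":
        return cls(tuple((i, i) for i in range(n)), atoms=atoms)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # (3, 3) proper rotation applied to B
    translation: np.ndarray       # (3,) added after rotation
    rmsd_global: float
    per_residue_deviation: np.ndarray   # per mapped pair, Å
    gdt_ts: float
    mapping: AtomMapping
    rmsd_per_region: Dict[str, dict] = field(default_factory=dict)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _atom_arrays(chain: BackboneChain, indices, atoms: str) -> np.ndarray:
    names = ("CA",) if atoms == "ca" else ("N", "CA", "C", "O")
    rows = []
    for i in indices:
        r = chain.residues[i]
        for name in names:
            coord = getattr(r, name.lower())
            if coord is None:
                raise ValueError(
                    f"residue {r.label} lacks atom {name} for the "
                    f"'{atoms}' atom set")
            rows.append(coord)
    return np.array(rows)


def superpose(chain_a: BackboneChain, chain_b: BackboneChain,
              mapping: Optional[AtomMapping] = None,
              regions_a: Optional[RegionMap] = None) -> SuperpositionResult:
    """Least-squares rigid fit of chain B onto chain A over mapped atoms."""
    if mapping is None:
        if len(chain_a) != len(chain_b):
            raise ValueError("chains differ in length; provide a mapping")
        mapping = AtomMapping.identity(len(chain_a))
    if len(mapping.pairs) < 3:
        raise ValueError("need at least 3 mapped residue pairs")
    ia = [a for a, _ in mapping.pairs]
    ib = [b for _, b in mapping.pairs]
    A = _atom_arrays(chain_a, ia, mapping.atoms)
    B = _atom_arrays(chain_b, ib, mapping.atoms)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(np.vstack([A0, B0])) < 2:
        raise ValueError("degenerate (collinear) geometry")
    rot, _ = Rotation.align_vectors(A0, B0)
    R = rot.as_matrix()
    t = ca - cb @ R.T
    Bf = B @ R.T + t
    dev_atoms = np.linalg.norm(A - Bf, axis=1)
    rmsd = float(np.sqrt(np.mean(dev_atoms ** 2)))
    # per-residue deviation: RMS over the residue's atoms in the atom set
    natoms = 1 if mapping.atoms == "ca" else 4
    per_res = np.sqrt(
        (dev_atoms ** 2).reshape(len(mapping.pairs), natoms).mean(axis=1))
    # GDT-TS always over Cα pairs
    ca_a = np.array([chain_a.residues[i].ca for i in ia])
    ca_b = np.array([chain_b.residues[i].ca for i in ib])
    ca_dev = np.linalg.norm(ca_a - (ca_b @ R.T + t), axis=1)
    gdt = gdt_ts_from_deviations(ca_dev)
    result = SuperpositionResult(
        rotation=R, translation=t, rmsd_global=rmsd,
        per_residue_deviation=per_res, gdt_ts=gdt, mapping=mapping)
    if regions_a is not None:
        result.rmsd_per_region = region_rmsd(chain_a, chain_b, result,
                                             regions_a)
    return result


def gdt_ts_from_deviations(deviations: np.ndarray,
                           thresholds: Sequence[float] = GDT_THRESHOLDS
                           ) -> float:
    """Mean over thresholds of the percentage of pairs within threshold."""
    d = np.asarray(deviations, float)
    return float(np.mean([100.0 * np.mean(d <= t) for t in thresholds]))


def region_rmsd(chain_a: BackboneChain, chain_b: BackboneChain,
                result: SuperpositionResult,
                regions_a: RegionMap) -> Dict[str, dict]:
    """Per-region deviation under the global fit, and per-region refit.

    Mode ``global_fit``: RMS of the region's residues' deviations from the
    already-computed global superposition. Mode ``refit``: an independent
    superposition over the region's pairs alone (None when < 3 pairs).
    """
    out: Dict[str, dict] = {}
    pair_region = []
    for (i, _j) in result.mapping.pairs:
        pair_region.append(regions_a.region_of(chain_a.residues[i].number))
    for name in regions_a.spans:
        sel = [k for k, r in enumerate(pair_region) if r == name]
        entry = {"n_pairs": len(sel), "global_fit": None, "refit": None}
        if sel:
            entry["global_fit"] = float(np.sqrt(np.mean(
                result.per_residue_deviation[np.array(sel)] ** 2)))
        if len(sel) >= 3:
            sub = AtomMapping(tuple(result.mapping.pairs[k] for k in sel),
                              atoms=result.mapping.atoms)
            try:
                entry["refit"] = superpose(chain_a, chain_b, sub).rmsd_global
            except ValueError:
                entry["refit"] = None
        out[name] = entry
    return out


def residuewise_deviation(reference: BackboneChain, model: BackboneChain,
                          atoms: str = "ca") -> np.ndarray:
    """Per-residue Cα deviation of a model from a reference of the same
    sequence (identity mapping) after a global fit."""
    if len(reference) != len(model):
        raise ValueError("reference and model differ in residue count")
    res = superpose(reference, model,
                    AtomMapping.identity(len(reference), atoms=atoms))
    if atoms == "ca":
        return res.per_residue_deviation
    ca_r = reference.coords("CA")
    ca_m = res.transform(model.coords("CA"))
    return np.linalg.norm(ca_r - ca_m, axis=1)
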