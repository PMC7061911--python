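"""PDB coordinate parsing into backbone chains plus backbone/cysteine torsions.

Parsing is delegated to gemmi; this module reduces a coordinate file to the
minimal per-residue record the rest of the pipeline consumes (N/CA/C required,
O/CB/SG optional), resolves alternate locations, flags chain breaks, and
measures φ/ψ and cysteine χ1 torsions.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .geometry import dihedral

#: C(i)-N(i+1) distance above which two consecutive residues are treated as a
#: chain break (peptide bond ~1.33 Å; generous margin for poor files).
BREAK_THRESHOLD = 2.5

_BACKBONE = ("N", "CA", "C")
_OPTIONAL = ("O", "CB", "SG")
_WATER = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for malformed or unusable coordinate input."""


@dataclass(frozen=True)
class Residue:
    number: int
    icode: str
    name: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: Optional[np.ndarray] = None
    cb: Optional[np.ndarray] = None
    sg: Optional[np.ndarray] = None

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}".strip()


@dataclass
class BackboneChain:
    """Ordered backbone of one chain (one model) with break bookkeeping."""

    chain_id: str
    residues: list
    break_flags: list = field(default_factory=list)
    dropped: int = 0  # residues excluded for missing N/CA/C
    model: int = 1

    def __post_init__(self):
        if not self.break_flags and len(self.residues) > 1:
            self.break_flags = [
                float(np.linalg.norm(b.n - a.c)) > BREAK_THRESHOLD
                for a, b in zip(self.residues, self.residues[1:])
            ]

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, atom: str = "CA") -> np.ndarray:
        """(n, 3) array of one backbone atom per residue."""
        return np.array([getattr(r, atom.lower()) for r in self.residues])

    def sequence3(self) -> list:
        return [r.name for r in self.residues]


@dataclass
class DihedralSeries:
    """Per-residue φ/ψ in degrees; NaN where undefined (termini, breaks)."""

    phi: np.ndarray
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> Optional[gemmi.Atom]:
    """Highest occupancy wins; ties resolved by first occurrence."""
    best = None
    for at in atoms:
        if best is None or at.occ > best.occ:
            best = at
    return best


def _prevalidate(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise StructureError(
                    f"malformed ATOM/HETATM record at line {lineno}: too short")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise StructureError(
                    f"malformed ATOM/HETATM record at line {lineno}: "
                    "bad coordinate fields") from None


def parse_structure(pdb_text: str, chain_selector: Optional[str] = None,
                    require_nonempty: bool = True) -> list:
    """Parse PDB text into BackboneChain objects, one per (model, chain).

    Alternate locations keep the highest-occupancy copy (ties: first seen);
    hydrogens and waters are ignored; residues missing any of N/CA/C are
    dropped and counted in ``chain.dropped``.
    """
    _prevalidate(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unreadable PDB input: {exc}") from exc

    chains: list = []
    for imodel, model in enumerate(st, start=1):
        for chain in model:
            if chain_selector is not None and chain.name != chain_selector:
                continue
            residues, dropped = [], 0
            for res in chain:
                if res.name in _WATER:
                    continue
                picked = {}
                for name in _BACKBONE + _OPTIONAL:
                    group = [a for a in res if a.name == name]
                    at = _pick_altloc(group)
                    if at is not None:
                        picked[name] = np.array(
                            [at.pos.x, at.pos.y, at.pos.z])
                if not any(n in picked for n in _BACKBONE):
                    continue  # ligand/ion: no backbone at all, not "missing"
                if not all(n in picked for n in _BACKBONE):
                    dropped += 1
                    continue
                residues.append(Residue(
                    number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=res.name,
                    n=picked["N"], ca=picked["CA"], c=picked["C"],
                    o=picked.get("O"), cb=picked.get("CB"),
                    sg=picked.get("SG"),
                ))
            if not residues:
                if chain_selector is not None and require_nonempty:
                    raise StructureError(
                        f"chain {chain.name!r} empty after filtering")
                continue
            residues.sort(key=lambda r: (r.number, r.icode))
            chains.append(BackboneChain(chain_id=chain.name,
                                        residues=residues,
                                        dropped=dropped, model=imodel))
    if not chains and require_nonempty:
        raise StructureError("no parseable chains in input")
    return chains


def read_structure(path, chain_selector: Optional[str] = None) -> list:
    """Read a PDB file (optionally gzip-compressed) from disk."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            text = fh.read()
    else:
        text = path.read_text()
    return parse_structure(text, chain_selector=chain_selector)


def compute_dihedrals(chain: BackboneChain) -> DihedralSeries:
    """Backbone φ/ψ per residue; NaN at termini and across chain breaks.

    φ_i = C(i-1)-N(i)-CA(i)-C(i); ψ_i = N(i)-CA(i)-C(i)-N(i+1).
    """
    n = len(chain)
    if n < 2:
        raise StructureError("need at least 2 residues for dihedrals")
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    res = chain.residues
    brk = chain.break_flags
    for i in range(n):
        if i > 0 and not brk[i - 1]:
            phi[i] = dihedral(res[i - 1].c, res[i].n, res[i].ca, res[i].c)
        if i < n - 1 and not brk[i]:
            psi[i] = dihedral(res[i].n, res[i].ca, res[i].c, res[i + 1].n)
    return DihedralSeries(phi=phi, psi=psi)


def cysteine_chi1(chain: BackboneChain, residue_index: int) -> float:
    """χ1 = N-CA-CB-SG of a cysteine, degrees in (-180, 180]."""
    res = chain.residues[residue_index]
    if res.name != "CYS":
        raise StructureError(
            f"residue {res.label} is {res.name}, not CYS")
    if res.cb is None or res.sg is None:
        missing = "CB" if res.cb is None else "SG"
        raise StructureError(
            f"cysteine {res.label} is missing atom {missing}")
    return dihedral(res.n, res.ca, res.cb, res.sg)


def to_pdb_string(chains) -> str:
    """Serialise BackboneChain(s) back to minimal PDB text (via gemmi)."""
    if isinstance(chains, BackboneChain):
        chains = [chains]
    st = gemmi.Structure()
    by_model: dict = {}
    for ch in chains:
        by_model.setdefault(ch.model, []).append(ch)
    for imodel in sorted(by_model):
        model = gemmi.Model(imodel)
        for ch in by_model[imodel]:
            gch = gemmi.Chain(ch.chain_id)
            for r in ch.residues:
                gres = gemmi.Residue()
                gres.name = r.name
                gres.seqid = gemmi.SeqId(r.number, r.icode or " ")
                for aname, coord, elem in (
                        ("N", r.n, "N"), ("CA", r.ca, "C"), ("C", r.c, "C"),
                        ("O", r.o, "O"), ("CB", r.cb, "C"), ("SG", r.sg, "S")):
                    if coord is None:
                        continue
                    at = gemmi.Atom()
                    at.name = aname
                    at.element = gemmi.Element(elem)
                    at.pos = gemmi.Position(*map(float, coord))
                    at.occ = 1.0
                    gres.add_atom(at)
                gch.add_residue(gres)
            model.add_chain(gch)
        st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def write_pdb(chains, path) -> None:
    Path(path).write_text(to_pdb_string(chains))


def dihedral_table(chain: BackboneChain):
    """Per-residue φ/ψ as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    dh = compute_dihedrals(chain)
    return pd.DataFrame({
        "chain": chain.chain_id,
        "resnum": [r.number for r in chain.residues],
        "icode": [r.icode for r in chain.residues],
        "resname": [r.name for r in chain.residues],
        "phi": dh.phi,
        "psi": dh.psi,
    })
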