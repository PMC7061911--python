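"""Disulfide bridge detection, sign-pattern geometry, and VHH topology.

A disulfide bridge is characterised by the five torsions along the
Cα→Cα path N-CA-CB-SG···SG'-CB'-CA'-N':

    χ1  = N - CA - CB - SG
    χ2  = CA - CB - SG - SG'
    χ3  = CB - SG - SG' - CB'
    χ'2 = SG - SG' - CB' - CA'
    χ'1 = SG' - CB' - CA' - N'

Torsions are stored and printed in that path order (χ1, χ2, χ3, χ'2, χ'1).
The sign pattern maps each torsion to '+' or '-' (zero counts as '+');
an all-negative pattern is the low-strain conformation. Within the VHH
architecture a bridge is classed as canonical (Cys23-Cys104), type 1
(CDR1-CDR3), type 2 (FR2-CDR3, with the FR2/CDR2 boundary counting as
FR2), intra-CDR3, or other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .geometry import dihedral
from .regions import RegionMap
from .structure_io import BackboneChain

#: SG-SG distance (Å) at or below which two cysteines count as bonded.
SS_DISTANCE_THRESHOLD = 2.3

DIHEDRAL_NAMES = ("chi1", "chi2", "chi3", "chi2_prime", "chi1_prime")

TOPOLOGY_CLASSES = ("canonical", "type1", "type2", "intra_cdr3", "other")


@dataclass
class DisulfideBridge:
    index_a: int                  # residue index of the N-terminal cysteine
    index_b: int
    number_a: int                 # residue (scheme) numbers
    number_b: int
    dihedrals: Tuple[float, float, float, float, float]
    ss_distance: float
    topology: Optional[str] = None

    @property
    def sign_pattern(self) -> str:
        return sign_pattern(self)


def sign_pattern(bridge: DisulfideBridge) -> str:
    """5-character '+'/'-' pattern in path order (χ1, χ2, χ3, χ'2, χ'1)."""
    for name, value in zip(DIHEDRAL_NAMES, bridge.dihedrals):
        if value is None or np.isnan(value):
            raise ValueError(f"dihedral {name} is undefined for this bridge")
    return "".join("-" if d < 0 else "+" for d in bridge.dihedrals)


def _bridge_dihedrals(res_a, res_b) -> Tuple[float, ...]:
    return (
        dihedral(res_a.n, res_a.ca, res_a.cb, res_a.sg),          # chi1
        dihedral(res_a.ca, res_a.cb, res_a.sg, res_b.sg),         # chi2
        dihedral(res_a.cb, res_a.sg, res_b.sg, res_b.cb),         # chi3
        dihedral(res_a.sg, res_b.sg, res_b.cb, res_b.ca),         # chi2'
        dihedral(res_b.sg, res_b.cb, res_b.ca, res_b.n),          # chi1'
    )


def detect_bridges(chain: BackboneChain,
                   threshold: float = SS_DISTANCE_THRESHOLD
                   ) -> List[DisulfideBridge]:
    """All disulfide bridges in a chain by SG-SG proximity.

    Candidate CYS pairs within the threshold are paired greedily by
    increasing distance, each cysteine joining at most one bridge. The
    N-terminal cysteine of each pair is always cysA, so patterns are
    deterministic.
    """
    cys = []
    for i, res in enumerate(chain.residues):
        if res.name != "CYS":
            continue
        if res.sg is None or res.cb is None:
            warnings.warn(f"cysteine {res.label} lacks CB/SG; skipped")
            continue
        cys.append(i)
    candidates = []
    for ai in range(len(cys)):
        for bi in range(ai + 1, len(cys)):
            i, j = cys[ai], cys[bi]
            d = float(np.linalg.norm(
                chain.residues[i].sg - chain.residues[j].sg))
            if d <= threshold:
                candidates.append((d, i, j))
    candidates.sort()
    used, bridges = set(), []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        ra, rb = chain.residues[i], chain.residues[j]
        bridges.append(DisulfideBridge(
            index_a=i, index_b=j, number_a=ra.number, number_b=rb.number,
            dihedrals=_bridge_dihedrals(ra, rb), ss_distance=d))
    bridges.sort(key=lambda b: (b.index_a, b.index_b))
    return bridges


def classify_topology(bridge: DisulfideBridge,
                      regions: Optional[RegionMap] = None) -> str:
    """VHH topology class of a bridge from the cysteines' scheme positions."""
    regions = regions or RegionMap.imgt()
    if {bridge.number_a, bridge.number_b} == {23, 104}:
        return "canonical"
    ra = regions.region_of(bridge.number_a)
    rb = regions.region_of(bridge.number_b)
    if ra is None or rb is None:
        warnings.warn(
            f"cysteine position {bridge.number_a}/{bridge.number_b} outside "
            "the domain span; classified as 'other'")
        return "other"
    pair = {ra, rb}
    if pair == {"CDR1", "CDR3"}:
        return "type1"
    if pair == {"FR2", "CDR3"}:
        return "type2"
    if pair == {"CDR3"}:
        return "intra_cdr3"
    return "other"


def bridge_table(bridges: List[DisulfideBridge],
                 regions: Optional[RegionMap] = None):
    """Disulfide report as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for b in bridges:
        row = {"cysA": b.number_a, "cysB": b.number_b,
               "distance": b.ss_distance}
        row.update(dict(zip(DIHEDRAL_NAMES, b.dihedrals)))
        row["pattern"] = b.sign_pattern
        row["topology"] = b.topology or classify_topology(b, regions)
        rows.append(row)
    return pd.DataFrame(rows)
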