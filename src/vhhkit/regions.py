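"""IMGT-based FR/CDR segmentation and VHH sequence analytics.

A VHH domain is split into seven regions (FR1, CDR1, FR2, CDR2, FR3, CDR3,
FR4) on the IMGT unique numbering; the same region map is shared by the
sequence statistics here and the structural analytics elsewhere. The
hallmark census covers the FR2 tetrad (42, 49, 50, 52) that historically
distinguishes VHH from conventional VH domains, the position-11 S/L marker,
the conserved Cys23/Cys104 pair, and any extra cysteines with the region
they fall in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Half-open IMGT unique-numbering spans for the seven regions.
IMGT_BOUNDARIES: Dict[str, Tuple[int, int]] = {
    "FR1": (1, 27), "CDR1": (27, 39), "FR2": (39, 56), "CDR2": (56, 66),
    "FR3": (66, 105), "CDR3": (105, 118), "FR4": (118, 129),
}

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

HALLMARK_RULES = {
    42: ({"F", "Y"}, "V"),
    49: ({"E", "K"}, "G"),
    50: ({"R", "C"}, "L"),
    52: ({"G", "L"}, "W"),
}

DSSP_CLASSES = "HGIEBTS-"

_AA_SET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class RegionMap:
    """Seven ordered, contiguous, half-open spans of scheme positions."""

    spans: Dict[str, Tuple[int, int]]

    @classmethod
    def imgt(cls) -> "RegionMap":
        return cls(dict(IMGT_BOUNDARIES))

    def region_of(self, position: int) -> Optional[str]:
        for name, (lo, hi) in self.spans.items():
            if lo <= position < hi:
                return name
        return None

    def span(self, region: str) -> Tuple[int, int]:
        return self.spans[region]

    def __iter__(self):
        return iter(self.spans.items())


@dataclass
class NumberedSequence:
    """A sequence with scheme position labels (gaps simply absent)."""

    id: str
    residues: List[Tuple[int, str]]    # (scheme position, 1-letter aa)
    scheme: str = "IMGT"

    def __post_init__(self):
        positions = [p for p, _ in self.residues]
        if positions != sorted(positions):
            raise ValueError(f"{self.id}: positions not increasing")
        bad = {a for _, a in self.residues} - _AA_SET
        if bad:
            raise ValueError(f"{self.id}: invalid amino acids {sorted(bad)}")

    def at(self, position: int) -> Optional[str]:
        for p, a in self.residues:
            if p == position:
                return a
        return None

    @classmethod
    def from_aligned(cls, seq_id: str, gapped: str,
                     column_positions: Sequence[int],
                     scheme: str = "IMGT") -> "NumberedSequence":
        """Numbered sequence from one row of an alignment whose columns
        carry scheme positions."""
        if len(gapped) != len(column_positions):
            raise ValueError("alignment row and column labels differ in length")
        residues = [(int(p), a) for p, a in zip(column_positions, gapped)
                    if a != "-"]
        return cls(id=seq_id, residues=residues, scheme=scheme)


@dataclass
class HallmarkReport:
    sequence_id: str
    hallmarks: Dict[int, Tuple[Optional[str], str]]  # pos -> (aa, class)
    position11: Tuple[Optional[str], str]
    cys23: bool
    cys104: bool
    extra_cys: List[Tuple[int, Optional[str]]]       # (position, region)

    @property
    def tetrad_class(self) -> str:
        classes = {cls for _, cls in self.hallmarks.values()}
        if classes == {"VHH-like"}:
            return "VHH-like"
        if classes == {"VH-like"}:
            return "VH-like"
        return "mixed"


@dataclass
class SSEProfile:
    freq: np.ndarray      # (n_columns, 8) over DSSP_CLASSES
    support: np.ndarray


def segment_regions(seq: NumberedSequence,
                    boundaries: Optional[RegionMap] = None) -> RegionMap:
    """Region map covering the sequence; residues outside the domain span
    are warned about and ignored by downstream region lookups."""
    region_map = boundaries or RegionMap.imgt()
    outside = [p for p, _ in seq.residues if region_map.region_of(p) is None]
    if outside:
        warnings.warn(
            f"{seq.id}: {len(outside)} residue(s) outside the domain span "
            f"(positions {outside[:5]}...)")
    return region_map


def residues_by_region(seq: NumberedSequence,
                       region_map: Optional[RegionMap] = None
                       ) -> Dict[str, list]:
    region_map = region_map or RegionMap.imgt()
    out: Dict[str, list] = {name: [] for name in region_map.spans}
    for p, a in seq.residues:
        name = region_map.region_of(p)
        if name is not None:
            out[name].append((p, a))
    return out


def hallmark_check(seq: NumberedSequence,
                   region_map: Optional[RegionMap] = None) -> HallmarkReport:
    """Classify the FR2 tetrad, position 11, and locate all cysteines."""
    region_map = region_map or RegionMap.imgt()
    hallmarks = {}
    for pos, (vhh_set, vh_aa) in HALLMARK_RULES.items():
        aa = seq.at(pos)
        if aa is None:
            cls = "absent"
        elif aa in vhh_set:
            cls = "VHH-like"
        elif aa == vh_aa:
            cls = "VH-like"
        else:
            cls = "other"
        hallmarks[pos] = (aa, cls)
    aa11 = seq.at(11)
    pos11 = (aa11, "absent" if aa11 is None else
             ("VHH-like" if aa11 == "S" else
              "VH-like" if aa11 == "L" else "other"))
    cys_positions = [p for p, a in seq.residues if a == "C"]
    extra = [(p, region_map.region_of(p)) for p in cys_positions
             if p not in (23, 104)]
    return HallmarkReport(
        sequence_id=seq.id, hallmarks=hallmarks, position11=pos11,
        cys23=23 in cys_positions, cys104=104 in cys_positions,
        extra_cys=extra)


def pairwise_identity(aln_a: str, aln_b: str,
                      columns: Optional[Sequence[int]] = None) -> float:
    """Percent identity over compared columns of two aligned rows.

    Columns gapped in both rows are excluded; gap-vs-residue counts as a
    mismatch. ``columns`` optionally restricts to a region's column set.
    Returns NaN when no column is comparable.
    """
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences differ in length")
    idx = range(len(aln_a)) if columns is None else columns
    compared = matches = 0
    for i in idx:
        a, b = aln_a[i], aln_b[i]
        if a == "-" and b == "-":
            continue
        compared += 1
        if a == b:
            matches += 1
    if compared == 0:
        return float("nan")
    return 100.0 * matches / compared


def identity_matrix(rows: Sequence[str],
                    columns: Optional[Sequence[int]] = None) -> np.ndarray:
    n = len(rows)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_identity(rows[i], rows[j],
                                                      columns)
    return out


def redundancy_filter(aln: Sequence[str], threshold: float,
                      ids: Optional[Sequence[str]] = None):
    """Greedy input-order clustering at an identity threshold (%).

    A sequence joins the first representative it exceeds the threshold
    with; otherwise it becomes a new representative. Returns the indices
    of representatives in input order (or their ids when given).
    """
    if not 0 < threshold <= 101:
        raise ValueError("threshold must be a percentage in (0, 101]")
    reps: List[int] = []
    for i, seq in enumerate(aln):
        for r in reps:
            if pairwise_identity(seq, aln[r]) > threshold:
                break
        else:
            reps.append(i)
    if ids is not None:
        return [ids[i] for i in reps]
    return reps


def length_statistics(seqs: Sequence[NumberedSequence],
                      region_map: Optional[RegionMap] = None):
    """Per-region and overall (min, median, max) of ungapped lengths."""
    if not seqs:
        raise ValueError("empty sequence set")
    region_map = region_map or RegionMap.imgt()
    summary = {}
    per_region = {name: [] for name in region_map.spans}
    totals = []
    for seq in seqs:
        by_region = residues_by_region(seq, region_map)
        for name, res in by_region.items():
            per_region[name].append(len(res))
        totals.append(len(seq.residues))
    for name, counts in per_region.items():
        summary[name] = (int(np.min(counts)), float(np.median(counts)),
                         int(np.max(counts)))
    summary["domain"] = (int(np.min(totals)), float(np.median(totals)),
                         int(np.max(totals)))
    return summary


def sse_profile(assignments: Sequence[str],
                column_map: Optional[Sequence[Sequence[int]]] = None
                ) -> SSEProfile:
    """Per-column frequencies of the 8 DSSP classes over aligned strings.

    Gap characters ('-' only when the string is an alignment row whose gaps
    are marked '.') — here '.' denotes a gap; '-' is the DSSP coil class.
    """
    if not assignments:
        raise ValueError("empty assignment set")
    if column_map is None:
        lengths = {len(s) for s in assignments}
        if len(lengths) != 1:
            raise ValueError("unequal lengths require a column_map")
        column_map = [range(len(assignments[0]))] * len(assignments)
    npos = 1 + max(max(cols) for cols in column_map)
    counts = np.zeros((npos, len(DSSP_CLASSES)))
    for s, cols in zip(assignments, column_map):
        for sym, pos in zip(s, cols):
            if sym == ".":
                continue
            if sym not in DSSP_CLASSES:
                raise ValueError(f"invalid DSSP class symbol {sym!r}")
            counts[pos, DSSP_CLASSES.index(sym)] += 1
    support = counts.sum(axis=1)
    freq = np.zeros_like(counts)
    nz = support > 0
    freq[nz] = counts[nz] / support[nz, None]
    return SSEProfile(freq=freq, support=support.astype(int))


def number_sequence_heuristic(seq_id: str, raw: str) -> NumberedSequence:
    """Anchor-based IMGT-like numbering (HEURISTIC, not IMGT software).

    Anchors the first cysteine to position 23, the second conserved
    cysteine to 104, and the tryptophan after it... positions between
    anchors are numbered by linear spacing; use a real numbering tool for
    production work.
    """
    cys = [i for i, a in enumerate(raw) if a == "C"]
    if len(cys) < 2:
        raise ValueError("need at least two cysteines for anchor numbering")
    c1, c2 = cys[0], cys[-1]
    residues = []
    # before/after the anchor block: count outward from the anchors
    for i, a in enumerate(raw):
        if i <= c1:
            pos = 23 - (c1 - i)
        elif i >= c2:
            pos = 104 + (i - c2)
        else:
            frac = (i - c1) / (c2 - c1)
            pos = 23 + round(frac * (104 - 23))
        residues.append((pos, a))
    # deduplicate collapsed interior positions by shifting forward
    seen, fixed = set(), []
    for pos, a in residues:
        while pos in seen:
            pos += 1
        seen.add(pos)
        fixed.append((pos, a))
    fixed.sort(key=lambda t: t[0])
    return NumberedSequence(id=seq_id, residues=fixed, scheme="IMGT-heuristic")
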