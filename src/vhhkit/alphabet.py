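"""Protein Block assignment and entropy statistics.

The Protein Block (PB) structural alphabet describes local backbone
conformation with 16 five-residue prototypes labelled ``a``-``p``, each
defined by 8 reference dihedrals (ψ(i-2), φ(i-1), ψ(i-1), φ(i), ψ(i),
φ(i+1), ψ(i+1), φ(i+2)). A residue is assigned the prototype with the
smallest angular RMSD (RMSDA) over its 8-angle window; residues without a
complete window (the two first/last residues, and anything within two
positions of a chain break) carry the undefined label ``Z``.

On top of the assignment sit the position-wise statistics used to compare
sets of structures: the PB frequency matrix, the equivalent number of PBs

    Neq = exp(-Σ_x f_x ln f_x)        (1 = single PB, 16 = uniform),

the L1 divergence between two frequency vectors

    ΔPB = Σ_x |f1_x - f2_x|           (0 = identical, 2 = disjoint),

and ΔNeq = |Neq1 - Neq2|.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import DihedralSeries

PB_LABELS = "abcdefghijklmnop"
UNDEFINED = "Z"

# 16 reference prototypes, 8 dihedrals each, transcribed from the PB
# definition publication (de Brevern, Etchebest & Hazout 2000, Proteins
# 41:271-287); identical to the table distributed with PBxplore.
# Column order: psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1),
# psi(i+1), phi(i+2).
PB_REFERENCE_ANGLES = {
    "a": [41.14, 75.53, 13.92, -99.80, 131.88, -96.27, 122.08, -99.68],
    "b": [108.24, -90.12, 119.54, -92.21, -18.06, -128.93, 147.04, -99.90],
    "c": [-11.61, -105.66, 94.81, -106.09, 133.56, -106.93, 135.97, -100.63],
    "d": [141.98, -112.79, 132.20, -114.79, 140.11, -111.05, 139.54, -103.16],
    "e": [133.25, -112.37, 137.64, -108.13, 133.00, -87.30, 120.54, 77.40],
    "f": [116.40, -105.53, 129.32, -96.68, 140.72, -74.19, -26.65, -94.51],
    "g": [0.40, -81.83, 4.91, -100.59, 85.50, -71.65, 130.78, 84.98],
    "h": [119.14, -102.58, 130.83, -67.91, 121.55, 76.25, -2.95, -90.88],
    "i": [130.68, -56.92, 119.26, 77.85, 10.42, -99.43, 141.40, -98.01],
    "j": [114.32, -121.47, 118.14, 82.88, -150.05, -83.81, 23.35, -85.82],
    "k": [117.16, -95.41, 140.40, -59.35, -29.23, -72.39, -25.08, -76.16],
    "l": [139.20, -55.96, -32.70, -68.51, -26.09, -74.44, -22.60, -71.74],
    "m": [-39.62, -64.73, -39.52, -65.54, -38.88, -66.89, -37.76, -70.19],
    "n": [-35.34, -65.03, -38.12, -66.34, -29.51, -89.10, -2.91, 77.90],
    "o": [-45.29, -67.44, -27.72, -87.27, 5.13, 77.49, 30.71, -93.23],
    "p": [-27.09, -86.14, 0.30, 59.85, 21.51, -96.30, 132.67, -92.91],
}

_PROTO = np.array([PB_REFERENCE_ANGLES[x] for x in PB_LABELS])  # (16, 8)

# sha256 of the canonical serialisation below; pins the reference table.
PB_TABLE_SHA256 = (
    "77bf632054183f77634e5eb2fa87147c2e1e6317984285402f690a80ba312d21"
)


def table_checksum() -> str:
    """Canonical sha256 of the prototype table (label:8 angles at 2 dp)."""
    text = "\n".join(
        f"{x}:" + ",".join(f"{v:.2f}" for v in PB_REFERENCE_ANGLES[x])
        for x in PB_LABELS
    )
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class PBFrequencyMatrix:
    """Per-position PB probability vectors over a set of sequences."""

    positions: np.ndarray          # ordered position keys
    freq: np.ndarray               # (n_positions, 16); rows sum to 1 or 0
    support: np.ndarray            # non-Z observation count per position


@dataclass
class ComparisonProfile:
    """Position-wise ΔPB / ΔNeq between two sets; NaN where undefined."""

    positions: np.ndarray
    delta_pb: np.ndarray
    delta_neq: np.ndarray


def _windows(dihedrals: DihedralSeries) -> np.ndarray:
    """(n, 8) matrix of assignment windows; NaN marks undefined entries."""
    phi, psi = dihedrals.phi, dihedrals.psi
    n = len(phi)
    win = np.full((n, 8), np.nan)
    for i in range(2, n - 2):
        win[i] = [psi[i - 2], phi[i - 1], psi[i - 1], phi[i],
                  psi[i], phi[i + 1], psi[i + 1], phi[i + 2]]
    return win


def _rmsda(window: np.ndarray) -> np.ndarray:
    """Angular RMSD of one 8-angle window against the 16 prototypes."""
    diff = (window[None, :] - _PROTO + 180.0) % 360.0 - 180.0
    return np.sqrt(np.mean(diff ** 2, axis=1))


def assign_pbs(dihedrals: DihedralSeries) -> str:
    """Assign one PB letter per residue; ``Z`` where the window is incomplete.

    Ties in the nearest-prototype search resolve to the alphabetically
    first label (argmin over the alphabet-ordered prototype matrix).
    """
    n = len(dihedrals)
    if n < 5:
        import warnings
        warnings.warn("chain shorter than 5 residues: all-Z PB sequence")
        return UNDEFINED * n
    win = _windows(dihedrals)
    labels = []
    for i in range(n):
        if np.any(np.isnan(win[i])):
            labels.append(UNDEFINED)
        else:
            labels.append(PB_LABELS[int(np.argmin(_rmsda(win[i])))])
    return "".join(labels)


def pb_frequencies(pb_sequences: Sequence[str],
                   column_map: Optional[Sequence[Sequence[int]]] = None,
                   n_positions: Optional[int] = None) -> PBFrequencyMatrix:
    """Per-position PB frequency vectors over a set of PB sequences.

    ``column_map[k][i]`` maps residue i of sequence k to a common position
    (identity when omitted; all sequences must then share one length).
    ``Z`` never contributes: positions seen only as Z have support 0 and an
    all-zero frequency row.
    """
    if not pb_sequences:
        raise ValueError("empty PB sequence set")
    if column_map is None:
        lengths = {len(s) for s in pb_sequences}
        if len(lengths) != 1:
            raise ValueError(
                "sequences of unequal length need an explicit column_map")
        column_map = [range(len(pb_sequences[0]))] * len(pb_sequences)
    if len(column_map) != len(pb_sequences):
        raise ValueError("column_map length does not match sequence count")

    npos = n_positions
    if npos is None:
        npos = 1 + max(max(cols) for cols in column_map)
    counts = np.zeros((npos, 16))
    for seq, cols in zip(pb_sequences, column_map):
        cols = list(cols)
        if len(cols) != len(seq):
            raise ValueError("column_map entry does not match its sequence")
        for sym, pos in zip(seq, cols):
            if sym == UNDEFINED or sym == "-":
                continue
            counts[pos, PB_LABELS.index(sym)] += 1
    support = counts.sum(axis=1)
    freq = np.zeros_like(counts)
    nz = support > 0
    freq[nz] = counts[nz] / support[nz, None]
    return PBFrequencyMatrix(positions=np.arange(npos), freq=freq,
                             support=support.astype(int))


def _check_normalised(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (16,):
        raise ValueError("PB frequency vector must have 16 components")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("PB frequency vector is not normalised")
    return f


def neq(freq) -> float:
    """Equivalent number of PBs: exp of the Shannon entropy (natural log)."""
    f = _check_normalised(freq)
    nz = f > 0
    return float(np.exp(-np.sum(f[nz] * np.log(f[nz]))))


def delta_pb(freq1, freq2) -> float:
    """L1 divergence between two PB frequency vectors, in [0, 2]."""
    f1, f2 = _check_normalised(freq1), _check_normalised(freq2)
    return float(np.abs(f1 - f2).sum())


def delta_neq(neq1: float, neq2: float) -> float:
    """Absolute difference of two Neq values, in [0, 15]."""
    return abs(float(neq1) - float(neq2))


def neq_profile(matrix: PBFrequencyMatrix) -> np.ndarray:
    """Per-position Neq; NaN where a position has no observations."""
    out = np.full(len(matrix.positions), np.nan)
    for i in range(len(out)):
        if matrix.support[i] > 0:
            out[i] = neq(matrix.freq[i])
    return out


def profile_comparison(set_a: Sequence[str], set_b: Sequence[str],
                       column_map_a=None, column_map_b=None,
                       n_positions: Optional[int] = None) -> ComparisonProfile:
    """Position-wise ΔPB and ΔNeq between two sets of PB sequences."""
    if not set_a or not set_b:
        raise ValueError("both PB sequence sets must be non-empty")
    fa = pb_frequencies(set_a, column_map_a, n_positions=n_positions)
    fb = pb_frequencies(set_b, column_map_b,
                        n_positions=len(fa.positions))
    npos = max(len(fa.positions), len(fb.positions))
    if len(fa.positions) != len(fb.positions):
        fa = pb_frequencies(set_a, column_map_a, n_positions=npos)
        fb = pb_frequencies(set_b, column_map_b, n_positions=npos)
    dpb = np.full(npos, np.nan)
    dneq = np.full(npos, np.nan)
    for i in range(npos):
        if fa.support[i] > 0 and fb.support[i] > 0:
            dpb[i] = delta_pb(fa.freq[i], fb.freq[i])
            dneq[i] = delta_neq(neq(fa.freq[i]), neq(fb.freq[i]))
    return ComparisonProfile(positions=np.arange(npos),
                             delta_pb=dpb, delta_neq=dneq)


# -- serialisation ---------------------------------------------------------

def pb_fasta(records) -> str:
    """Serialise (id, pb_string) pairs as FASTA-like text."""
    return "".join(f">{name}\n{seq}\n" for name, seq in records)


def read_pb_fasta(text: str):
    """Parse FASTA-like PB text back to (id, pb_string) pairs."""
    records, name, chunks = [], None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:].strip(), []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def frequency_table(matrix: PBFrequencyMatrix):
    """Frequency matrix + support + Neq as a pandas DataFrame."""
    import pandas as pd

    df = pd.DataFrame(matrix.freq, columns=[f"f_{x}" for x in PB_LABELS])
    df.insert(0, "position", matrix.positions)
    df["support"] = matrix.support
    df["neq"] = neq_profile(matrix)
    return df
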