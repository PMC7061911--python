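"""Conformational diversity of model ensembles of one sequence.

Given a set of structural models (e.g., 100 comparative models from one
modelling scenario), each model's backbone is reduced to its Protein Block
string; per residue position the PB distribution over models gives an
Neq profile (1 = every model agrees locally, larger = conformational
spread). Profiles are binned Table-style ([1,2), [2,3), ... [6,7)),
positions with Neq above 1 + tolerance count as conformationally diverse,
and two scenarios are compared position-wise by ΔPB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import alphabet
from .regions import RegionMap
from .structure_io import BackboneChain, compute_dihedrals

#: Floating-point slack above 1 below which a position counts as rigid;
#: the entropy of a one-PB distribution is only 1 up to rounding.
NEQ_TOLERANCE = 1e-9

NEQ_BIN_EDGES = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)


@dataclass
class ModelEnsemble:
    """Models of one sequence plus their PB strings."""

    label: str
    models: List[BackboneChain]
    pb_sequences: List[str]

    @classmethod
    def from_chains(cls, label: str,
                    models: Sequence[BackboneChain]) -> "ModelEnsemble":
        if not models:
            raise ValueError("ensemble needs at least one model")
        n = len(models[0])
        names = models[0].sequence3()
        for m in models[1:]:
            if len(m) != n or m.sequence3() != names:
                raise ValueError(
                    "all models must share one residue sequence")
        pbs = [alphabet.assign_pbs(compute_dihedrals(m)) for m in models]
        return cls(label=label, models=list(models), pb_sequences=pbs)

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class NeqBinSummary:
    counts: Dict[str, int]        # "[1,2)" -> count, half-open bins
    n_diverse: int                # positions with Neq > 1 + tolerance
    n_defined: int


def ensemble_neq(ensemble: ModelEnsemble) -> np.ndarray:
    """Per-position Neq over the ensemble's PB strings (NaN: no support)."""
    if len(ensemble) < 2:
        warnings.warn("single-model ensemble: Neq profile is trivially 1")
    freq = alphabet.pb_frequencies(ensemble.pb_sequences)
    return alphabet.neq_profile(freq)


def neq_bins(profile: np.ndarray,
             tolerance: float = NEQ_TOLERANCE) -> NeqBinSummary:
    """Bin an Neq profile Table-style.

    Positions within ``tolerance`` of 1 are rigid and excluded from the
    bins; the rest are counted into half-open bins [1,2), [2,3), ... and
    summed as the diverse-position count.
    """
    vals = np.asarray(profile, float)
    defined = vals[~np.isnan(vals)]
    diverse = defined[defined > 1.0 + tolerance]
    counts = {}
    for lo, hi in zip(NEQ_BIN_EDGES[:-1], NEQ_BIN_EDGES[1:]):
        counts[f"[{lo:g},{hi:g})"] = int(
            np.sum((diverse >= lo) & (diverse < hi)))
    return NeqBinSummary(counts=counts, n_diverse=int(diverse.size),
                         n_defined=int(defined.size))


def scenario_delta_pb(ensemble_a: ModelEnsemble,
                      ensemble_b: ModelEnsemble) -> alphabet.ComparisonProfile:
    """Position-wise ΔPB (and ΔNeq) between two modelling scenarios."""
    seq_a = ensemble_a.models[0].sequence3()
    seq_b = ensemble_b.models[0].sequence3()
    if seq_a != seq_b:
        raise ValueError("scenarios model different sequences")
    return alphabet.profile_comparison(ensemble_a.pb_sequences,
                                       ensemble_b.pb_sequences)


def anchor_variability(ensemble: ModelEnsemble, regions: RegionMap,
                       flank: int = 3) -> Dict[str, list]:
    """Neq at CDR anchor positions (the ``flank`` residues on each side).

    Returns, per CDR, a list of (residue index, side, neq, diverse_flag);
    anchors truncated by a chain terminus are flagged with side suffix
    '(truncated)'.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    profile = ensemble_neq(ensemble)
    numbers = [r.number for r in ensemble.models[0].residues]
    n = len(numbers)
    report: Dict[str, list] = {}
    for cdr in ("CDR1", "CDR2", "CDR3"):
        lo, hi = regions.span(cdr)
        inside = [i for i, num in enumerate(numbers) if lo <= num < hi]
        entries = []
        if inside and flank > 0:
            first, last = inside[0], inside[-1]
            for k in range(1, flank + 1):
                for idx, side in ((first - k, "preceding"),
                                  (last + k, "succeeding")):
                    if 0 <= idx < n:
                        val = profile[idx]
                        entries.append((idx, side, float(val),
                                        bool(val > 1.0 + NEQ_TOLERANCE)))
                    else:
                        entries.append((idx, side + " (truncated)",
                                        float("nan"), False))
        report[cdr] = sorted(entries)
    return report
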