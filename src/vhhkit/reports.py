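"""Pipeline report bundles: sequence, structure, and ensemble analyses.

Each ``run_*_report`` function ties the core modules into one reproducible
run: inputs are named in a config, every number in the output TSVs is
delegated to a core-module operation, and the bundle embeds the resolved
config plus a content hash of the inputs so identical inputs give
byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import alphabet, disulfide, ensemble, regions, structure_io, superpose

logger = logging.getLogger("vhhkit")


@dataclass
class PipelineConfig:
    output_dir: str = "vhhkit_report"
    alignment_fasta: Optional[str] = None      # aligned FASTA (sequence report)
    column_positions: Optional[str] = None     # TSV: column -> scheme position
    structures: List[str] = field(default_factory=list)   # PDB paths
    ensembles: Dict[str, str] = field(default_factory=dict)  # scenario -> dir
    reference_model: Optional[str] = None
    chain: Optional[str] = None
    redundancy_threshold: float = 95.0
    ss_distance: float = disulfide.SS_DISTANCE_THRESHOLD
    neq_tolerance: float = ensemble.NEQ_TOLERANCE
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _hash_files(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(p.encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _write_bundle_meta(outdir: Path, config: PipelineConfig,
                       input_paths, counts: dict) -> None:
    meta = {
        "config": asdict(config),
        "input_hash": _hash_files(input_paths),
        "counts": counts,
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2,
                                                     sort_keys=True) + "\n")


def _read_alignment(path):
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FileNotFoundError(f"no sequences in {path}")
    return records


def _column_positions(path, width: int):
    if path is None:
        return list(range(1, width + 1))
    df = pd.read_csv(path, sep="\t")
    return df["position"].tolist()


def run_sequence_report(config: PipelineConfig) -> Path:
    """Identity distributions, length stats, hallmark census, dedup list."""
    if config.alignment_fasta is None:
        raise FileNotFoundError("sequence report needs alignment_fasta")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _read_alignment(config.alignment_fasta)
    ids = [r[0] for r in records]
    rows = [r[1] for r in records]
    width = len(rows[0])
    positions = _column_positions(config.column_positions, width)
    region_map = regions.RegionMap.imgt()
    logger.info("sequence report: %d sequences, %d columns", len(rows), width)

    numbered = [regions.NumberedSequence.from_aligned(i, s, positions)
                for i, s in zip(ids, rows)]

    # per-region identity distributions with medians
    col_by_region = {
        name: [i for i, p in enumerate(positions)
               if region_map.region_of(p) == name]
        for name in regions.REGION_ORDER}
    id_rows = []
    for name in ("domain",) + regions.REGION_ORDER:
        cols = None if name == "domain" else col_by_region[name]
        if cols is not None and not cols:
            continue
        mat = regions.identity_matrix(rows, cols)
        iu = np.triu_indices(len(rows), 1)
        vals = mat[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            id_rows.append({"region": name, "n_pairs": int(vals.size),
                            "median": float(np.median(vals)),
                            "min": float(vals.min()),
                            "max": float(vals.max())})
    pd.DataFrame(id_rows, columns=["region", "n_pairs", "median",
                                   "min", "max"]).to_csv(
        outdir / "identity_summary.tsv", sep="\t", index=False)

    # length summary
    stats = regions.length_statistics(numbered, region_map)
    pd.DataFrame(
        [{"region": k, "min": v[0], "median": v[1], "max": v[2]}
         for k, v in stats.items()]
    ).to_csv(outdir / "length_summary.tsv", sep="\t", index=False)

    # hallmark census
    census = []
    for seq in numbered:
        rep = regions.hallmark_check(seq, region_map)
        row = {"id": seq.id, "tetrad_class": rep.tetrad_class,
               "cys23": rep.cys23, "cys104": rep.cys104,
               "n_extra_cys": len(rep.extra_cys),
               "extra_cys": ";".join(
                   f"{p}:{r}" for p, r in rep.extra_cys)}
        for pos, (aa, cls) in sorted(rep.hallmarks.items()):
            row[f"aa{pos}"] = aa or "-"
            row[f"class{pos}"] = cls
        row["aa11"], row["class11"] = rep.position11
        census.append(row)
    pd.DataFrame(census).to_csv(outdir / "hallmark_census.tsv",
                                sep="\t", index=False)

    reps = regions.redundancy_filter(rows, config.redundancy_threshold,
                                     ids=ids)
    logger.info("redundancy filter at >%s%%: %d -> %d sequences",
                config.redundancy_threshold, len(rows), len(reps))
    pd.DataFrame({"representative": reps}).to_csv(
        outdir / "representatives.tsv", sep="\t", index=False)

    _write_bundle_meta(outdir, config, [config.alignment_fasta],
                       {"sequences": len(rows),
                        "representatives": len(reps)})
    return outdir


def run_structure_report(config: PipelineConfig) -> Path:
    """RMSD matrix, PB maps/Neq, disulfide table over a structure set."""
    if not config.structures:
        raise FileNotFoundError("structure report needs a structure manifest")
    missing = [p for p in config.structures if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing structure files: {missing}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    region_map = regions.RegionMap.imgt()

    chains, names = [], []
    for path in config.structures:
        parsed = structure_io.read_structure(path, config.chain)
        chains.append(parsed[0])
        names.append(Path(path).stem)
    logger.info("structure report: %d structures", len(chains))

    # pairwise RMSD over shared residue counts (equal-length sets expected)
    n = len(chains)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(chains[i]) != len(chains[j]):
                rmsd[i, j] = rmsd[j, i] = np.nan
                continue
            res = superpose.superpose(chains[i], chains[j])
            rmsd[i, j] = rmsd[j, i] = res.rmsd_global
    pd.DataFrame(rmsd, index=names, columns=names).to_csv(
        outdir / "rmsd_matrix.tsv", sep="\t")

    # PB map + Neq profile
    pbs = [alphabet.assign_pbs(structure_io.compute_dihedrals(c))
           for c in chains]
    same_length = len({len(p) for p in pbs}) == 1
    if same_length:
        freq = alphabet.pb_frequencies(pbs)
        alphabet.frequency_table(freq).to_csv(
            outdir / "pb_map.tsv", sep="\t", index=False)
    alphabet_path = outdir / "pb_sequences.fasta"
    alphabet_path.write_text(alphabet.pb_fasta(zip(names, pbs)))

    # disulfides
    tables = []
    n_bridges = 0
    for name, chain in zip(names, chains):
        bridges = disulfide.detect_bridges(chain, config.ss_distance)
        n_bridges += len(bridges)
        if bridges:
            tab = disulfide.bridge_table(bridges, region_map)
            tab.insert(0, "structure", name)
            tables.append(tab)
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(
            outdir / "disulfides.tsv", sep="\t", index=False)
    else:
        (outdir / "disulfides.tsv").write_text(
            "structure\tcysA\tcysB\tdistance\tpattern\ttopology\n")
    logger.info("found %d disulfide bridge(s)", n_bridges)

    _write_bundle_meta(outdir, config, config.structures,
                       {"structures": n, "bridges": n_bridges})
    return outdir


def _load_scenario(label: str, directory, chain_selector) -> ensemble.ModelEnsemble:
    paths = sorted(Path(directory).glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"scenario {label}: no PDB files in {directory}")
    models = [structure_io.read_structure(p, chain_selector)[0]
              for p in paths]
    return ensemble.ModelEnsemble.from_chains(label, models)


def run_ensemble_report(config: PipelineConfig) -> Path:
    """Per-scenario Neq profiles/bins, scenario ΔPB, deviation profiles."""
    if not config.ensembles:
        raise FileNotFoundError("ensemble report needs scenario directories")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    scenarios = {label: _load_scenario(label, d, config.chain)
                 for label, d in sorted(config.ensembles.items())}
    logger.info("ensemble report: %d scenario(s)", len(scenarios))

    profiles, bin_rows = {}, []
    for label, ens in scenarios.items():
        prof = ensemble.ensemble_neq(ens)
        profiles[label] = prof
        summary = ensemble.neq_bins(prof, config.neq_tolerance)
        row = {"scenario": label, "n_models": len(ens),
               "n_diverse": summary.n_diverse}
        row.update(summary.counts)
        bin_rows.append(row)
    pd.DataFrame(profiles).to_csv(outdir / "neq_profiles.tsv", sep="\t",
                                  index_label="position")
    pd.DataFrame(bin_rows).to_csv(outdir / "neq_bins.tsv", sep="\t",
                                  index=False)

    labels = list(scenarios)
    dpb_rows = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            comp = ensemble.scenario_delta_pb(scenarios[la], scenarios[lb])
            dpb_rows[f"{la}|{lb}"] = comp.delta_pb
    if dpb_rows:
        pd.DataFrame(dpb_rows).to_csv(outdir / "delta_pb.tsv", sep="\t",
                                      index_label="position")

    if config.reference_model:
        ref = structure_io.read_structure(config.reference_model,
                                          config.chain)[0]
        dev = {}
        for label, ens in scenarios.items():
            dev[label] = superpose.residuewise_deviation(ref, ens.models[0])
        pd.DataFrame(dev).to_csv(outdir / "residuewise_rmsd.tsv", sep="\t",
                                 index_label="position")

    input_paths = [p for d in config.ensembles.values()
                   for p in sorted(Path(d).glob("*.pdb"))]
    if config.reference_model:
        input_paths.append(config.reference_model)
    _write_bundle_meta(outdir, config, input_paths,
                       {"scenarios": len(scenarios),
                        "models": sum(len(e) for e in scenarios.values())})
    return outdir
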