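"""Pipeline orchestration: run the evaluation stages in dependency order
over a YAML config and aggregate a per-SAG summary report.

Contaminant exclusion always precedes the reference-facing metrics, so
GC, recovery, and ANI are computed on the cleaned scaffold set — unless
the screening stage is explicitly disabled, in which case the summary
flags that recovery ran on all scaffolds.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import ani as ani_mod
from . import contam, markers as markers_mod, recovery
from .intervals import IntervalSet
from .io import (
    GeneAnnotation,
    SequenceSet,
    read_alignments,
    read_annotation,
    read_fasta,
    write_fasta,
    write_report,
)
from .sequtil import gc_fraction
from .simulate import SimConfig, simulate_scenario


@dataclass
class AssemblyStats:
    total_length: int
    n_scaffolds: int
    n50: int
    l75: int
    gc_pct: float


def assembly_stats(scaffolds: SequenceSet, min_len: int = 500) -> AssemblyStats:
    """Total length, scaffold count, N50, L75 and GC of scaffolds >= min_len.

    N50 is the length of the scaffold at which the cumulative
    sorted-descending length first exceeds half the total; L75 is the
    number of scaffolds needed to reach 75 % of the total.
    """
    lengths = sorted(
        (scaffolds.length(s) for s in scaffolds if scaffolds.length(s) >= min_len),
        reverse=True,
    )
    if not lengths:
        raise ValueError(f"no scaffolds of length >= {min_len}")
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for ln in lengths:
        cum += ln
        if cum > total / 2:
            n50 = ln
            break
    cum = 0
    l75 = len(lengths)
    for i, ln in enumerate(lengths, 1):
        cum += ln
        if cum >= 0.75 * total:
            l75 = i
            break
    gc_bases = acgt = 0
    for sid in scaffolds:
        seq = scaffolds[sid]
        if len(seq) < min_len:
            continue
        gc_bases += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    gc_pct = 100.0 * gc_bases / acgt if acgt else 0.0
    return AssemblyStats(total, len(lengths), n50, l75, gc_pct)


@dataclass
class RunConfig:
    """Everything one evaluation run needs: paths, thresholds, toggles, seed."""

    # inputs (unused paths may stay None; simulate mode generates them)
    reference_fasta: str | None = None
    annotation_path: str | None = None
    annotation_dialect: str = "gff3"
    assembly_fasta: str | None = None
    alignments_path: str | None = None
    alignments_dialect: str = "tab12"
    taxonomy_tsv: str | None = None
    marker_dir: str | None = None
    # stage toggles
    simulate: bool = False
    screen_contamination: bool = True
    run_recovery: bool = True
    run_ani: bool = True
    run_markers: bool = False
    # thresholds
    min_scaffold: int = 500
    gene_thresholds: tuple[float, ...] = (0.9, 0.5, 0.2)
    ani_min_identity: float = 70.0
    ani_max_evalue: float = 1e-5
    tnf_min_scaffold: int = 10_000
    tnf_window: int = 5_000
    otu_threshold: float = 0.97
    saturation_threshold: float = 0.05
    marker_min_score: float = 60.0
    host_taxon: str = "host"
    inversion_min_block: int = 1_000
    seed: int = 0
    # simulate-mode parameters (forwarded to SimConfig)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.gene_thresholds = tuple(cfg.gene_thresholds)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gene_thresholds"] = list(self.gene_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = asdict(self)
        data["gene_thresholds"] = list(self.gene_thresholds)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj: Any, ndigits: int = 4) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the enabled stages in dependency order and write a report bundle.

    Returns the combined summary (also written to ``summary.json``); every
    output carries the config hash and seed, and reruns with the same
    config and inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    taxonomy = None
    # --- input acquisition -------------------------------------------------
    if config.simulate:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        scenario = simulate_scenario(sim_cfg)
        reference, annotation = scenario.reference, scenario.annotation
        scaffolds = scenario.scaffolds
        taxonomy = scenario.taxonomy
        alignments = None  # computed below with the internal aligner
        write_fasta(reference, outdir / "reference.fasta")
        write_fasta(scaffolds, outdir / "scaffolds.fasta")
        summary["stages"]["simulate"] = {
            "genome_length": sim_cfg.genome_length,
            "n_reads": len(scenario.reads),
            "n_scaffolds": len(scaffolds),
        }
    else:
        def need(path, stage):
            if path is None:
                raise ValueError(f"stage {stage!r} enabled but no input path configured")
            p = Path(path)
            if not p.exists():
                raise ValueError(f"stage {stage!r}: missing input {p}")
            return p

        reference = read_fasta(need(config.reference_fasta, "recover"))
        annotation = (
            read_annotation(need(config.annotation_path, "recover"), config.annotation_dialect)
            if config.annotation_path
            else None
        )
        scaffolds = read_fasta(need(config.assembly_fasta, "recover"))
        alignments = (
            read_alignments(config.alignments_path, config.alignments_dialect)
            if config.alignments_path
            else None
        )
        if config.taxonomy_tsv:
            taxonomy = contam._load_taxonomy(need(config.taxonomy_tsv, "screen"))

    # --- assembly statistics ----------------------------------------------
    stats = assembly_stats(scaffolds, min_len=config.min_scaffold)
    summary["stages"]["assembly_stats"] = {
        "total_length": stats.total_length,
        "n_scaffolds": stats.n_scaffolds,
        "n50": stats.n50,
        "l75": stats.l75,
        "gc_pct": stats.gc_pct,
    }

    # --- contamination screen ---------------------------------------------
    host_scaffolds = scaffolds
    if config.screen_contamination and taxonomy is not None:
        tnf = contam.tnf_profile(
            scaffolds, min_scaffold=config.tnf_min_scaffold, window=config.tnf_window
        )
        clustering = contam.cluster_tnf(tnf, seed=config.seed)
        verdicts = contam.classify_scaffolds(
            scaffolds, taxonomy, clustering, host_rule=config.host_taxon
        )
        gc = contam.gc_screen(scaffolds, verdicts, window=config.tnf_window)
        host_ids = [s for s in scaffolds if verdicts[s].label != "contaminant"]
        host_scaffolds = scaffolds.subset(host_ids)
        verdict_df = pd.DataFrame(
            [
                {"scaffold_id": s, "label": verdicts[s].label,
                 "evidence": ",".join(sorted(verdicts[s].evidence))}
                for s in sorted(scaffolds.ids())
            ]
        )
        write_report(verdict_df, outdir / "scaffold_verdicts.tsv")
        summary["stages"]["contamination"] = {
            "n_contaminant": sum(1 for s in scaffolds if verdicts[s].label == "contaminant"),
            "n_host": sum(1 for s in scaffolds if verdicts[s].label == "host"),
            "n_unknown": sum(1 for s in scaffolds if verdicts[s].label == "unknown"),
            "tnf_clusters": clustering.k,
            "gc_all": gc.gc_all,
            "gc_after_removal": gc.gc_host_only,
            "gc_bimodal_after_removal": gc.bimodal,
        }
    elif not config.screen_contamination:
        summary["stages"]["contamination"] = {"skipped": True, "recovery_on_all_scaffolds": True}

    # --- recovery and ANI ---------------------------------------------------
    if config.run_recovery or config.run_ani:
        kept = host_scaffolds.subset(
            s for s in host_scaffolds if host_scaffolds.length(s) >= config.min_scaffold
        )
        if alignments is None:
            alignments = ani_mod.chunk_align(kept, reference)
        else:
            alignments = [r for r in alignments if r.query_id in kept]

    if config.run_recovery:
        report = recovery.assembly_vs_reference(
            alignments, host_scaffolds, reference, annotation, min_scaffold=config.min_scaffold
        )
        summary["stages"]["recovery"] = {
            "pct_assembly_aligned": report.pct_assembly_aligned,
            "reference_breadth_pct": report.reference_breadth_pct,
            "genic_share_pct": report.genic_share_pct,
        }
        if annotation is not None:
            fractions, counts = recovery.gene_completeness(
                report.covered_reference, annotation, thresholds=config.gene_thresholds
            )
            summary["stages"]["recovery"]["gene_counts_at"] = {
                str(t): c for t, c in counts.items()
            }
            write_report(
                pd.DataFrame(
                    [{"gene_id": g, "completeness": f} for g, f in sorted(fractions.items())]
                ),
                outdir / "gene_completeness.tsv",
            )
            inv = recovery.detect_inversions(
                alignments, annotation, min_block=config.inversion_min_block
            )
            summary["stages"]["recovery"]["n_inversion_calls"] = len(inv)

    if config.run_ani:
        try:
            ani_res = ani_mod.compute_ani(
                alignments,
                min_identity=config.ani_min_identity,
                max_evalue=config.ani_max_evalue,
            )
            summary["stages"]["ani"] = {
                "ani_query_pct": ani_res.ani_query_pct,
                "ani_target_pct": ani_res.ani_target_pct,
                "headline": ani_res.headline,
                "n_alignments_used": ani_res.n_alignments_used,
            }
        except ValueError as exc:
            summary["stages"]["ani"] = {"error": str(exc)}

    # --- markers -------------------------------------------------------------
    if config.run_markers and config.marker_dir:
        mset = markers_mod.read_marker_set(config.marker_dir)
        hits = markers_mod.search_markers(
            host_scaffolds, mset, min_score=config.marker_min_score
        )
        row = markers_mod.build_supermatrix(hits, mset, taxon_name="sag")
        markers_mod.write_supermatrix_fasta([row], outdir / "supermatrix.fasta")
        summary["stages"]["markers"] = {
            "n_markers": len(mset),
            "n_recovered": row.n_recovered,
            "recovery_pct": row.recovery_pct,
            "ungapped_positions": row.ungapped_positions,
            "total_columns": row.total_columns,
        }

    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
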