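"""Stage 1 — read-mapping summaries and downsampling saturation analysis.

A SAG's read mapping profile separates two very different failure modes:
a low mapped-read percentage points to contamination or chimerism, while
a low breadth at high mapped percentage points to amplification bias
(reads piled on few loci).  The saturation curve (assembly length vs read
subsample size) tells whether further sequencing could still improve the
assembly: a flat curve means it cannot.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .intervals import IntervalSet, breadth, depth_from_alignments, intersect
from .io import AlignmentRecord, GeneAnnotation, SequenceSet

_PAIR_RE = re.compile(r"^(?P<unit>.+)[/_](?P<mate>[12])$")


@dataclass
class MappingSummary:
    n_reads: int
    n_mapped: int
    pct_mapped: float
    breadth_pct: float
    depth_histogram: dict[int, int]
    genic_covered_fraction: float


def mapping_summary(
    read_alignments: Sequence[AlignmentRecord],
    reference: SequenceSet,
    annotation: GeneAnnotation | None,
    n_total_reads: int,
) -> MappingSummary:
    """Summarise read mapping over every reference sequence.

    A read counts as mapped if it has at least one alignment record; the
    depth histogram spans the whole reference (zero-depth positions
    included), and the genic fraction is the share of covered positions
    lying inside merged gene spans.
    """
    for rec in read_alignments:
        if rec.target_id not in reference:
            raise ValueError(f"alignment to unknown reference sequence {rec.target_id!r}")
    mapped_ids = {rec.query_id for rec in read_alignments}
    if n_total_reads < len(mapped_ids):
        raise ValueError("n_total_reads is smaller than the number of distinct mapped reads")

    by_seq: dict[str, list[AlignmentRecord]] = {sid: [] for sid in reference}
    for rec in read_alignments:
        by_seq[rec.target_id].append(rec)

    hist: dict[int, int] = {}
    covered = IntervalSet()
    ref_len = reference.total_length
    for sid in reference:
        prof = depth_from_alignments(by_seq[sid], sid, reference.length(sid))
        for d, c in prof.histogram().items():
            hist[d] = hist.get(d, 0) + c
        cov = prof.covered(1)
        for s, ivals in cov.per_seq.items():
            covered.per_seq.setdefault(s, []).extend(ivals)

    covered = IntervalSet(covered.per_seq)  # renormalise
    cov_len = covered.total_length
    genic_frac = 0.0
    if annotation is not None and cov_len:
        spans = IntervalSet.from_intervals(annotation.gene_spans())
        genic_frac = intersect(covered, spans).total_length / cov_len

    return MappingSummary(
        n_reads=n_total_reads,
        n_mapped=len(mapped_ids),
        pct_mapped=100.0 * len(mapped_ids) / n_total_reads if n_total_reads else 0.0,
        breadth_pct=100.0 * cov_len / ref_len if ref_len else 0.0,
        depth_histogram=dict(sorted(hist.items())),
        genic_covered_fraction=genic_frac,
    )


def downsample_reads(
    reads: SequenceSet,
    fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.8, 1.0),
    seed: int = 0,
    nested: bool = True,
) -> dict[float, SequenceSet]:
    """Random read subsets at the given fractions.

    Reads whose ids end in ``/1``-``/2`` (or ``_1``/``_2``) are kept
    together as pairs and counted as single units.  With ``nested=True``
    the subsets form a chain under inclusion (one shared shuffle).
    """
    if not len(reads):
        raise ValueError("cannot downsample an empty read set")
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fraction must be in (0,1], got {f}")

    units: dict[str, list[str]] = {}
    for rid in reads:
        m = _PAIR_RE.match(rid)
        units.setdefault(m.group("unit") if m else rid, []).append(rid)
    unit_keys = sorted(units)
    rng = np.random.default_rng(seed)
    order = [unit_keys[i] for i in rng.permutation(len(unit_keys))]

    out: dict[float, SequenceSet] = {}
    for f in fractions:
        k = int(round(f * len(unit_keys)))
        if nested:
            chosen = order[:k]
        else:
            idx = rng.choice(len(unit_keys), size=k, replace=False)
            chosen = [unit_keys[i] for i in idx]
        subset = SequenceSet()
        for u in sorted(chosen):
            for rid in units[u]:
                subset.add(rid, reads[rid])
        out[f] = subset
    return out


@dataclass
class SaturationPoint:
    fraction: float
    n_reads: int
    assembly_length: int


@dataclass
class SaturationCurve:
    points: list[SaturationPoint]
    saturated: bool


def saturation_curve(
    subsets: Mapping[float, SequenceSet],
    assembler: Callable[[SequenceSet], SequenceSet],
    min_contig: int = 500,
    saturation_threshold: float = 0.05,
) -> SaturationCurve:
    """Assemble each subset and measure total contig length (>= min_contig).

    The curve is saturated when the relative length gain between the two
    largest fractions falls below ``saturation_threshold`` (default 5 %).
    """
    if len(subsets) < 3:
        raise ValueError("need at least 3 fractions for a saturation curve")
    points = []
    for f in sorted(subsets):
        contigs = assembler(subsets[f])
        length = sum(contigs.length(c) for c in contigs if contigs.length(c) >= min_contig)
        points.append(SaturationPoint(f, len(subsets[f]), length))
    prev, last = points[-2].assembly_length, points[-1].assembly_length
    saturated = prev > 0 and (last - prev) / prev < saturation_threshold
    return SaturationCurve(points, saturated)


def command_assembler(template: str, workdir: str | None = None) -> Callable[[SequenceSet], SequenceSet]:
    """Wrap an external assembler command template into a callable.

    The template receives ``{reads_in}`` (a FASTA of the subset) and
    ``{outdir}``; the assembler must leave its contigs at
    ``{outdir}/contigs.fasta``.  Failures propagate the command's stderr.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    from .io import read_fasta, write_fasta

    def run(reads: SequenceSet) -> SequenceSet:
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            reads_in = Path(tmp) / "reads.fasta"
            outdir = Path(tmp) / "asm"
            outdir.mkdir()
            write_fasta(reads, reads_in)
            cmd = template.format(reads_in=reads_in, outdir=outdir)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"assembler failed ({cmd}): {proc.stderr.strip()}")
            return read_fasta(outdir / "contigs.fasta")

    return run


def truth_assembler(truth, source_genome, min_depth: int = 1):
    """Perfect-assembler closure for saturation curves on simulated reads.

    Restricts the ground-truth placements to the reads present in each
    subset before assembling, so nested subsets yield nested coverage.
    """
    from .simulate import SagSimTruth, perfect_assembler

    def run(reads: SequenceSet) -> SequenceSet:
        sub = SagSimTruth(
            read_origin={r: o for r, o in truth.read_origin.items() if r in reads},
            read_true_interval={r: t for r, t in truth.read_true_interval.items() if r in reads},
            read_strand={r: s for r, s in truth.read_strand.items() if r in reads},
            window_factors=truth.window_factors,
            contaminant_genomes=truth.contaminant_genomes,
        )
        contigs, _ = perfect_assembler(sub, source_genome, min_depth=min_depth)
        return contigs

    return run
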