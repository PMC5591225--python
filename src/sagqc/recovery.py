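"""Stage 3 — scaffold-to-reference recovery metrics.

How much of the assembly aligns to the reference, how much of the
reference it recovers, how that recovery distributes over genes
(completeness at the 90/50/20 % thresholds), whether pooled co-assembly
adds positions beyond the union of individual SAGs, and where strand
discordance marks segmental inversions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .intervals import IntervalSet, intersect, union
from .io import AlignmentRecord, GeneAnnotation, SequenceSet


@dataclass
class RecoveryReport:
    pct_assembly_aligned: float
    reference_breadth_pct: float
    genic_share_pct: float
    covered_reference: IntervalSet
    aligned_assembly: IntervalSet
    gene_completeness: dict[str, float] | None = None
    counts_at: dict[float, int] | None = None


def assembly_vs_reference(
    scaffold_alignments: Sequence[AlignmentRecord],
    assembly: SequenceSet,
    reference: SequenceSet,
    annotation: GeneAnnotation | None = None,
    min_scaffold: int = 500,
) -> RecoveryReport:
    """Recovery metrics from scaffold-to-reference alignments.

    Scaffolds shorter than ``min_scaffold`` are excluded from both the
    numerator and denominator of the assembly-aligned percentage, and
    their alignments are dropped.
    """
    kept = {sid for sid in assembly if assembly.length(sid) >= min_scaffold}
    if not kept:
        raise ValueError(f"no scaffolds of length >= {min_scaffold}")
    records = []
    for rec in scaffold_alignments:
        if rec.query_id not in assembly:
            raise ValueError(f"alignment query {rec.query_id!r} absent from assembly")
        if rec.target_id not in reference:
            raise ValueError(f"alignment target {rec.target_id!r} absent from reference")
        if rec.query_id in kept:
            records.append(rec)

    covered = IntervalSet.from_alignments(records, side="target")
    aligned = IntervalSet.from_alignments(records, side="query")
    assembly_len = sum(assembly.length(sid) for sid in kept)
    ref_len = reference.total_length

    genic_share = 0.0
    if annotation is not None and covered.total_length:
        spans = IntervalSet.from_intervals(annotation.gene_spans())
        genic_share = 100.0 * intersect(covered, spans).total_length / covered.total_length

    return RecoveryReport(
        pct_assembly_aligned=100.0 * aligned.total_length / assembly_len,
        reference_breadth_pct=100.0 * covered.total_length / ref_len if ref_len else 0.0,
        genic_share_pct=genic_share,
        covered_reference=covered,
        aligned_assembly=aligned,
    )


def gene_completeness(
    covered: IntervalSet,
    annotation: GeneAnnotation,
    thresholds: Sequence[float] = (0.9, 0.5, 0.2),
    mode: str = "cds",
) -> tuple[dict[str, float], dict[float, int]]:
    """Per-gene covered fraction and gene counts at completeness thresholds.

    ``mode='cds'`` measures coverage of the CDS union (the default, since
    completeness is about coding sequence); ``mode='span'`` measures the
    whole gene span instead.
    """
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"threshold must be in (0,1], got {t}")
    if mode not in ("cds", "span"):
        raise ValueError(f"mode must be 'cds' or 'span', got {mode!r}")

    fractions: dict[str, float] = {}
    for gene in annotation:
        if mode == "cds":
            gene_set = IntervalSet({gene.seq_id: gene.cds})
        else:
            gene_set = IntervalSet({gene.seq_id: [gene.span]})
        glen = gene_set.total_length
        if glen == 0:
            raise ValueError(f"gene {gene.gene_id!r} has zero length")
        fractions[gene.gene_id] = intersect(covered, gene_set).total_length / glen

    counts = {t: sum(1 for f in fractions.values() if f >= t) for t in thresholds}
    return fractions, counts


@dataclass
class SharedPositions:
    union_length: int
    shared_fraction: float
    pooled_exclusive_length: int


def shared_positions(
    individual_covered: Sequence[IntervalSet],
    pooled_covered: IntervalSet,
) -> SharedPositions:
    """Fraction of the union of individual covered sets shared with the
    pooled assembly's covered set, plus the pooled-exclusive length."""
    if not individual_covered:
        raise ValueError("need at least one individual covered set")
    u = union(*individual_covered)
    if u.total_length == 0:
        raise ValueError("union of individual covered sets is empty")
    shared = intersect(u, pooled_covered).total_length
    return SharedPositions(
        union_length=u.total_length,
        shared_fraction=shared / u.total_length,
        pooled_exclusive_length=pooled_covered.total_length - shared,
    )


@dataclass
class InversionCall:
    scaffold_id: str
    target_id: str
    breakpoint: tuple[int, int]  # [start, end) on the reference
    plus_block: AlignmentRecord
    minus_block: AlignmentRecord
    affected_gene_ids: list[str] = field(default_factory=list)


def detect_inversions(
    scaffold_alignments: Sequence[AlignmentRecord],
    annotation: GeneAnnotation | None = None,
    min_block: int = 1_000,
) -> list[InversionCall]:
    """Call inversion breakpoints from strand-discordant alignment blocks.

    Per scaffold, blocks of at least ``min_block`` aligned bases are
    ordered along the scaffold; each adjacent pair with opposite strands
    on the same reference sequence yields a call whose breakpoint is the
    reference interval strictly between the two projections (pairs whose
    projections overlap produce no call). Genes whose span overlaps the
    breakpoint are reported.
    """
    by_scaffold: dict[str, list[AlignmentRecord]] = {}
    for rec in scaffold_alignments:
        if rec.aligned_length >= min_block:
            by_scaffold.setdefault(rec.query_id, []).append(rec)

    calls: list[InversionCall] = []
    for sid in sorted(by_scaffold):
        blocks = sorted(by_scaffold[sid], key=lambda r: (r.q_start, r.q_end))
        strands = {b.strand for b in blocks}
        if strands != {"+", "-"}:
            continue
        for a, b in zip(blocks, blocks[1:]):
            if a.strand == b.strand or a.target_id != b.target_id:
                continue
            lo = min(a.t_end, b.t_end)
            hi = max(a.t_start, b.t_start)
            if lo >= hi:
                continue
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            genes = []
            if annotation is not None:
                bp = IntervalSet({a.target_id: [(lo, hi)]})
                for gene in annotation:
                    span_set = IntervalSet({gene.seq_id: [gene.span]})
                    if intersect(bp, span_set).total_length:
                        genes.append(gene.gene_id)
            calls.append(InversionCall(sid, a.target_id, (lo, hi), plus, minus, sorted(genes)))
    return calls
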