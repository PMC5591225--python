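"""Stage 4 — average nucleotide identity (ANI) between two assemblies.

The procedure mirrors the classical BLAST-tabular ANI recipe: discard
alignments below 70 % identity or above e-value 1e-5 (so that only
homologous regions survive), merge the residual overlapping alignments on
each coordinate system — the merged interval carrying the mean identity
of its constituents — and report the length-weighted average identity.
Because alignment lengths differ between the genome acting as query and
the genome acting as target, the ANI is computed in both coordinate
systems; the conservative headline value for a pair is the minimum of the
two directions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from ._align import best_infix_hit_stranded
from .io import AlignmentRecord, SequenceSet

log = logging.getLogger(__name__)


@dataclass
class AniResult:
    ani_query_pct: float
    ani_target_pct: float
    aligned_length_query: int
    aligned_length_target: int
    aligned_fraction_query: float | None
    aligned_fraction_target: float | None
    n_alignments_used: int

    @property
    def headline(self) -> float:
        return min(self.ani_query_pct, self.ani_target_pct)


def _merge_with_identity(
    items: list[tuple[int, int, float]],
    weighted: bool,
) -> list[tuple[int, int, float]]:
    """Merge overlapping/touching (start, end, identity) records.

    Merged identity is the unweighted mean of constituent identities by
    default, or the length-weighted mean when ``weighted`` is set.
    """
    items = sorted(items)
    merged: list[tuple[int, int, list[tuple[int, float]]]] = []
    for s, e, ident in items:
        if merged and s <= merged[-1][1]:
            ms, me, members = merged[-1]
            merged[-1] = (ms, max(me, e), members + [(e - s, ident)])
        else:
            merged.append((s, e, [(e - s, ident)]))
    out = []
    for s, e, members in merged:
        if weighted:
            total = sum(l for l, _ in members)
            ident = sum(l * i for l, i in members) / total
        else:
            ident = sum(i for _, i in members) / len(members)
        out.append((s, e, ident))
    return out


def compute_ani(
    alignments: Sequence[AlignmentRecord],
    query_genome: SequenceSet | None = None,
    target_genome: SequenceSet | None = None,
    min_identity: float = 70.0,
    max_evalue: float = 1e-5,
    weight_within_merge: bool = False,
) -> AniResult:
    """Filter, merge, and length-weight alignments into an ANI estimate.

    Records lacking e-values (e.g. from the internal chunk aligner) pass
    the e-value filter with a logged notice.
    """
    surviving = []
    missing_evalue = 0
    for rec in alignments:
        if rec.identity_pct < min_identity:
            continue
        if rec.e_value is None:
            missing_evalue += 1
        elif rec.e_value > max_evalue:
            continue
        surviving.append(rec)
    if missing_evalue:
        log.info("%d alignments lack e-values; e-value filter skipped for them", missing_evalue)
    if not surviving:
        raise ValueError("ANI undefined: no alignments survive the filters")

    def side_ani(side: str) -> tuple[float, int]:
        per_seq: dict[str, list[tuple[int, int, float]]] = {}
        for rec in surviving:
            if side == "query":
                per_seq.setdefault(rec.query_id, []).append((rec.q_start, rec.q_end, rec.identity_pct))
            else:
                per_seq.setdefault(rec.target_id, []).append((rec.t_start, rec.t_end, rec.identity_pct))
        num = denom = 0.0
        for items in per_seq.values():
            for s, e, ident in _merge_with_identity(items, weight_within_merge):
                num += (e - s) * ident
                denom += e - s
        return num / denom, int(denom)

    ani_q, len_q = side_ani("query")
    ani_t, len_t = side_ani("target")
    return AniResult(
        ani_query_pct=ani_q,
        ani_target_pct=ani_t,
        aligned_length_query=len_q,
        aligned_length_target=len_t,
        aligned_fraction_query=(len_q / query_genome.total_length) if query_genome else None,
        aligned_fraction_target=(len_t / target_genome.total_length) if target_genome else None,
        n_alignments_used=len(surviving),
    )


def chunk_align(
    query: SequenceSet,
    target: SequenceSet,
    chunk: int = 1_000,
    min_chunk: int = 200,
    max_divergence: float = 0.30,
) -> list[AlignmentRecord]:
    """Internal toy aligner: place fixed-size query chunks in the target.

    Each chunk is aligned as an infix (both strands, edit distance) to
    every target sequence and the best placement kept; chunks with no
    placement within the divergence budget emit no record.  Identity is
    exact for substitution-only divergence.  Records carry no e-value.
    """
    records = []
    targets = list(target.items())
    for qid, qseq in query.items():
        for start in range(0, len(qseq), chunk):
            sub = qseq[start:start + chunk]
            if len(sub) < min_chunk:
                continue
            best = None
            for tid, tseq in targets:
                hit = best_infix_hit_stranded(sub, tseq, max_divergence)
                if hit is None:
                    continue
                if best is None or hit[2] > best[1][2]:
                    best = (tid, hit)
            if best is None:
                continue
            tid, (ts, te, ident, strand) = best
            records.append(
                AlignmentRecord(
                    query_id=qid, q_start=start, q_end=start + len(sub),
                    target_id=tid, t_start=ts, t_end=te,
                    strand=strand, identity_pct=100.0 * ident,
                    aligned_length=max(len(sub), te - ts),
                )
            )
    return records


def ani_matrix(
    genomes: Sequence[tuple[str, SequenceSet]],
    aligner: Callable[[SequenceSet, SequenceSet], list[AlignmentRecord]] | None = None,
    **ani_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, str], AniResult | None]]:
    """All-pairs ANI. The matrix cell holds the conservative headline
    value min(ANI_query, ANI_target); the per-pair results carry both
    directions. Pairs whose ANI is undefined leave their cell empty."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes for an ANI matrix")
    aligner = aligner or chunk_align
    names = [n for n, _ in genomes]
    mat = pd.DataFrame(float("nan"), index=names, columns=names)
    results: dict[tuple[str, str], AniResult | None] = {}
    for i, (na, ga) in enumerate(genomes):
        mat.loc[na, na] = 100.0
        for nb, gb in genomes[i + 1:]:
            try:
                res = compute_ani(aligner(ga, gb), ga, gb, **ani_kwargs)
            except ValueError:
                results[(na, nb)] = None
                continue
            results[(na, nb)] = res
            mat.loc[na, nb] = mat.loc[nb, na] = res.headline
    return mat, results
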