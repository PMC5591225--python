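"""Stage 5 — scoring a SAG gene annotation against the reference.

Three complementary views: interval-level overlap (Jaccard J of merged
gene bodies), unique reference genes recovered through protein best hits
(fragmented predictions that all hit the same reference gene collapse to
one), and protein-domain set comparisons (domain content tends to survive
fragmentation better than whole gene models).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import pandas as pd

from .intervals import IntervalSet, jaccard
from .io import FileFormatError, GeneAnnotation


def annotation_jaccard(
    predicted: GeneAnnotation,
    reference: GeneAnnotation,
    mode: str = "span",
) -> float:
    """Jaccard statistic between two annotations on shared coordinates.

    Both annotations must already live on the same coordinate system
    (projecting SAG annotations through scaffold-to-reference alignments
    is the caller's responsibility).  ``mode='span'`` compares merged gene
    bodies; ``mode='cds'`` compares merged CDS intervals.
    """
    if not len(predicted):
        raise ValueError("empty predicted annotation")
    if mode == "span":
        a = IntervalSet.from_intervals(predicted.gene_spans())
        b = IntervalSet.from_intervals(reference.gene_spans())
    elif mode == "cds":
        a = IntervalSet.from_intervals(predicted.cds_triples())
        b = IntervalSet.from_intervals(reference.cds_triples())
    else:
        raise ValueError(f"mode must be 'span' or 'cds', got {mode!r}")
    return jaccard(a, b)


@dataclass
class UniqueGeneRecovery:
    n_unique: int
    gene_ids: set
    assignments: dict[str, str]  # predicted protein -> best reference gene
    pct_reference_genes: float | None = None


def _load_protein_hits(hits) -> pd.DataFrame:
    cols = ["predicted_protein_id", "reference_gene_id", "identity_pct", "e_value", "bit_score"]
    if isinstance(hits, pd.DataFrame):
        missing = set(cols) - set(hits.columns)
        if missing:
            raise ValueError(f"protein hit table missing columns {sorted(missing)}")
        return hits[cols].copy()
    rows = []
    with open(hits) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == cols[0]:
                continue
            if len(parts) < 5:
                raise FileFormatError(f"{hits}:{lineno}: expected >=5 columns")
            try:
                rows.append({
                    "predicted_protein_id": parts[0],
                    "reference_gene_id": parts[1],
                    "identity_pct": float(parts[2]),
                    "e_value": float(parts[3]),
                    "bit_score": float(parts[4]),
                })
            except ValueError as exc:
                raise FileFormatError(f"{hits}:{lineno}: malformed numeric field") from exc
    return pd.DataFrame(rows, columns=cols)


def unique_gene_recovery(
    protein_hits,
    max_evalue: float = 1e-5,
    min_identity: float = 90.0,
    n_reference_genes: int | None = None,
) -> UniqueGeneRecovery:
    """Distinct reference genes recovered through protein best hits.

    Rows failing either threshold are removed; each predicted protein is
    assigned its best surviving hit (max bit score, ties broken by min
    e-value then lexicographic gene id); ``n_unique`` is the number of
    distinct reference genes assigned.
    """
    df = _load_protein_hits(protein_hits)
    df = df[(df["e_value"] < max_evalue) & (df["identity_pct"] > min_identity)]
    assignments: dict[str, str] = {}
    for pid, grp in df.groupby("predicted_protein_id"):
        best = grp.sort_values(
            ["bit_score", "e_value", "reference_gene_id"],
            ascending=[False, True, True], kind="mergesort",
        ).iloc[0]
        assignments[str(pid)] = str(best["reference_gene_id"])
    genes = set(assignments.values())
    pct = 100.0 * len(genes) / n_reference_genes if n_reference_genes else None
    return UniqueGeneRecovery(len(genes), genes, assignments, pct)


@dataclass
class DomainComparison:
    sets: dict[str, set]
    shared_with_reference: dict[str, int]
    unique_per_set: dict[str, int]
    pct_reference_domains: dict[str, float]
    venn: dict[tuple[str, ...], int]  # membership pattern -> region count


def _load_domains(table) -> set:
    if isinstance(table, (set, frozenset)):
        return set(table)
    if isinstance(table, pd.DataFrame):
        return set(table["domain_id"].astype(str))
    domains = set()
    with open(table) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "protein_id":
                continue
            if len(parts) < 2:
                raise FileFormatError(f"{table}:{lineno}: expected >=2 columns")
            domains.add(parts[1])
    return domains


def domain_overlap(domain_tables: Mapping[str, object], reference_name: str) -> DomainComparison:
    """Set algebra over per-annotation protein-domain id sets.

    Each table maps to its distinct domain-id set; pairwise shared/unique
    counts are computed against the reference set, and a joint Venn over
    all sets (up to 4) records the count of each membership region.
    """
    if reference_name not in domain_tables:
        raise ValueError(f"unknown reference annotation name: {reference_name!r}")
    sets = {name: _load_domains(tab) for name, tab in domain_tables.items()}
    ref = sets[reference_name]

    shared = {n: len(s & ref) for n, s in sets.items() if n != reference_name}
    unique = {n: len(s - ref) for n, s in sets.items() if n != reference_name}
    pct = {
        n: (100.0 * len(s & ref) / len(ref)) if ref else 0.0
        for n, s in sets.items() if n != reference_name
    }

    names = sorted(sets)
    venn: dict[tuple[str, ...], int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            region = set(universe)
            for n in names:
                region = region & sets[n] if n in members else region - sets[n]
            venn[members] = len(region)
    return DomainComparison(sets, shared, unique, pct, venn)
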