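"""Stage 2 — host vs contaminant scaffold classification.

Four lines of evidence, mirroring standard single-cell genome hygiene:

1. taxonomy: best e-value-filtered hit per scaffold against a reference
   database (the hit table itself is an input — running the database
   search is out of scope);
2. tetranucleotide-frequency (TNF) composition: canonical 4-mer profiles
   of 5 kb windows from scaffolds >= 10 kb, clustered by PCA + k-means
   with silhouette-based model selection, propagating taxonomy labels to
   unannotated scaffolds through cluster co-membership;
3. GC content: length-weighted assembly GC plus a two-component Gaussian
   mixture bimodality flag on per-window GC — removing true contaminants
   should collapse a bimodal distribution to the host mode;
4. 16S rDNA: infix search of a 16S query against (contaminant) scaffolds
   and greedy longest-first centroid clustering of the extracted copies
   into OTUs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from ._align import best_infix_hit_stranded, global_identity
from .io import FileFormatError, SequenceSet
from .sequtil import gc_fraction, revcomp

# Canonical 4-mers: each 4-mer pooled with its reverse complement -> 136 classes.
_ALL_KMERS = ["".join(p) for p in product("ACGT", repeat=4)]
CANONICAL_4MERS = sorted({min(k, revcomp(k)) for k in _ALL_KMERS})
_KMER_COL = {k: CANONICAL_4MERS.index(min(k, revcomp(k))) for k in _ALL_KMERS}
N_CANONICAL = len(CANONICAL_4MERS)  # 136


@dataclass
class TnfMatrix:
    """Rows of canonical 4-mer frequencies, one per (scaffold, window)."""

    rows: list[tuple[str, int]]  # (scaffold_id, window_start)
    values: np.ndarray           # shape (n_rows, 136), each row sums to 1
    window: int
    min_scaffold: int

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def scaffold_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self.rows})


def tnf_profile(
    scaffolds: SequenceSet,
    min_scaffold: int = 10_000,
    window: int = 5_000,
    max_n_fraction: float = 0.10,
) -> TnfMatrix:
    """Canonical tetranucleotide frequencies of non-overlapping windows.

    Only scaffolds of at least ``min_scaffold`` bases contribute; windows
    start at 0, the final partial window is discarded, and windows with
    more than ``max_n_fraction`` N are skipped.  4-mers containing N are
    not counted.
    """
    if window < 256:
        raise ValueError("window must be >= 256 (4^4 possible 4-mers)")
    rows: list[tuple[str, int]] = []
    vectors: list[np.ndarray] = []
    for sid in sorted(scaffolds.ids()):
        seq = scaffolds[sid]
        if len(seq) < min_scaffold:
            continue
        for start in range(0, len(seq) - window + 1, window):
            wseq = seq[start:start + window]
            if wseq.count("N") / window > max_n_fraction:
                continue
            counts = np.zeros(N_CANONICAL, dtype=np.float64)
            for i in range(window - 3):
                col = _KMER_COL.get(wseq[i:i + 4])
                if col is not None:
                    counts[col] += 1
            total = counts.sum()
            if total == 0:
                continue
            rows.append((sid, start))
            vectors.append(counts / total)
    values = np.array(vectors) if vectors else np.zeros((0, N_CANONICAL))
    return TnfMatrix(rows, values, window, min_scaffold)


@dataclass
class TnfClustering:
    k: int
    window_labels: np.ndarray
    scaffold_labels: dict[str, int]
    silhouettes: dict[int, float]


def cluster_tnf(
    matrix: TnfMatrix,
    k_candidates: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
    min_silhouette: float = 0.25,
) -> TnfClustering:
    """PCA(10) + k-means over the TNF rows, k chosen by mean silhouette.

    Falls back to a single cluster when fewer than two rows exist or when
    the best silhouette is below ``min_silhouette`` (no real structure).
    Scaffold labels are the majority label of their windows.
    """
    n = matrix.n_rows
    if n < 2:
        labels = np.zeros(n, dtype=int)
        return TnfClustering(1, labels, _majority(matrix.rows, labels), {})

    n_comp = min(10, n, matrix.values.shape[1])
    X = PCA(n_components=n_comp, random_state=seed).fit_transform(matrix.values)

    silhouettes: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in sorted(k_candidates):
        if k < 2 or n < 2 * k or k > n - 1:
            continue
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        fits[k] = km.labels_
        silhouettes[k] = float(silhouette_score(X, km.labels_))

    if not silhouettes or max(silhouettes.values()) < min_silhouette:
        labels = np.zeros(n, dtype=int)
        return TnfClustering(1, labels, _majority(matrix.rows, labels), silhouettes)

    best_k = max(sorted(silhouettes), key=lambda k: silhouettes[k])
    labels = fits[best_k]
    return TnfClustering(best_k, labels, _majority(matrix.rows, labels), silhouettes)


def _majority(rows: list[tuple[str, int]], labels: np.ndarray) -> dict[str, int]:
    votes: dict[str, dict[int, int]] = {}
    for (sid, _), lab in zip(rows, labels):
        votes.setdefault(sid, {})[int(lab)] = votes.setdefault(sid, {}).get(int(lab), 0) + 1
    return {
        sid: min(v, key=lambda c: (-v[c], c))  # majority, ties -> smaller cluster id
        for sid, v in votes.items()
    }


@dataclass(frozen=True)
class Verdict:
    label: str                 # 'host' | 'contaminant' | 'unknown'
    evidence: frozenset = frozenset()


def _load_taxonomy(taxonomy_hits) -> pd.DataFrame:
    if isinstance(taxonomy_hits, pd.DataFrame):
        df = taxonomy_hits.copy()
        required = {"scaffold_id", "taxon", "e_value"}
        if not required <= set(df.columns):
            raise ValueError(f"taxonomy table must have columns {sorted(required)}")
        if "bit_score" not in df.columns:
            df["bit_score"] = 0.0
        return df
    rows = []
    with open(taxonomy_hits) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "scaffold_id":
                continue
            if len(cols) < 3:
                raise FileFormatError(f"{taxonomy_hits}:{lineno}: expected >=3 columns")
            try:
                e_value = float(cols[2])
                bit = float(cols[3]) if len(cols) > 3 else 0.0
            except ValueError as exc:
                raise FileFormatError(f"{taxonomy_hits}:{lineno}: malformed numeric field") from exc
            rows.append({"scaffold_id": cols[0], "taxon": cols[1], "e_value": e_value, "bit_score": bit})
    return pd.DataFrame(rows, columns=["scaffold_id", "taxon", "e_value", "bit_score"])


def classify_scaffolds(
    scaffolds: SequenceSet,
    taxonomy_hits,
    tnf: TnfClustering | None = None,
    host_rule: Callable[[str], bool] | str = "host",
    max_evalue: float = 1e-5,
) -> dict[str, Verdict]:
    """Per-scaffold host/contaminant verdicts.

    Taxonomy evidence dominates: the best surviving hit (e-value filter,
    then max bit score, min e-value, lexicographic taxon) decides through
    ``host_rule`` (a predicate on the taxon string, or a case-insensitive
    substring).  Scaffolds with no surviving hit inherit the label of
    their TNF cluster when that cluster is anchored by taxonomically
    labelled scaffolds; otherwise they are ``unknown``.
    """
    if isinstance(host_rule, str):
        needle = host_rule.lower()
        rule = lambda taxon: needle in taxon.lower()  # noqa: E731
    else:
        rule = host_rule

    df = _load_taxonomy(taxonomy_hits)
    df = df[df["e_value"] < max_evalue]
    tax_label: dict[str, str] = {}
    for sid, grp in df.groupby("scaffold_id"):
        best = grp.sort_values(
            ["bit_score", "e_value", "taxon"], ascending=[False, True, True], kind="mergesort"
        ).iloc[0]
        tax_label[str(sid)] = "host" if rule(str(best["taxon"])) else "contaminant"

    # Anchor TNF clusters with the taxonomy-labelled scaffolds they contain.
    cluster_anchor: dict[int, str] = {}
    if tnf is not None:
        votes: dict[int, dict[str, int]] = {}
        for sid, cluster in tnf.scaffold_labels.items():
            lab = tax_label.get(sid)
            if lab:
                votes.setdefault(cluster, {})[lab] = votes.setdefault(cluster, {}).get(lab, 0) + 1
        for cluster, v in votes.items():
            ranked = sorted(v.items(), key=lambda kv: -kv[1])
            if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                cluster_anchor[cluster] = ranked[0][0]

    verdicts: dict[str, Verdict] = {}
    for sid in scaffolds:
        if sid in tax_label:
            verdicts[sid] = Verdict(tax_label[sid], frozenset({"taxonomy"}))
            continue
        if tnf is not None and sid in tnf.scaffold_labels:
            anchor = cluster_anchor.get(tnf.scaffold_labels[sid])
            if anchor:
                verdicts[sid] = Verdict(anchor, frozenset({"tnf"}))
                continue
        verdicts[sid] = Verdict("unknown")
    return verdicts


@dataclass
class GcScreen:
    gc_all: float
    gc_host_only: float
    bimodal: bool
    component_means: tuple[float, float] | None
    component_weights: tuple[float, float] | None


def gc_screen(
    scaffolds: SequenceSet,
    verdicts: Mapping[str, Verdict] | None = None,
    window: int = 5_000,
    delta_mean: float = 0.05,
    min_weight: float = 0.10,
) -> GcScreen:
    """Length-weighted GC before/after contaminant removal, plus a
    two-component mixture bimodality flag on per-window GC.

    ``bimodal`` is computed on the scaffolds that remain after excluding
    contaminant verdicts (all scaffolds when no verdicts are given): it is
    true iff the two component means differ by more than ``delta_mean``
    and both weights exceed ``min_weight``.
    """
    if not len(scaffolds):
        raise ValueError("no scaffolds to screen")

    def weighted_gc(ids) -> float:
        gc_bases = total = 0
        for sid in ids:
            seq = scaffolds[sid]
            acgt = sum(seq.count(b) for b in "ACGT")
            gc_bases += seq.count("G") + seq.count("C")
            total += acgt
        return gc_bases / total if total else 0.0

    all_ids = list(scaffolds.ids())
    keep = [
        sid for sid in all_ids
        if verdicts is None or verdicts.get(sid, Verdict("unknown")).label != "contaminant"
    ]
    gc_all = weighted_gc(all_ids)
    gc_host = weighted_gc(keep) if keep else 0.0

    window_gc = []
    for sid in keep:
        seq = scaffolds[sid]
        if len(seq) < window:
            window_gc.append(gc_fraction(seq))
            continue
        for start in range(0, len(seq) - window + 1, window):
            window_gc.append(gc_fraction(seq[start:start + window]))

    bimodal = False
    means = weights = None
    if len(window_gc) >= 10:
        X = np.array(window_gc).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(X)
        m = tuple(float(x) for x in gm.means_.ravel())
        w = tuple(float(x) for x in gm.weights_.ravel())
        means, weights = m, w
        bimodal = abs(m[0] - m[1]) > delta_mean and min(w) > min_weight
    return GcScreen(gc_all, gc_host, bimodal, means, weights)


@dataclass
class Otu:
    centroid_id: str
    centroid_seq: str
    members: list[tuple[str, int, int]]  # (scaffold_id, start, end)
    sag_ids: set = field(default_factory=set)


@dataclass
class OtuTable:
    otus: list[Otu]
    identity_threshold: float

    def __len__(self) -> int:
        return len(self.otus)


def rdna_screen(
    scaffolds: SequenceSet,
    query_16s: str,
    min_identity: float = 0.80,
    otu_threshold: float = 0.97,
    min_hit_length: int = 300,
    sag_of: Mapping[str, str] | None = None,
    max_hits_per_scaffold: int = 10,
) -> OtuTable:
    """Extract 16S-like regions and cluster them into OTUs.

    The query is placed by iterated infix alignment (both strands, with
    masking between rounds); regions of at least ``min_hit_length`` bases
    and ``min_identity`` are extracted, oriented to the query strand,
    sorted longest-first, and greedily clustered: a sequence joins the
    first existing OTU whose centroid it matches at ``otu_threshold``
    global identity, else founds a new OTU.
    """
    query = query_16s.upper()
    if not query:
        raise ValueError("empty 16S query")
    extracted: list[tuple[str, int, int, str]] = []
    for sid in sorted(scaffolds.ids()):
        target = scaffolds[sid]
        for _ in range(max_hits_per_scaffold):
            hit = best_infix_hit_stranded(query, target, max_divergence=1.0 - min_identity + 0.15)
            if hit is None:
                break
            s, e, ident, strand = hit
            if ident < min_identity or (e - s) < min_hit_length:
                break
            seq = scaffolds[sid][s:e]
            extracted.append((sid, s, e, revcomp(seq) if strand == "-" else seq))
            target = target[:s] + "N" * (e - s) + target[e:]

    extracted.sort(key=lambda t: (-(t[2] - t[1]), t[0], t[1]))
    otus: list[Otu] = []
    for sid, s, e, seq in extracted:
        placed = False
        for otu in otus:
            if global_identity(seq, otu.centroid_seq) >= otu_threshold:
                otu.members.append((sid, s, e))
                otu.sag_ids.add(sag_of.get(sid, "sag") if sag_of else "sag")
                placed = True
                break
        if not placed:
            otus.append(
                Otu(
                    centroid_id=f"OTU_{len(otus) + 1}",
                    centroid_seq=seq,
                    members=[(sid, s, e)],
                    sag_ids={sag_of.get(sid, "sag") if sag_of else "sag"},
                )
            )
    return OtuTable(otus, otu_threshold)
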