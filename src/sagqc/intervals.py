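"""Exact interval arithmetic and depth accounting.

Half-open [start, end) intervals throughout; touching intervals merge.
These primitives back every downstream recovery metric, so they are kept
exact and are cross-checked against per-base boolean-array oracles in the
test suite.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


class IntervalSet:
    """Per-sequence sorted disjoint half-open intervals.

    Construction always normalises: intervals are sorted and overlapping or
    touching intervals are merged, so any two IntervalSets with the same
    per-base membership compare equal.
    """

    def __init__(self, per_seq: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self.per_seq: dict[str, list[tuple[int, int]]] = {}
        if per_seq:
            for sid, ivals in per_seq.items():
                self.per_seq[sid] = _merge_sorted(ivals)
            self.per_seq = {k: v for k, v in self.per_seq.items() if v}

    @classmethod
    def from_intervals(cls, triples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        per: dict[str, list[tuple[int, int]]] = {}
        for sid, s, e in triples:
            per.setdefault(sid, []).append((s, e))
        return cls(per)

    @classmethod
    def from_alignments(cls, records, side: str = "target") -> "IntervalSet":
        if side == "target":
            return cls.from_intervals((r.target_id, r.t_start, r.t_end) for r in records)
        if side == "query":
            return cls.from_intervals((r.query_id, r.q_start, r.q_end) for r in records)
        raise ValueError(f"side must be 'target' or 'query', got {side!r}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        triples = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                triples.append((cols[0], int(cols[1]), int(cols[2])))
        return cls.from_intervals(triples)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.per_seq):
                for s, e in self.per_seq[sid]:
                    fh.write(f"{sid}\t{s}\t{e}\n")

    @property
    def total_length(self) -> int:
        return sum(e - s for ivals in self.per_seq.values() for s, e in ivals)

    def length(self, seq_id: str) -> int:
        return sum(e - s for s, e in self.per_seq.get(seq_id, []))

    def seqs(self) -> list[str]:
        return sorted(self.per_seq)

    def intervals(self, seq_id: str) -> list[tuple[int, int]]:
        return list(self.per_seq.get(seq_id, []))

    def is_empty(self) -> bool:
        return not self.per_seq

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.per_seq == other.per_seq

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.per_seq)} seqs, {self.total_length} bp)"


def _merge_sorted(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivals:
        if s >= e:
            raise ValueError(f"invalid interval [{s},{e}): start must be < end")
        if s < 0:
            raise ValueError(f"negative interval start {s}")
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:  # overlap or touch
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def merge(per_seq: Mapping[str, Iterable[tuple[int, int]]]) -> IntervalSet:
    """Minimal disjoint cover of the given intervals (touching intervals merge)."""
    return IntervalSet(per_seq)


def union(*sets: IntervalSet) -> IntervalSet:
    per: dict[str, list[tuple[int, int]]] = {}
    for iset in sets:
        for sid, ivals in iset.per_seq.items():
            per.setdefault(sid, []).extend(ivals)
    return IntervalSet(per)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact per-base intersection (commutative)."""
    per: dict[str, list[tuple[int, int]]] = {}
    for sid in set(a.per_seq) & set(b.per_seq):
        ia, ib = a.per_seq[sid], b.per_seq[sid]
        out = []
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if s < e:
                out.append((s, e))
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        if out:
            per[sid] = out
    result = IntervalSet()
    result.per_seq = per  # already disjoint and sorted
    return result


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """J = |a n b| / |a u b|, on base pairs. Undefined (error) when both empty."""
    la, lb = a.total_length, b.total_length
    if la == 0 and lb == 0:
        raise ValueError("undefined Jaccard: both interval sets are empty")
    li = intersect(a, b).total_length
    return li / (la + lb - li)


@dataclass
class DepthProfile:
    """Per-position integer read depth for one sequence."""

    seq_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.size)

    def covered(self, min_depth: int = 1) -> IntervalSet:
        """Intervals with depth >= min_depth, as an IntervalSet."""
        mask = self.depth >= min_depth
        return IntervalSet({self.seq_id: _runs(mask)}) if mask.any() else IntervalSet()

    def histogram(self) -> dict[int, int]:
        counts = np.bincount(self.depth)
        return {d: int(c) for d, c in enumerate(counts) if c}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open intervals."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def depth_from_alignments(alignments, seq_id: str, seq_length: int) -> DepthProfile:
    """depth[p] = number of records whose target interval contains p."""
    delta = np.zeros(seq_length + 1, dtype=np.int64)
    for rec in alignments:
        if rec.target_id != seq_id:
            raise ValueError(f"record targets {rec.target_id!r}, expected {seq_id!r}")
        if rec.t_end > seq_length:
            raise ValueError(
                f"record [{rec.t_start},{rec.t_end}) out of range for length {seq_length}"
            )
        delta[rec.t_start] += 1
        delta[rec.t_end] -= 1
    return DepthProfile(seq_id, np.cumsum(delta[:-1]))


def breadth(profile: DepthProfile, min_depth: int = 1) -> float:
    """Fraction of positions with depth >= min_depth."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if profile.length == 0:
        return 0.0
    return float((profile.depth >= min_depth).mean())


def depth_to_bedgraph(profile: DepthProfile, path: str | Path) -> None:
    """Export a depth profile as BedGraph (runs of constant depth)."""
    d = profile.depth
    with open(path, "w") as fh:
        if d.size == 0:
            return
        change = np.nonzero(np.diff(d))[0] + 1
        bounds = np.concatenate(([0], change, [d.size]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            fh.write(f"{profile.seq_id}\t{s}\t{e}\t{int(d[s])}\n")
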