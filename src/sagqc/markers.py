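"""Stage 6 — phylogenomic marker recovery from nucleotide scaffolds.

Markers are single-copy protein-domain alignments.  Each marker's
representative (its first taxon, ungapped) is searched against all six
reading frames of every scaffold with affine-gap local protein alignment
(BLOSUM62; gap open 11, extend 1, i.e. a gap of length L costs
11 + (L-1)).  A marker counts as recovered when its best score reaches
``min_score``; recovered residues are mapped back onto the marker's
alignment columns so a supermatrix row (with per-taxon ungapped-position
accounting) can be emitted for external tree inference.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io import SequenceSet
from .sequtil import revcomp

log = logging.getLogger(__name__)

_CODON = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    _CODON[stop] = "*"

FRAMES = (1, 2, 3, -1, -2, -3)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_PROTEIN_ALPHABET = set(str(_BLOSUM62.alphabet))


def translate_frame(seq: str, frame: int) -> str:
    """Translate one reading frame (+1..+3 forward, -1..-3 on the reverse
    complement); codons containing N give X, trailing partial codons drop."""
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = seq if frame > 0 else revcomp(seq)
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(s) - 2, 3):
        codon = s[i:i + 3]
        out.append("X" if "N" in codon else _CODON.get(codon, "X"))
    return "".join(out)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six frame translations of a DNA sequence over {A,C,G,T,N}."""
    return {f: translate_frame(seq, f) for f in FRAMES}


class MarkerSet:
    """A collection of reference protein alignments, one per marker."""

    def __init__(self, markers: Mapping[str, Sequence[tuple[str, str]]]):
        self.markers: dict[str, list[tuple[str, str]]] = {}
        for mid, seqs in markers.items():
            seqs = [(n, s.upper()) for n, s in seqs]
            if not seqs:
                raise ValueError(f"marker {mid!r} has no sequences")
            lengths = {len(s) for _, s in seqs}
            if len(lengths) != 1:
                raise ValueError(f"marker {mid!r}: aligned sequences differ in length")
            self.markers[mid] = seqs

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def aligned_length(self, marker_id: str) -> int:
        return len(self.markers[marker_id][0][1])

    @property
    def total_columns(self) -> int:
        return sum(self.aligned_length(m) for m in self.markers)

    def representative(self, marker_id: str) -> str:
        """Ungapped sequence of the marker's first taxon."""
        return self.markers[marker_id][0][1].replace("-", "")

    def column_map(self, marker_id: str) -> list[int]:
        """Alignment column of each representative residue."""
        aligned = self.markers[marker_id][0][1]
        return [col for col, c in enumerate(aligned) if c != "-"]


def read_marker_set(directory: str | Path) -> MarkerSet:
    """Load a marker set from a directory of per-marker multi-FASTA files."""
    directory = Path(directory)
    markers = {}
    for path in sorted(directory.glob("*.fa*")):
        seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        markers[path.stem] = seqs
    if not markers:
        raise ValueError(f"no marker FASTA files found in {directory}")
    return MarkerSet(markers)


def _sanitize(pep: str) -> str:
    return "".join(c if c in _PROTEIN_ALPHABET else "X" for c in pep.upper())


def make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def self_score(peptide: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score of a peptide locally aligned to itself (the maximum any hit
    of that marker can reach)."""
    aligner = make_aligner(gap_open, gap_extend)
    pep = _sanitize(peptide)
    return float(aligner.score(pep, pep))


@dataclass
class MarkerHit:
    marker_id: str
    scaffold_id: str | None
    frame: int | None
    score: float
    aligned_columns: int
    recovered: bool
    rep_residues: dict[int, str] = field(default_factory=dict)  # rep index -> residue


def search_markers(
    scaffolds: SequenceSet,
    marker_set: MarkerSet,
    min_score: float = 60.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[MarkerHit]:
    """Best six-frame local-alignment hit per marker across all scaffolds.

    Deterministic: ties between equal-scoring placements resolve to the
    lexicographically first scaffold and the first frame in
    (+1,+2,+3,-1,-2,-3) order.
    """
    if not len(marker_set):
        raise ValueError("empty marker set")
    aligner = make_aligner(gap_open, gap_extend)

    frames_cache: dict[str, dict[int, str]] = {
        sid: {f: _sanitize(translate_frame(scaffolds[sid], f)) for f in FRAMES}
        for sid in sorted(scaffolds.ids())
    }

    hits = []
    for mid in sorted(marker_set):
        rep = _sanitize(marker_set.representative(mid))
        best: tuple[float, str, int] | None = None
        for sid in sorted(frames_cache):
            for f in FRAMES:
                pep = frames_cache[sid][f]
                if len(pep) < 5:
                    continue
                score = float(aligner.score(pep, rep))
                if best is None or score > best[0]:
                    best = (score, sid, f)
        if best is None or best[0] <= 0:
            hits.append(MarkerHit(mid, None, None, 0.0, 0, False))
            continue
        score, sid, f = best
        aln = aligner.align(frames_cache[sid][f], rep)[0]
        frame_blocks, rep_blocks = aln.aligned
        rep_residues: dict[int, str] = {}
        pep = frames_cache[sid][f]
        for (fs, fe), (rs, re_) in zip(frame_blocks, rep_blocks):
            for off in range(fe - fs):
                rep_residues[rs + off] = pep[fs + off]
        cols = marker_set.column_map(mid)
        aligned_columns = len({cols[i] for i in rep_residues})
        hits.append(
            MarkerHit(mid, sid, f, score, aligned_columns, score >= min_score, rep_residues)
        )
    return hits


@dataclass
class SupermatrixRow:
    taxon: str
    sequence: str
    ungapped_positions: int
    total_columns: int
    n_recovered: int
    n_markers: int
    recovery_pct: float
    per_marker: dict[str, tuple[bool, int]]  # marker -> (recovered, ungapped cells)


def build_supermatrix(
    marker_hits: Iterable[MarkerHit],
    marker_set: MarkerSet,
    taxon_name: str,
) -> SupermatrixRow:
    """Concatenate recovered marker residues into one supermatrix row.

    Recovered markers contribute residues at the alignment columns their
    representative residues occupy; unrecovered markers contribute
    all-gap blocks.  Duplicate hits for one marker keep the best score.
    """
    best_hits: dict[str, MarkerHit] = {}
    for hit in marker_hits:
        if hit.marker_id not in marker_set.markers:
            raise ValueError(f"hit references unknown marker {hit.marker_id!r}")
        prev = best_hits.get(hit.marker_id)
        if prev is not None:
            log.info("duplicate hit for marker %s: keeping the better score", hit.marker_id)
        if prev is None or hit.score > prev.score:
            best_hits[hit.marker_id] = hit

    blocks: list[str] = []
    per_marker: dict[str, tuple[bool, int]] = {}
    n_rec = 0
    for mid in sorted(marker_set):
        width = marker_set.aligned_length(mid)
        row = ["-"] * width
        hit = best_hits.get(mid)
        if hit is not None and hit.recovered:
            n_rec += 1
            cols = marker_set.column_map(mid)
            for rep_idx, residue in hit.rep_residues.items():
                row[cols[rep_idx]] = residue
        block = "".join(row)
        per_marker[mid] = (hit is not None and hit.recovered, sum(1 for c in block if c != "-"))
        blocks.append(block)

    sequence = "".join(blocks)
    ungapped = sum(1 for c in sequence if c != "-")
    n_markers = len(marker_set)
    return SupermatrixRow(
        taxon=taxon_name,
        sequence=sequence,
        ungapped_positions=ungapped,
        total_columns=len(sequence),
        n_recovered=n_rec,
        n_markers=n_markers,
        recovery_pct=100.0 * n_rec / n_markers,
        per_marker=per_marker,
    )


def write_supermatrix_fasta(rows: Sequence[SupermatrixRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(f">{row.taxon}\n{row.sequence}\n")
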