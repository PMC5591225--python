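"""Readers and writers for the external formats the pipeline touches.

Every coordinate exposed by this module is 0-based, half-open, on the
forward strand of the sequence it refers to.  The two external dialects
that use 1-based inclusive coordinates (GFF3 and 12-column tabular local
alignments) are converted at this boundary and never leak their native
convention into the rest of the package.

Minus-strand tabular alignment records (target start > target end) are
normalised so the stored target interval is forward-strand, with the
strand flag retained for the synteny/inversion stage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
# IUPAC ambiguity codes other than N; mapped to N with a warning on read.
_IUPAC_AMBIG = set("RYSWKMBDHV")


class FileFormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Sequence sets
# ---------------------------------------------------------------------------

class SequenceSet:
    """Named DNA sequences (a reference genome, SAG scaffolds, or reads).

    Sequences are stored upper-case over {A,C,G,T,N}.  Ids are unique and
    non-empty; iteration order is insertion order.
    """

    def __init__(self, records: Mapping[str, str] | None = None):
        self._records: dict[str, str] = {}
        if records:
            for sid, seq in records.items():
                self.add(sid, seq)

    def add(self, seq_id: str, sequence: str) -> None:
        if not seq_id:
            raise ValueError("sequence id must be non-empty")
        if seq_id in self._records:
            raise ValueError(f"duplicate sequence id: {seq_id!r}")
        seq = sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for id {seq_id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            ambig = bad & _IUPAC_AMBIG
            if bad - ambig:
                raise ValueError(
                    f"non-IUPAC characters {sorted(bad - ambig)} in sequence {seq_id!r}"
                )
            log.warning(
                "sequence %s: IUPAC ambiguity codes %s mapped to N",
                seq_id, "".join(sorted(ambig)),
            )
            seq = seq.translate(str.maketrans({c: "N" for c in ambig}))
        self._records[seq_id] = seq

    def __getitem__(self, seq_id: str) -> str:
        return self._records[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __iter__(self):
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def items(self):
        return self._records.items()

    def ids(self) -> list[str]:
        return list(self._records)

    def length(self, seq_id: str) -> int:
        return len(self._records[seq_id])

    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self._records.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._records.values())

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        out = SequenceSet()
        for sid in ids:
            out.add(sid, self._records[sid])
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, SequenceSet) and self._records == other._records

    def __repr__(self) -> str:
        return f"SequenceSet({len(self)} records, {self.total_length} bp)"


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file; the description after the first whitespace is dropped."""
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        out.add(rec.id, str(rec.seq))
    return out


def read_fastq(path: str | Path) -> SequenceSet:
    """Read a FASTQ file as a :class:`SequenceSet`; qualities are ignored."""
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fastq"):
        out.add(rec.id, str(rec.seq))
    return out


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq(seqs: SequenceSet, path: str | Path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs.items():
            fh.write(f"@{sid}\n{s}\n+\n{chr(quality + 33) * len(s)}\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    seq_id: str
    strand: str
    cds: tuple[tuple[int, int], ...]  # sorted, non-overlapping, half-open

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds[0][0], self.cds[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


class GeneAnnotation:
    """Per-gene CDS interval lists on reference coordinates."""

    def __init__(self, genes: Iterable[Gene] = ()):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id: {gene.gene_id!r}")
        if not gene.cds:
            raise ValueError(f"gene {gene.gene_id!r} has zero CDS length")
        prev_end = -1
        for s, e in gene.cds:
            if not (0 <= s < e):
                raise ValueError(f"gene {gene.gene_id!r}: invalid CDS interval [{s},{e})")
            if s < prev_end:
                raise ValueError(f"gene {gene.gene_id!r}: overlapping CDS intervals")
            prev_end = e
        if gene.strand not in "+-":
            raise ValueError(f"gene {gene.gene_id!r}: strand must be + or -")
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneAnnotation) and self.genes == other.genes

    def gene_spans(self) -> list[tuple[str, int, int]]:
        return [(g.seq_id, *g.span) for g in self]

    def cds_triples(self) -> list[tuple[str, int, int]]:
        return [(g.seq_id, s, e) for g in self for s, e in g.cds]

    def validate_against(self, seqs: SequenceSet) -> None:
        for g in self:
            if g.seq_id not in seqs:
                raise ValueError(f"gene {g.gene_id!r} on unknown sequence {g.seq_id!r}")
            if g.span[1] > seqs.length(g.seq_id):
                raise ValueError(f"gene {g.gene_id!r} extends past end of {g.seq_id!r}")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path) -> GeneAnnotation:
    feature_parent: dict[str, str | None] = {}
    feature_type: dict[str, str] = {}
    cds_rows: list[tuple[int, str, int, int, str, dict[str, str]]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FileFormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end_i < start_i:
                raise FileFormatError(f"{path}:{lineno}: end < start")
            adict = _parse_gff3_attributes(attrs)
            if ftype.upper() == "CDS":
                cds_rows.append((lineno, seqid, start_i - 1, end_i, strand, adict))
            else:
                fid = adict.get("ID")
                if fid:
                    feature_type[fid] = ftype
                    feature_parent[fid] = adict.get("Parent")

    def resolve_gene(parent: str) -> str:
        seen = set()
        cur = parent
        while cur in feature_parent and cur not in seen:
            seen.add(cur)
            if feature_type.get(cur) == "gene":
                return cur
            nxt = feature_parent[cur]
            if nxt is None:
                return cur
            cur = nxt.split(",")[0]
        return cur

    grouped: dict[str, dict] = {}
    for lineno, seqid, s, e, strand, adict in cds_rows:
        parent = adict.get("Parent") or adict.get("ID")
        if not parent:
            raise FileFormatError(f"{path}:{lineno}: CDS without resolvable gene parent")
        gene_id = resolve_gene(parent.split(",")[0])
        info = grouped.setdefault(gene_id, {"seq_id": seqid, "strand": strand, "cds": []})
        if info["seq_id"] != seqid:
            raise FileFormatError(f"{path}:{lineno}: gene {gene_id!r} spans multiple sequences")
        info["cds"].append((s, e))

    ann = GeneAnnotation()
    for gid, info in grouped.items():
        cds = tuple(sorted(info["cds"]))
        ann.add(Gene(gid, info["seq_id"], info["strand"], cds))
    return ann


def _read_bed12(path: Path) -> GeneAnnotation:
    ann = GeneAnnotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FileFormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(cols)}")
            chrom, start, _end, name, _score, strand = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4], cols[5]
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FileFormatError(f"{path}:{lineno}: block count mismatch")
            cds = tuple(sorted((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)))
            ann.add(Gene(name, chrom, strand, cds))
    return ann


def read_annotation(path: str | Path, dialect: str = "gff3") -> GeneAnnotation:
    """Read a gene annotation.

    GFF3 CDS features are grouped by gene through Parent chains (CDS ->
    mRNA -> gene); BED12 blocks are taken as CDS intervals.  1-based
    closed GFF3 coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def write_annotation(ann: GeneAnnotation, path: str | Path, dialect: str = "gff3") -> None:
    path = Path(path)
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid in sorted(ann.genes):
                g = ann[gid]
                s, e = g.span
                fh.write(f"{g.seq_id}\tsagqc\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={gid}\n")
                mid = f"{gid}.mRNA"
                fh.write(f"{g.seq_id}\tsagqc\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={mid};Parent={gid}\n")
                for cs, ce in g.cds:
                    fh.write(f"{g.seq_id}\tsagqc\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\tParent={mid}\n")
    elif dialect == "bed12":
        with open(path, "w") as fh:
            for gid in sorted(ann.genes):
                g = ann[gid]
                s, e = g.span
                sizes = ",".join(str(ce - cs) for cs, ce in g.cds)
                starts = ",".join(str(cs - s) for cs, ce in g.cds)
                fh.write(
                    f"{g.seq_id}\t{s}\t{e}\t{gid}\t0\t{g.strand}\t{s}\t{e}\t0\t{len(g.cds)}\t{sizes}\t{starts}\n"
                )
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Local alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One local alignment with dual 0-based half-open forward-strand coordinates."""

    query_id: str
    q_start: int
    q_end: int
    target_id: str
    t_start: int
    t_end: int
    strand: str = "+"
    identity_pct: float = 100.0
    aligned_length: int = 0
    e_value: float | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"invalid query interval [{self.q_start},{self.q_end})")
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(f"invalid target interval [{self.t_start},{self.t_end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity {self.identity_pct} outside [0,100]")
        if self.aligned_length == 0:
            self.aligned_length = max(self.q_end - self.q_start, self.t_end - self.t_start)
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("e_value must be non-negative")


def _parse_tab12_line(cols: list[str], path, lineno: int) -> AlignmentRecord:
    qid, tid = cols[0], cols[1]
    try:
        ident = float(cols[2])
        aln_len = int(cols[3])
        qs, qe = int(cols[6]), int(cols[7])
        ts, te = int(cols[8]), int(cols[9])
        evalue = float(cols[10])
        bitscore = float(cols[11])
    except ValueError as exc:
        raise FileFormatError(f"{path}:{lineno}: malformed numeric field") from exc
    if min(qs, qe, ts, te) < 1:
        raise FileFormatError(f"{path}:{lineno}: coordinates must be positive (1-based)")
    strand = "+"
    if ts > te:
        ts, te = te, ts
        strand = "-"
    if qs > qe:
        raise FileFormatError(f"{path}:{lineno}: query start > end (query is always forward)")
    return AlignmentRecord(
        query_id=qid, q_start=qs - 1, q_end=qe,
        target_id=tid, t_start=ts - 1, t_end=te,
        strand=strand, identity_pct=ident, aligned_length=aln_len,
        e_value=evalue, score=bitscore,
    )


def _parse_paf_line(cols: list[str], path, lineno: int) -> AlignmentRecord:
    try:
        qid, _qlen, qs, qe = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
        strand = cols[4]
        tid, _tlen, ts, te = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
        matches, block = int(cols[9]), int(cols[10])
    except ValueError as exc:
        raise FileFormatError(f"{path}:{lineno}: malformed numeric field") from exc
    if min(qs, qe, ts, te) < 0:
        raise FileFormatError(f"{path}:{lineno}: negative coordinates")
    identity = 100.0 * matches / block if block else 0.0
    return AlignmentRecord(
        query_id=qid, q_start=qs, q_end=qe,
        target_id=tid, t_start=ts, t_end=te,
        strand=strand, identity_pct=identity, aligned_length=block,
    )


def read_alignments(path: str | Path, dialect: str = "tab12") -> list[AlignmentRecord]:
    """Read local alignments in PAF or 12-column tabular (BLAST outfmt-6-like) format.

    tab12 uses 1-based inclusive coordinates; records with target start >
    target end are normalised to forward-strand intervals with strand '-'.
    PAF identity is computed as 100 * matches / alignment_block_length.
    """
    path = Path(path)
    if dialect not in ("tab12", "paf"):
        raise ValueError(f"unknown alignment dialect: {dialect!r}")
    n_cols = 12
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "tab12" and len(cols) != n_cols:
                raise FileFormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            if dialect == "paf" and len(cols) < n_cols:
                raise FileFormatError(f"{path}:{lineno}: expected >=12 PAF columns, got {len(cols)}")
            if dialect == "tab12":
                records.append(_parse_tab12_line(cols, path, lineno))
            else:
                records.append(_parse_paf_line(cols, path, lineno))
    return records


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records as 12-column tabular with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for r in records:
            ts, te = r.t_start + 1, r.t_end
            if r.strand == "-":
                ts, te = te, ts
            evalue = r.e_value if r.e_value is not None else 0.0
            score = r.score if r.score is not None else 0.0
            fh.write(
                f"{r.query_id}\t{r.target_id}\t{r.identity_pct}\t{r.aligned_length}\t0\t0\t"
                f"{r.q_start + 1}\t{r.q_end}\t{ts}\t{te}\t{evalue}\t{score}\n"
            )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a table deterministically: rows sorted by the first column,
    columns in their given order, floats at 4 decimals."""
    if table is None:
        raise ValueError("table must not be None")
    df = table.copy()
    if len(df.columns) and len(df):
        df = df.sort_values(list(df.columns)[0], kind="mergesort").reset_index(drop=True)
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].round(4)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    elif format == "json":
        payload = {"columns": list(df.columns), "rows": df.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unknown report format: {format!r}")
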