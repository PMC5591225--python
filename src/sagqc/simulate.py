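"""Synthetic SAG data generator.

Emulates the statistical structure of single-cell amplified genomes from
multiple displacement amplification (MDA):

* a host reference genome with a gene annotation (defaults mirror a
  choanoflagellate-like composition: GC 0.54, 66 % coding);
* diverged strains of that reference (per-base substitutions at a chosen
  rate, plus segmental inversions) so that the ~99 % intra-strain vs
  ~95 % strain-vs-reference average-nucleotide-identity contrast can be
  regenerated on demand;
* MDA-biased read sets: the genome is split into windows, each window
  receives an i.i.d. LogNormal(0, sigma) amplification factor, and read
  start positions are drawn proportionally to the factor of their window.
  sigma is the single bias knob: sigma = 0 gives uniform (Lander-Waterman)
  coverage, large sigma gives a few hyper-amplified regions next to large
  zero-coverage deserts;
* bacterial-like contaminant genomes with their own GC content,
  contributing a configurable fraction of reads, and two-locus chimeric
  reads mimicking MDA chimerism;
* a "perfect assembler" that turns ground-truth read placements into
  contigs (maximal intervals at or above a depth cutoff), so downstream
  recovery stages can be tested without an external assembler.

Every operation is deterministic under the config seed, and every read
carries a ground-truth origin label.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import AlignmentRecord, Gene, GeneAnnotation, SequenceSet
from .sequtil import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {ord(b): i for i, b in enumerate("ACGT")}


@dataclass
class SimConfig:
    """Parameters of one synthetic SAG experiment.

    Defaults reproduce the composition of the reference organism the
    toolkit was designed around: 54 % GC, 66 % coding, 240 bp reads.
    """

    genome_length: int = 500_000
    gc_content: float = 0.54
    n_genes: int | None = None  # default: one gene per ~1.1 kb of coding sequence
    coding_fraction: float = 0.66
    min_gene_length: int = 300
    read_length: int = 240
    target_depth: float = 20.0
    window: int = 2_000
    sigma: float = 0.0
    contaminant_genomes: Sequence[tuple[int, float]] = ()
    contaminant_read_fraction: float = 0.0
    chimera_rate: float = 0.0
    subst_rate: float = 0.0
    inversions: Sequence[tuple[int, int]] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_genes is None:
            self.n_genes = max(1, round(self.genome_length * self.coding_fraction / 1_100))
        for name in ("gc_content", "coding_fraction", "chimera_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 <= self.contaminant_read_fraction < 1.0):
            raise ValueError("contaminant_read_fraction must be in [0,1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.window > self.genome_length:
            raise ValueError("window must be <= genome_length")
        if not (0.0 <= self.subst_rate < 0.2):
            raise ValueError("subst_rate must be in [0, 0.2)")


@dataclass
class StrainTruth:
    """Ground truth of a mutated strain."""

    mutated_positions: dict[str, np.ndarray]
    inversion_intervals: list[tuple[str, int, int]]


@dataclass
class SagSimTruth:
    """Ground-truth labels emitted with a simulated read set."""

    read_origin: dict[str, str]  # read_id -> 'host' | 'contaminant_k' | 'chimeric'
    read_true_interval: dict[str, tuple[str, int, int]]
    read_strand: dict[str, str]
    window_factors: dict[str, np.ndarray]
    contaminant_genomes: SequenceSet

    def origin_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.read_origin.values():
            out[o] = out.get(o, 0) + 1
        return out


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(_BASES, size=length, p=p)
    return codes.tobytes().decode("ascii")


def simulate_reference(config: SimConfig) -> tuple[SequenceSet, GeneAnnotation]:
    """Generate an i.i.d. genome with non-overlapping gene spans.

    Gene spans total exactly ``round(coding_fraction * genome_length)``
    bases; each gene is a single-CDS interval of at least
    ``min_gene_length`` bases.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = random_sequence(rng, L, config.gc_content)
    genome = SequenceSet({"ref_1": seq})

    n = config.n_genes
    coding_total = int(round(config.coding_fraction * L))
    if n * config.min_gene_length > coding_total:
        raise ValueError(
            f"coding_fraction {config.coding_fraction} unachievable with {n} genes "
            f"of minimum length {config.min_gene_length}"
        )
    extra = coding_total - n * config.min_gene_length
    gene_lens = config.min_gene_length + rng.multinomial(extra, np.full(n, 1.0 / n))
    gaps = rng.multinomial(L - coding_total, np.full(n + 1, 1.0 / (n + 1)))
    ann = GeneAnnotation()
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        start, end = pos, pos + int(gene_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(Gene(f"g{i + 1:05d}", "ref_1", strand, ((start, end),)))
        pos = end
    return genome, ann


def mutate_strain(
    genome: SequenceSet,
    subst_rate: float,
    inversions: Sequence[tuple] = (),
    seed: int = 0,
) -> tuple[SequenceSet, StrainTruth]:
    """Substitute each base (to a different base) with probability
    ``subst_rate``, then reverse-complement the listed intervals.

    Inversions are ``(start, end)`` pairs on the first sequence, or
    ``(seq_id, start, end)`` triples; they must be disjoint.
    """
    if not (0.0 <= subst_rate < 0.2):
        raise ValueError("subst_rate must be in [0, 0.2)")
    first_id = next(iter(genome))
    triples: list[tuple[str, int, int]] = []
    for inv in inversions:
        if len(inv) == 2:
            triples.append((first_id, int(inv[0]), int(inv[1])))
        else:
            triples.append((str(inv[0]), int(inv[1]), int(inv[2])))
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for sid, s, e in triples:
        if not (0 <= s < e <= genome.length(sid)):
            raise ValueError(f"inversion [{s},{e}) out of range on {sid!r}")
        by_seq.setdefault(sid, []).append((s, e))
    for sid, ivals in by_seq.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping inversions on {sid!r}")

    rng = np.random.default_rng(seed)
    mutated = SequenceSet()
    mut_positions: dict[str, np.ndarray] = {}
    for sid, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        idx = np.nonzero(rng.random(arr.size) < subst_rate)[0]
        if idx.size:
            base_idx = np.array([_BASE_INDEX.get(b, -1) for b in arr[idx]])
            ok = base_idx >= 0  # leave N untouched
            idx = idx[ok]
            base_idx = base_idx[ok]
            offsets = rng.integers(1, 4, size=idx.size)
            arr[idx] = _BASES[(base_idx + offsets) % 4]
        out = arr.tobytes().decode("ascii")
        for s, e in sorted(by_seq.get(sid, [])):
            out = out[:s] + revcomp(out[s:e]) + out[e:]
        mutated.add(sid, out)
        mut_positions[sid] = idx
    truth = StrainTruth(mut_positions, sorted(triples))
    return mutated, truth


def simulate_mda_reads(genome: SequenceSet, config: SimConfig) -> tuple[SequenceSet, SagSimTruth]:
    """Draw an MDA-biased read set from ``genome`` (plus contaminants).

    Host read starts are drawn with probability proportional to the
    LogNormal(0, sigma) factor of their containing window; contaminant
    reads are uniform over contaminant genomes generated here from the
    (length, gc) specs in the config; a ``chimera_rate`` fraction of host
    reads are junctions of two uniformly chosen loci.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    G = genome.total_length
    n_total = int(round(config.target_depth * G / rl))
    n_contam = int(round(config.contaminant_read_fraction * n_total))
    n_host = n_total - n_contam
    n_chim = int(round(config.chimera_rate * n_host))

    # Per-window amplification factors, then per-valid-start weights.
    window_factors: dict[str, np.ndarray] = {}
    start_seqs: list[str] = []
    start_weights: list[np.ndarray] = []
    start_offsets: list[int] = []
    for sid, seq in genome.items():
        n_win = max(1, -(-len(seq) // config.window))
        factors = (
            rng.lognormal(0.0, config.sigma, n_win)
            if config.sigma > 0
            else np.ones(n_win)
        )
        window_factors[sid] = factors
        n_valid = len(seq) - rl + 1
        if n_valid <= 0:
            continue
        w = factors[np.arange(n_valid) // config.window]
        start_seqs.append(sid)
        start_weights.append(w)
        start_offsets.append(n_valid)
    if not start_weights:
        raise ValueError("no sequence long enough to draw reads from")
    weights = np.concatenate(start_weights)
    prob = weights / weights.sum()
    bounds = np.cumsum(start_offsets)

    def locate(flat: int) -> tuple[str, int]:
        k = int(np.searchsorted(bounds, flat, side="right"))
        prev = 0 if k == 0 else int(bounds[k - 1])
        return start_seqs[k], flat - prev

    # Contaminant genomes.
    contam = SequenceSet()
    for k, (clen, cgc) in enumerate(config.contaminant_genomes, start=1):
        contam.add(f"contam_{k}", random_sequence(rng, int(clen), float(cgc)))

    reads = SequenceSet()
    origin: dict[str, str] = {}
    true_interval: dict[str, tuple[str, int, int]] = {}
    strand_of: dict[str, str] = {}
    counter = 0

    def emit(seq: str, orig: str, interval=None) -> None:
        nonlocal counter
        counter += 1
        rid = f"r{counter:07d}"
        minus = rng.random() < 0.5
        reads.add(rid, revcomp(seq) if minus else seq)
        origin[rid] = orig
        strand_of[rid] = "-" if minus else "+"
        if interval is not None:
            true_interval[rid] = interval

    # Host reads (biased starts), a fraction of them chimeric.
    flat_starts = rng.choice(weights.size, size=n_host, p=prob) if n_host else np.array([], int)
    chim_flags = np.zeros(n_host, dtype=bool)
    if n_chim:
        chim_flags[rng.choice(n_host, size=n_chim, replace=False)] = True
    for flat, is_chim in zip(flat_starts, chim_flags):
        if is_chim:
            h1 = rl // 2
            sid1, s1 = locate(int(rng.choice(weights.size)))
            sid2, s2 = locate(int(rng.choice(weights.size)))
            seq = genome[sid1][s1:s1 + h1] + genome[sid2][s2:s2 + (rl - h1)]
            emit(seq, "chimeric")
        else:
            sid, s = locate(int(flat))
            emit(genome[sid][s:s + rl], "host", (sid, s, s + rl))

    # Contaminant reads: genome chosen proportional to length, start uniform.
    if n_contam:
        if not len(contam):
            raise ValueError("contaminant_read_fraction > 0 but no contaminant_genomes given")
        cl = np.array([max(1, contam.length(c) - rl + 1) for c in contam], dtype=float)
        cids = contam.ids()
        picks = rng.choice(len(cids), size=n_contam, p=cl / cl.sum())
        for k in picks:
            sid = cids[int(k)]
            s = int(rng.integers(0, max(1, contam.length(sid) - rl + 1)))
            emit(contam[sid][s:s + rl], sid, (sid, s, min(s + rl, contam.length(sid))))

    truth = SagSimTruth(origin, true_interval, strand_of, window_factors, contam)
    return reads, truth


def perfect_assembler(
    truth: SagSimTruth,
    source_genome: SequenceSet,
    min_depth: int = 1,
) -> tuple[SequenceSet, dict[str, tuple[str, int, int]]]:
    """Idealised assembler over ground-truth read placements.

    Contigs are maximal intervals of ``source_genome`` whose truth-placed
    read depth is >= ``min_depth``; sequence is copied verbatim from the
    sampled genome.  Chimeric reads never contribute.  Contig ids encode
    their source coordinates.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    contigs = SequenceSet()
    cmap: dict[str, tuple[str, int, int]] = {}
    for sid in source_genome:
        L = source_genome.length(sid)
        delta = np.zeros(L + 1, dtype=np.int64)
        for rid, (r_sid, s, e) in truth.read_true_interval.items():
            if r_sid != sid or truth.read_origin[rid] == "chimeric":
                continue
            delta[s] += 1
            delta[min(e, L)] -= 1
        depth = np.cumsum(delta[:-1])
        mask = depth >= min_depth
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        for s, e in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
            cid = f"{sid}:{int(s)}-{int(e)}"
            contigs.add(cid, source_genome[sid][int(s):int(e)])
            cmap[cid] = (sid, int(s), int(e))
    return contigs, cmap


@dataclass
class SagScenario:
    """One fully simulated SAG experiment, ready for every pipeline stage."""

    config: SimConfig
    reference: SequenceSet
    annotation: GeneAnnotation
    strain: SequenceSet
    strain_truth: StrainTruth
    reads: SequenceSet
    truth: SagSimTruth
    scaffolds: SequenceSet
    scaffold_origin: dict[str, str]        # contig id -> 'host' | 'contam_k'
    scaffold_map: dict[str, tuple[str, int, int]]
    taxonomy: "object"                     # pandas DataFrame of anchor hits


def simulate_scenario(config: SimConfig, min_depth: int = 1) -> SagScenario:
    """Reference + diverged strain + MDA reads + perfectly assembled
    scaffolds (host and contaminant) + anchor taxonomy hits.

    The strain (substitutions + inversions per the config) is what the
    cell "really" carries; reads are drawn from it, and host contigs are
    copied from it, so scaffold-to-reference alignments show the
    strain-vs-reference divergence.  The largest host contig and the
    largest contig of each contaminant genome receive a taxonomy anchor
    hit, mimicking the scaffolds that find a database match.
    """
    import pandas as pd

    reference, annotation = simulate_reference(config)
    strain, strain_truth = mutate_strain(
        reference, config.subst_rate, config.inversions, seed=config.seed + 1
    )
    reads, truth = simulate_mda_reads(strain, replace(config, seed=config.seed + 2))

    host_contigs, host_map = perfect_assembler(truth, strain, min_depth=min_depth)
    contam_contigs, contam_map = (
        perfect_assembler(truth, truth.contaminant_genomes, min_depth=min_depth)
        if len(truth.contaminant_genomes)
        else (SequenceSet(), {})
    )

    scaffolds = SequenceSet()
    origin: dict[str, str] = {}
    smap: dict[str, tuple[str, int, int]] = {}
    for cid, seq in host_contigs.items():
        scaffolds.add(cid, seq)
        origin[cid] = "host"
        smap[cid] = host_map[cid]
    for cid, seq in contam_contigs.items():
        scaffolds.add(cid, seq)
        origin[cid] = contam_map[cid][0]
        smap[cid] = contam_map[cid]

    anchors = []
    host_ids = [c for c in scaffolds if origin[c] == "host"]
    if host_ids:
        largest = max(host_ids, key=scaffolds.length)
        anchors.append({"scaffold_id": largest, "taxon": "host_species",
                        "e_value": 1e-50, "bit_score": 500.0})
    for gid in truth.contaminant_genomes:
        cids = [c for c in scaffolds if origin[c] == gid]
        if cids:
            largest = max(cids, key=scaffolds.length)
            anchors.append({"scaffold_id": largest, "taxon": f"bacterium_{gid}",
                            "e_value": 1e-40, "bit_score": 400.0})
    taxonomy = pd.DataFrame(
        anchors, columns=["scaffold_id", "taxon", "e_value", "bit_score"]
    )

    return SagScenario(
        config=config, reference=reference, annotation=annotation,
        strain=strain, strain_truth=strain_truth, reads=reads, truth=truth,
        scaffolds=scaffolds, scaffold_origin=origin, scaffold_map=smap,
        taxonomy=taxonomy,
    )


def alignments_from_truth(
    truth: SagSimTruth,
    read_length: int | None = None,
    origins: tuple[str, ...] = ("host",),
) -> list[AlignmentRecord]:
    """Idealised read-to-reference alignments derived from truth placements.

    Stands in for an external read mapper in desk-scale tests: every
    non-chimeric read of the requested origins maps once, full-length, at
    its true locus.
    """
    records = []
    for rid, (sid, s, e) in sorted(truth.read_true_interval.items()):
        if truth.read_origin[rid] not in origins:
            continue
        records.append(
            AlignmentRecord(
                query_id=rid, q_start=0, q_end=e - s,
                target_id=sid, t_start=s, t_end=e,
                strand=truth.read_strand[rid], identity_pct=100.0,
                aligned_length=e - s,
            )
        )
    return records
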