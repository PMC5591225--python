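# Methods

This note documents the models and conventions behind `sagqc`: what the
synthetic data generator emulates, the exact definitions of each metric,
the numerical choices made where the design was genuinely open, and what
the desk-scale tests do and do not demonstrate about real data.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open on the forward strand.
GFF3 (1-based closed) and 12-column tabular alignments (1-based
inclusive; target start > end encodes the minus strand) are converted at
the IO boundary. Minus-strand alignment records are stored with
forward-strand intervals plus a strand flag, so interval arithmetic never
sees strand while inversion detection still can.

Interval sets are kept as sorted disjoint lists; touching intervals merge
(half-open semantics). Depth profiles are dense integer arrays — the
references this toolkit targets are at most tens of megabases, and the
synthetic tests stay ≤ 1 Mb, so a sparse mode is deliberately out of
scope. `merge`, `intersect`, `jaccard` and `depth` are cross-checked
against per-base boolean-array oracles in the test suite; the Jaccard of
two empty sets is an error rather than a value.

## The MDA simulator

The generator does not attempt to model the phi29 amplification mechanism
(branch structure, primer bias); it reproduces the *statistical
signature* that matters for evaluation:

* **Reference genome** — i.i.d. bases at a configurable GC (default
  0.54) with non-overlapping single-CDS gene spans totalling the coding
  fraction (default 0.66) exactly; both defaults mirror the
  choanoflagellate-like composition the toolkit was designed around.
  Default gene density is one gene per ~1.1 kb of coding sequence,
  minimum gene length 300 bp.
* **Strain divergence** — each base substitutes to a *different* base
  with probability `subst_rate`, so the expected mismatch fraction equals
  the rate and ANI ≈ 100·(1 − rate); disjoint intervals can be
  reverse-complemented to plant inversions. Rates of 0.01 and 0.05
  regenerate the ~99 % intra-strain vs ~95 % strain-vs-reference ANI
  contrast.
* **Amplification bias** — the genome is tiled into windows (default
  2 kb) and each window receives an i.i.d. LogNormal(0, σ) factor; read
  start positions are drawn proportionally to their window's factor. σ is
  the single bias knob: σ = 0 reproduces Lander–Waterman coverage, and
  the heavy right tail at large σ yields >1000× spikes beside
  zero-coverage deserts. Total read count is
  `round(depth · G / read_length)` (read length defaults to 240 bp).
* **Contamination and chimeras** — contaminant genomes are generated
  from (length, GC) specs and contribute a fixed read fraction, drawn
  uniformly; a `chimera_rate` fraction of host reads are two-locus joins
  with uniform breakpoints. Every read carries a ground-truth origin
  label and (for non-chimeric reads) its true interval.
* **Perfect assembler** — contigs are the maximal intervals whose
  truth-placed read depth reaches `min_depth`, copied verbatim from the
  sampled genome. It isolates the recovery metrics from assembler
  behaviour; an external assembler can be substituted through a command
  template (`{reads_in}`, `{outdir}`).

Reads are error-free by default: the toolkit evaluates *recovery*, not
base accuracy. Quality scores, paired-end insert-size structure and
sequencing error are not simulated, so passing tests say nothing about
base-level artefacts in real data — only about the geometry of coverage,
contamination and divergence.

**Bias calibration.** For the three-SAG scenario used in the acceptance
checks (a low-bias, a high-bias, and a high-contamination SAG), σ was
calibrated on seeded replicates until the qualitative breadth ordering of
the motivating study regime was stable: σ = 1.5 / 4.5 / 2.0 with
contaminant read fractions 0.43 / 0.16 / 0.92 at 60× total depth and
1 kb windows reproduce, in 20/20 seeds, the counter-intuitive signature
in which the SAG with the *highest* mapped-read percentage has the
*lowest* genome breadth. With fewer windows or shallower depth the
ordering is noise-dominated.

## Metric definitions and numerical choices

* **Saturation** — the curve is "saturated" when the relative assembly
  length gain between the two largest read fractions is < 5 % (a
  configurable stand-in for reading the plateau off the curve by eye).
  Contigs shorter than 500 bp are excluded wherever assemblies are
  measured, matching the scaffold filter used everywhere else. Read
  pairs (ids ending `/1`/`/2` or `_1`/`_2`) are subsampled as units;
  nested subsets share one shuffle so the chain property holds exactly.
* **TNF screen** — 4-mers are collapsed with their reverse complements
  into 136 canonical classes (strand invariance of contigs); windows are
  5 kb non-overlapping from scaffolds ≥ 10 kb, windows with > 10 % N are
  skipped, rows are frequency-normalised only. Clustering is PCA (10
  components) + k-means over k ∈ {1..4}, picking the best mean
  silhouette and falling back to one cluster below 0.25 — a
  deterministic, dependency-light replacement for self-organising-map
  visual binning. Taxonomy labels anchor clusters; unannotated scaffolds
  inherit their cluster's anchored label, otherwise stay `unknown`.
* **Taxonomy rule** — "first hit" is interpreted as the best-scoring hit
  after the e-value < 1e−5 filter, ties broken by higher bit score, then
  lower e-value, then lexicographic taxon, for determinism.
* **GC bimodality** — a two-component Gaussian mixture on per-window GC;
  flagged bimodal iff component means differ by > 0.05 and both weights
  exceed 0.10 (invented, configurable thresholds replacing a dedicated
  GC-segmentation tool).
* **16S OTUs** — hit regions ≥ 300 bp at ≥ 80 % identity are extracted
  by iterated infix alignment with masking, oriented to the query
  strand, and clustered greedily longest-first at 97 % global identity
  (the conventional OTU threshold; configurable).
* **ANI** — after the identity/e-value filter, overlapping or touching
  alignments are merged per coordinate system and the merged interval
  carries the *unweighted mean* of its constituents' identities (a
  length-weighted variant sits behind a flag); the ANI is the
  length-weighted mean over merged intervals. Because query-side and
  target-side alignment lengths differ, both are reported; the headline
  pairwise value is the conservative minimum of the two. Records without
  e-values (the internal aligner) pass the e-value filter with a logged
  notice.
* **Internal chunk aligner** — fixed-size query chunks (default 1 kb)
  are placed as infixes in the target by edit distance (both strands),
  identity = 1 − dist / max(chunk, span). Exact for substitution-only
  divergence, slightly conservative under indels; it exists so strains
  and perfect contigs can be aligned without an external aligner, and is
  *not* a general-purpose aligner — real analyses should import PAF or
  tabular alignments from a dedicated tool.
* **Gene completeness** — measured on the CDS union by default (the
  thresholds are about coding sequence); a gene-span mode is available
  because the choice is genuinely ambiguous. Counts at descending
  thresholds are monotone by construction and property-tested.
* **Inversions** — alignment blocks ≥ 1 kb (suppressing micro-alignment
  strand noise) are ordered along each scaffold; each adjacent
  discordant-strand pair on one reference sequence yields a breakpoint =
  the reference interval strictly between the two projections;
  overlapping projections and cross-sequence discordance produce no
  call.
* **Annotation Jaccard** — computed on merged gene bodies by default
  (CDS mode behind a flag); projecting SAG gene models onto reference
  coordinates through alignment chains is the caller's responsibility,
  and unprojectable genes should be dropped and counted.
* **Marker search** — markers are searched as their representative
  (first taxon, ungapped) against all six frames with local affine-gap
  alignment (BLOSUM62, first gap residue −11, extension −1; codons
  containing N translate to X). The recovery threshold of 60 score units
  is a calibrated stand-in for an unspecified historical criterion:
  planted 70-residue markers score in the hundreds while the best local
  score of an 80-residue marker against ~500 residues of random
  six-frame translation stays well below 60 (0/50 seeded replicates).
  Recovered residues are mapped through the representative onto the
  marker's alignment columns; unrecovered markers contribute all-gap
  blocks, giving exact ungapped-position accounting per taxon row.
* **Assembly statistics** — N50 is the length of the scaffold at which
  the cumulative sorted-descending length first *strictly exceeds* half
  the total (so for lengths {1000, 500, 500} the N50 is 500); L75 is the
  number of scaffolds needed to reach 75 %. Both use scaffolds ≥ 500 bp.

## Pipeline order

Contaminant exclusion precedes every reference-facing metric: GC,
recovery, gene completeness and ANI are computed on the cleaned scaffold
set, because contaminants distort all of them. Disabling the screen is
allowed but flagged in the summary. Runs are deterministic under a fixed
seed and config: summaries are byte-identical across reruns, and every
output carries the config hash.

## Problem sizes

The test suite and the acceptance script run on genomes of 20–200 kb at
depths of 6–60×, sizes chosen so the full suite completes in well under
a minute while every statistical check retains comfortable margins
(binomial noise on a 100 kb ANI comparison is ~0.01 percentage points
against tolerances of 0.3–0.4). Nothing in the implementation depends on
these sizes; the dense depth arrays are the only O(genome) memory.

## Known limitations

* The simulator's bias model is phenomenological; it reproduces coverage
  unevenness, not the amplification mechanism, and the σ values mapping
  to any particular real SAG must be fitted per dataset.
* The internal chunk aligner under-reports identity around indels and
  finds only the single best placement per chunk; repeats and segmental
  duplications need a real aligner.
* TNF clustering assumes compositionally distinct contaminants; a
  contaminant with host-like GC and 4-mer usage will pass the screen and
  can only be caught by taxonomy.
* Marker recovery uses a single representative per marker rather than a
  profile; highly diverged homologs may be missed at the default
  threshold.
* Gene prediction, read trimming, de novo assembly, database searches,
  domain scanning and tree inference are consumed as inputs or delegated
  to external tools by design.
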