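# Methods

## Scope and model

`drs3p` analyses the 3′ ends of nanopore direct-RNA reads for a two-condition,
replicated design. Three per-gene/per-condition statistics are computed:
the full-length read ratio, the median poly(A) tail length (PAL), and the
relative-expression-difference (RED) score for alternative polyadenylation
(APA). Basecalling, error correction, alignment and the raw-signal poly(A)
estimation are upstream of this package: inputs are coordinate-level
alignments (BAM or a TSV dialect), a `nanopolish polya`-style per-read PAL
table, and a GFF3 annotation.

## Coordinates and gene models

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive GFF3 convention happens only at parse/write boundaries,
so no positional rule ever carries an off-by-one adjustment. Multi-isoform
genes are collapsed to one representative transcript — the longest summed
exon length, ties broken by lexicographically smallest transcript id —
because every downstream rule (translation start, most-3′ exon) is applied
per gene. The "translation start" is the first base of the annotated start
codon (the 5′-most CDS base in transcription order), not the transcription
start. Genes lacking exons or CDS are skipped with a warning; malformed
coordinates abort with the offending line number.

## Read assignment

A read is assigned to the gene whose genomic span it overlaps by the most
bases, requiring matching strand (DRS is strand-of-origin; antisense 3′
ends would corrupt PAS calls). Overlap is measured against the gene span,
not exon intersection, because direct-RNA reads may retain introns. Reads
with no overlapping gene or with an exact tie between two genes are left
unassigned (`Unassigned_NoFeature` / `Unassigned_Ambiguity`) and never
enter downstream statistics; fractional assignment is deliberately avoided
so per-gene read sets stay integral. A MAPQ filter exists but defaults to
off.

## Full-length classification

A read is full-length when its 5′ terminal aligned base reaches the
translation start in transcription order (`five_prime <= cds_start + slack`
on `+`, mirrored on `−`). `slack` defaults to 0 nt; it exists because
completeness criteria in the literature vary in their tolerance window.
Reads of genes without CDS annotation are excluded from both numerator and
denominator. Condition-level ratios pool replicate counts
(Σ full / Σ total), not replicate ratios.

## Differential PAL

Per gene, the PAL is the median over assigned QC-PASS reads (standard order
statistic; mean of the central pair for even n). For the two-condition
comparison, replicates are pooled within condition and read-level PALs are
compared with the two-sided Mann–Whitney rank-sum test — chosen for
robustness to the right-skewed, heavy-tailed PAL distributions; the test is
exact at small n and rank-based, so adding a constant to all PALs never
changes p. A gene is differential when p < α (default 0.05) and the ratio
of condition medians strictly exceeds 1.5. Genes with fewer than
`min_reads` (default 10) PASS reads in either condition are excluded from
testing rather than reported as non-significant. A zero median on exactly
one side yields an infinite fold change flagged for review, never an
automatic call. No multiple-testing correction enters the decision rule; a
Benjamini–Hochberg column is emitted for diagnostics.

## PAS clustering and APA

Each read's PAS is its 3′ terminal aligned base. Per gene, positions are
pooled across all samples (so both conditions share one cluster frame) and
chained by single linkage: sorted positions join the current cluster while
the gap to the previous position is ≤ 24 nt. Single linkage is the standard
reading of "within 24 nt of each other" in PAS-cluster work; a max-diameter
alternative would split long chains but is not implemented. The cluster
representative is the member position with the highest read count, ties
broken toward the most-3′ position in transcription order (conservatively
favouring the longer 3′UTR); clusters with fewer than 3 supporting reads in
total are discarded. Counts are normalized to RPM against each sample's
total of assigned reads. The per-gene denominator variant would cancel
inside RED, so the library-level denominator only affects reported RPM
values, never significance.

APA is assessed on the most-3′ exon: among retained clusters whose
representative lies on it, the two with the highest RPM summed across both
conditions (so library depth cannot pick the pair) define the proximal
(nearer the stop codon in transcription order) and distal site. Per
condition, RED = log2(dPAS/pPAS) on summed replicate RPM, and
ΔRED = |RED₁ − RED₂|; significance requires ΔRED > log2(1.3) ≈ 0.3785,
the ">30 % change" rule on the usage ratio (the literal reading ΔRED > 0.3
is available via `red_threshold`). Each of the two clusters must carry at
least `min_support` reads in each condition; otherwise the gene is
not-testable — this subsumes a zero-count guard, and no pseudocounts are
used. The condition with the smaller RED (relatively more proximal usage)
is reported as the shorter-3′UTR condition.

ΔRED is a thresholded effect size, not a test statistic: at per-site
condition depth n the sampling noise of a log2 count ratio is roughly
√(2/p + 2/d)/ln 2, so null genes cross the log2(1.3) threshold with
appreciable probability below ~250 reads per site per condition. The
pipeline reports all testable genes so users can see this; the calibration
scenarios in the tests quantify it (≈ 2–4 % false calls at depth 250/site,
tens of percent at depth 50/site).

## Synthetic data generator

The generator emulates exactly the statistical structure the analyses
consume, with all latent variables written to truth tables:

- **Layout** — 200 genes (default) on 2 chromosomes, 2–4 exons of
  300–800 bp, introns 200–500 bp, random strand, CDS start 30–150 nt into
  the first transcription exon, two truth PAS on the most-3′ exon separated
  by 150 nt (must exceed the 24-nt gap plus twice the jitter bound so truth
  sites can never merge).
- **Reads** — per gene and sample, the PAS is drawn from the gene's
  condition-specific two-site mixture, the aligned 3′ end adds rounded
  normal jitter (σ = 3 nt, clipped at ±10); the 5′ end reaches the
  transcript start with the condition's completeness probability, otherwise
  a uniform truncation point strictly 3′ of the start codon; PAL is
  log-normal parameterized by the target median; QC fails with probability
  0.05.
- **Effects (default scenario)** — condition 1 ("callus"-like) has
  completeness 0.8 vs 0.6, a global 1.1× PAL factor (below the 1.5
  fold-change gate, so it shifts the global median without creating calls),
  15 % of genes PAL-differential at fold 2.0 (80 % longer in condition 1),
  and 15 % of genes APA-shifted from 50/50 to 80/20 proximal usage
  (ΔRED = 2.0; 75 % shorter in condition 1). These choices reproduce the
  qualitative signature of an undifferentiated vs differentiated tissue
  pair: higher completeness, longer tails, shorter 3′UTRs.
- **PAL noise** — log-normal σ = 0.2, set so that at a depth of 200 reads a
  per-gene sample median estimates its target to within ±5 nt essentially
  always; real PAL distributions are broader and more multimodal, which the
  generator does not attempt.

Fixed seed ⇒ byte-identical outputs (a `numpy` `SeedSequence` child per
sample; all discrete draws integer-based). Alignments are emitted both as
the TSV dialect and as sorted, indexed BAM so both ingest paths are
exercised.

What passing on synthetic data does **not** show: robustness to alignment
artefacts at 3′ ends (the generator's jitter is symmetric and bounded),
internal priming, intronic/internal APA (sites are only placed on the
terminal exon), isoform-level effects, or PAL estimation error from the raw
signal (PALs are drawn, not estimated).

## Numerical and degenerate-input choices

- Median: numpy order statistic, linear interpolation irrelevant (mean of
  central pair at even n).
- Rank-sum: scipy's implementation (exact at small tie-free n, normal
  approximation with continuity correction otherwise).
- Empty inputs: empty PAS list → no clusters; empty sample after filtering
  → all-NA summary row with a warning, exit 0.
- RPM with a zero assigned-read total is a fatal configuration error.
- Determinism: all tables are written in sorted, stable order; re-running
  a pipeline on identical inputs is byte-identical.

## Problem sizes

The shipped analysis uses 200 genes × 4 samples × 50 reads (~40,000 reads);
the calibration scenarios use up to 400 genes at 250 reads per gene and
sample. These sizes put every Monte-Carlo bound comfortably inside its
binomial error bars while keeping a full run in seconds on one CPU; all
counts scale linearly in `SyntheticConfig`.

## Known limitations

- Gene-span overlap assignment cannot separate overlapping same-strand
  genes and ignores splice compatibility.
- The ΔRED rule has no significance test attached (by design); shallow
  genes produce threshold crossings from count noise alone.
- One representative transcript per gene; isoform-level APA and PAL are out
  of scope.
- The two-proportion z-test attached to the full-length comparison is an
  auxiliary report, not part of any decision rule.
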