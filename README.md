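# drs3p — 3′-end analysis of nanopore direct-RNA reads

`drs3p` compares the mRNA 3′ ends of two tissues from nanopore direct RNA
sequencing (DRS): an undifferentiated, regenerable tissue (callus) against
stem-differentiating xylem. Because DRS reads native RNA 3′→5′, each read
carries its poly(A) tail signal and its aligned 3′ end marks the cleavage
and polyadenylation site. From coordinate-level alignments, per-read
poly(A)-length calls (the `nanopolish polya` report) and a GFF3 annotation,
the package computes three readouts per tissue:

1. **Full-length ratio** — a read is full-length when its 5′ aligned end
   reaches the annotated translation start of its gene.
2. **Differential poly(A) tail length (PAL)** — the per-gene PAL is the
   median over assigned QC-PASS reads; conditions are compared per gene
   with a two-sided Mann–Whitney rank-sum test on read-level PALs, and a
   gene is differential when *p* < 0.05 and the median fold change
   exceeds 1.5.
3. **Alternative polyadenylation (APA)** — per-read polyadenylation sites
   (PAS) within 24 nt of each other are chained into clusters; clusters
   need support from ≥ 3 reads, and counts are RPM-normalized. On the
   most-3′ exon the two most abundant clusters define a proximal (pPAS)
   and distal (dPAS) site, and per condition the relative expression
   difference is

   RED_c = log2(dPAS_c / pPAS_c),  ΔRED = |RED₁ − RED₂|.

   A gene's 3′UTR length changes significantly when ΔRED > log2(1.3),
   i.e. a > 30 % change in the distal/proximal usage ratio; the condition
   with the smaller RED has the shorter 3′UTR.

Reads are assigned to genes by largest same-strand overlap with the gene
span (ambiguous ties and antisense overlaps are discarded), mirroring
gene-level long-read counting.

A synthetic-data generator (`drs3p.synthetic`) emulates the full study
design — two conditions × two replicates, per-gene log-normal PAL
distributions, two-site PAS usage mixtures, 3′-end jitter, per-read QC
failure and condition-specific 5′ completeness — with every latent choice
recorded in truth tables, so each statistic can be validated against what
was injected.

## Worked example

```bash
python analysis/01_simulate.py      # default scenario, 200 genes, 40,000 reads
python analysis/02_run_pipeline.py  # full analysis with published thresholds
python analysis/03_summarize.py     # condition summary + truth reconciliation
python analysis/04_figures.py       # optional diagnostic plots (scratch/figures)
```

or, equivalently, through the CLI: `drs3p simulate`, `drs3p run`,
`drs3p summarize`. The summarize step prints (seed 42):

```
condition  full_length_ratio  global_pal_median  n_pal_longer  n_apa_shorter_3putr
   callus             0.7991           104.6475            27                   59
    xylem             0.6002            88.6200             6                   35

differential PAL: 33/33 injected fold changes recovered, 0 extra calls on null genes
APA: 31/31 injected usage shifts recovered, 63 extra calls on null genes (count noise at this depth)
```

Reading this: the callus-like condition shows the higher full-length ratio
(0.80 vs 0.60, matching the configured completeness probabilities), longer
poly(A) tails (global median of per-gene medians 105 vs 89 nt), and more
genes with a significantly shorter 3′UTR (59 vs 35) — the three
direction-of-effect signatures of the undifferentiated tissue. All injected
PAL fold changes and APA usage shifts are recovered; the extra APA calls on
null genes reflect multinomial count noise around the ΔRED threshold at 100
reads per condition and gene (see `docs/methods.md`).

Every published threshold (24-nt gap, ≥ 3-read support, α = 0.05, fold
change 1.5, ΔRED log2(1.3), slack 0) is a named parameter of
`PipelineConfig` / a CLI flag, and the run manifest records the full filter
funnel (total → primary → Assigned → PASS counts per sample).

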