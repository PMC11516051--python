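#!/usr/bin/env python
"""Generate the default two-condition synthetic dataset.

Writes a callus-like vs xylem-like scenario (200 genes, 2 replicates per
condition, 50 reads per gene per sample, ~40,000 reads total) with full
ground truth under results/simulated/: GFF3 annotation, per-sample
alignment TSVs and BAMs, nanopolish-dialect poly(A) tables, truth tables
and a sample sheet.
"""

from pathlib import Path

from drs3p.synthetic import SyntheticConfig, write_scenario

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SyntheticConfig(seed=42)
    outdir = ROOT / "results" / "simulated"
    paths = write_scenario(cfg, outdir)
    n_reads = cfg.n_genes * cfg.reads_per_gene * len(cfg.sample_ids)
    print(f"wrote {cfg.n_genes} genes and {n_reads} reads for samples:")
    for sid, cond, rep in cfg.sample_ids:
        print(f"  {sid} ({cond}, replicate {rep})")
    print(f"annotation: {paths.gff3}")
    print(f"sample sheet: {paths.sample_sheet}")
    print(f"ground truth: {paths.gene_truth}, {paths.read_truth}")


if __name__ == "__main__":
    main()
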