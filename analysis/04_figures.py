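#!/usr/bin/env python
"""Diagnostic figures for the simulated run (optional artifacts).

Draws the full-length ratio bars, per-condition PAL violins, the
differential-PAL volcano and the per-condition RED scatter from the
pipeline tables, mirroring the standard readouts of a two-tissue 3'-end
comparison. Figures go to scratch/figures/ and feed no decision.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    run = ROOT / "results" / "pipeline"
    outdir = ROOT / "scratch" / "figures"
    outdir.mkdir(parents=True, exist_ok=True)

    fl = pd.read_csv(run / "full_length_summary.tsv", sep="\t")
    fl = fl[~fl["sample_id"].str.startswith("pooled:")]
    fig, ax = plt.subplots(figsize=(4, 3))
    colors = {"callus": "tab:green", "xylem": "tab:brown"}
    ax.bar(fl["sample_id"], 100 * fl["ratio"], color=[colors[c] for c in fl["condition"]])
    ax.set_ylabel("full-length reads (%)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(outdir / "full_length_ratio.png", dpi=150)

    pal = pd.read_csv(run / "gene_pal.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(4, 3))
    data = [pal.loc[pal["condition"] == c, "median_pal"].dropna() for c in colors]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks([1, 2], list(colors))
    ax.set_ylabel("per-gene median PAL (nt)")
    fig.tight_layout()
    fig.savefig(outdir / "pal_violins.png", dpi=150)

    dpal = pd.read_csv(run / "differential_pal.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(4, 3))
    x = np.log2(dpal["median_callus"] / dpal["median_xylem"])
    y = -np.log10(dpal["p_value"].clip(lower=1e-300))
    ax.scatter(x, y, s=8, c=np.where(dpal["significant"], "tab:red", "0.7"))
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, c="k")
    for fc in (1.5, 1 / 1.5):
        ax.axvline(np.log2(fc), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 median PAL (callus/xylem)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(outdir / "pal_volcano.png", dpi=150)

    apa = pd.read_csv(run / "apa_results.tsv", sep="\t")
    apa = apa[apa["testable"]]
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(
        apa["red_callus"],
        apa["red_xylem"],
        s=8,
        c=np.where(apa["significant"], "tab:red", "0.7"),
    )
    lim = max(apa["red_callus"].abs().max(), apa["red_xylem"].abs().max()) + 0.5
    ax.plot([-lim, lim], [-lim, lim], lw=0.8, c="k")
    ax.set_xlabel("RED (callus)")
    ax.set_ylabel("RED (xylem)")
    fig.tight_layout()
    fig.savefig(outdir / "red_scatter.png", dpi=150)

    print(f"figures written to {outdir}")


if __name__ == "__main__":
    main()
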