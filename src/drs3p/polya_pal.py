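"""Per-read poly(A)-length ingest and per-gene differential PAL.

Poly(A) tail lengths (PAL) are read from the tab-separated report of the
nanopolish ``polya`` subcommand; only reads whose segmentation passed QC
(``qc_tag == "PASS"``) are used. The per-gene PAL is the median over all
assigned PASS reads of that gene. Two conditions are compared per gene with
a two-sided Mann-Whitney rank-sum test on the read-level PALs (replicates
pooled within condition); a gene is called differential when p < 0.05 and
the ratio of condition medians exceeds 1.5 (strictly).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("readname", "polya_length", "qc_tag")


class PolyATableError(ValueError):
    """Fatal problem with a poly(A) call table."""


@dataclass(frozen=True)
class PolyACallRecord:
    read_id: str
    polya_length: float
    qc_tag: str

    def __post_init__(self) -> None:
        if self.polya_length < 0:
            raise ValueError(f"negative poly(A) length for {self.read_id}")


def load_polya_table(path: str | Path) -> pd.DataFrame:
    """Load a nanopolish-polya-dialect TSV, keeping PASS records only.

    Returns a DataFrame with columns ``read_id`` and ``polya_length``.
    Duplicate read names are resolved by keeping the first PASS occurrence,
    with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PolyATableError(f"{path}: missing required column(s): {missing}")
    df = df[df["qc_tag"] == "PASS"]
    n_dup = df["readname"].duplicated().sum()
    if n_dup:
        logger.warning("%s: %d duplicate read name(s); keeping first occurrence", path, n_dup)
        df = df.drop_duplicates(subset="readname", keep="first")
    out = df[["readname", "polya_length"]].rename(columns={"readname": "read_id"})
    return out.reset_index(drop=True)


def gene_pal(
    assignments: pd.DataFrame,
    polya: pd.DataFrame,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Per-gene PAL summary for one sample.

    ``assignments`` must carry Assigned reads only (columns read_id,
    gene_id); ``polya`` the PASS records (read_id, polya_length). A gene
    observed with fewer than ``min_reads`` PASS reads is reported with an
    undefined (NaN) median.
    """
    merged = assignments.merge(polya, on="read_id", how="inner")
    grp = merged.groupby("gene_id")["polya_length"]
    out = grp.agg(n="size", median_pal="median").reset_index()
    out.loc[out["n"] < min_reads, "median_pal"] = np.nan
    return out


@dataclass(frozen=True)
class PALTestResult:
    """Differential-PAL call for one gene between two conditions."""

    n_a: int
    n_b: int
    median_a: float
    median_b: float
    fold_change: float  # >= 1, orientation in `longer_in`
    longer_in: str  # "a", "b" or "none"
    p_value: float
    significant: bool
    review: bool = False  # zero median on one side only


def differential_pal(
    pals_a: Sequence[float],
    pals_b: Sequence[float],
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    min_reads: int = 10,
) -> PALTestResult | None:
    """Test one gene's read-level PALs between two conditions.

    Returns ``None`` (gene excluded from testing, not "non-significant")
    when either condition has fewer than ``min_reads`` reads. Fold change
    is the ratio of the larger to the smaller condition median; the call is
    significant only when the rank-sum p-value is below ``alpha`` AND the
    fold change strictly exceeds ``fc_threshold``. A zero median on exactly
    one side gives an infinite fold change flagged for review rather than
    an automatic call.
    """
    a = np.asarray(pals_a, dtype=float)
    b = np.asarray(pals_b, dtype=float)
    if a.size < min_reads or b.size < min_reads:
        return None
    med_a = float(np.median(a))
    med_b = float(np.median(b))
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if med_a == med_b:
        fc, longer = 1.0, "none"
    elif med_a > med_b:
        fc = math.inf if med_b == 0 else med_a / med_b
        longer = "a"
    else:
        fc = math.inf if med_a == 0 else med_b / med_a
        longer = "b"
    review = math.isinf(fc)
    significant = (not review) and p < alpha and fc > fc_threshold
    return PALTestResult(
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=med_a,
        median_b=med_b,
        fold_change=fc,
        longer_in=longer,
        p_value=p,
        significant=significant,
        review=review,
    )


def differential_pal_table(
    pal_by_gene_a: dict[str, Sequence[float]],
    pal_by_gene_b: dict[str, Sequence[float]],
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Differential-PAL table over all genes testable in both conditions.

    Columns are suitable for a volcano plot; an optional Benjamini-Hochberg
    adjusted p (``padj``) is emitted alongside the raw-p decision rule.
    """
    rows = []
    for gene in sorted(set(pal_by_gene_a) & set(pal_by_gene_b)):
        res = differential_pal(
            pal_by_gene_a[gene], pal_by_gene_b[gene], alpha, fc_threshold, min_reads
        )
        if res is None:
            continue
        rows.append(
            {
                "gene_id": gene,
                f"n_{cond_a}": res.n_a,
                f"n_{cond_b}": res.n_b,
                f"median_{cond_a}": res.median_a,
                f"median_{cond_b}": res.median_b,
                "fold_change": res.fold_change,
                "longer_in": {"a": cond_a, "b": cond_b, "none": "none"}[res.longer_in],
                "p_value": res.p_value,
                "significant": res.significant,
                "review": res.review,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            f"n_{cond_a}",
            f"n_{cond_b}",
            f"median_{cond_a}",
            f"median_{cond_b}",
            "fold_change",
            "longer_in",
            "p_value",
            "significant",
            "review",
        ],
    )
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["padj"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["padj"] = pd.Series(dtype=float)
    return df
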