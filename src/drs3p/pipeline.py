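"""End-to-end orchestration: ingest -> assignment -> full-length -> PAL -> PAS/APA.

Runs the whole 3'-end analysis for a two-condition sample sheet and writes
stable TSV/BED outputs plus a run manifest with the filter funnel (total,
primary, Assigned, PASS counts) so every filtering lever is auditable.
Outputs are deterministic: re-running on identical inputs reproduces
byte-identical primary tables.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import read_gff3
from .alignment_ingest import (
    ASSIGNED,
    SampleSheet,
    assignment_table,
    assign_reads_to_genes,
    load_alignments,
)
from .full_length import FullLengthSummary, full_length_ratio, pool_summaries
from .pas_apa import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_SUPPORT,
    DEFAULT_RED_THRESHOLD,
    build_gene_clusters,
    call_apa,
    clusters_to_bed6,
)
from .polya_pal import differential_pal_table, load_polya_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the published rules."""

    sample_sheet: str = ""
    annotation: str = ""
    outdir: str = "drs3p_run"
    max_gap: int = DEFAULT_MAX_GAP
    min_support: int = DEFAULT_MIN_SUPPORT
    alpha: float = 0.05
    fc_threshold: float = 1.5
    red_threshold: float = DEFAULT_RED_THRESHOLD
    min_reads: int = 10
    slack: int = 0
    min_mapq: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_gap", "min_support", "alpha", "fc_threshold", "red_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunBundle:
    """In-memory handles to every table the pipeline wrote."""

    config: PipelineConfig
    outdir: Path
    conditions: tuple[str, str]
    assignments: dict[str, pd.DataFrame]  # sample_id -> per-read table
    full_length: pd.DataFrame
    gene_pal: pd.DataFrame
    differential_pal: pd.DataFrame
    apa: pd.DataFrame
    manifest: dict[str, object]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunBundle:
    """Execute every stage and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet = SampleSheet.read_tsv(config.sample_sheet)
    conditions = sheet.conditions
    if len(conditions) != 2:
        raise ValueError(
            f"differential stages need exactly 2 conditions, got {list(conditions)}"
        )
    c1, c2 = conditions
    genes = read_gff3(config.annotation)
    gene_map = {g.gene_id: g for g in genes}

    manifest: dict[str, object] = {
        "version": __version__,
        "annotation": str(config.annotation),
        "annotation_sha256": _sha256(config.annotation),
        "n_genes": len(genes),
    }
    for k, v in asdict(config).items():
        manifest[f"config.{k}"] = v

    assignments: dict[str, pd.DataFrame] = {}
    fl_rows: list[FullLengthSummary] = []
    sample_condition: dict[str, str] = {}
    totals_assigned: dict[str, int] = {}
    pal_frames = []
    pas_reads: dict[str, list[tuple[str, int]]] = {}  # gene -> (sample, pas)

    for sample in sheet.samples:
        sample_condition[sample.sample_id] = sample.condition
        reads = list(
            assign_reads_to_genes(
                load_alignments(sample.alignment_path, min_mapq=config.min_mapq), genes
            )
        )
        table = assignment_table(reads)
        assignments[sample.sample_id] = table
        n_total = len(table)
        n_assigned = int((table["status"] == ASSIGNED).sum())
        totals_assigned[sample.sample_id] = n_assigned
        manifest[f"counts.{sample.sample_id}.total_reads"] = n_total
        manifest[f"counts.{sample.sample_id}.assigned"] = n_assigned
        manifest[f"counts.{sample.sample_id}.alignment_sha256"] = _sha256(sample.alignment_path)

        assigned_reads = [r for r in reads if r.status == ASSIGNED]
        fl = full_length_ratio(
            assigned_reads, gene_map, sample.sample_id, sample.condition, slack=config.slack
        )
        fl_rows.append(fl)

        if sample.polya_path is None:
            logger.warning(
                "sample %s has no poly(A) table; PAL/PAS stages skipped for it",
                sample.sample_id,
            )
            manifest[f"counts.{sample.sample_id}.pass"] = 0
            continue
        polya = load_polya_table(sample.polya_path)
        manifest[f"counts.{sample.sample_id}.pass"] = len(polya)
        assigned_tbl = table[table["status"] == ASSIGNED][["read_id", "gene_id"]]
        merged = assigned_tbl.merge(polya, on="read_id", how="inner")
        manifest[f"counts.{sample.sample_id}.assigned_pass"] = len(merged)
        pal_frames.append(
            merged.assign(sample_id=sample.sample_id, condition=sample.condition)
        )
        # PAS positions from Assigned+PASS reads
        read_pas = table.merge(merged[["read_id"]], on="read_id")
        for row in read_pas.itertuples(index=False):
            pas = row.end - 1 if row.strand == "+" else row.start
            pas_reads.setdefault(row.gene_id, []).append((sample.sample_id, pas))

    # --- full-length summaries
    fl_all = fl_rows + [pool_summaries(fl_rows, c) for c in conditions]
    fl_df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "n_full": s.n_full,
                "n_total": s.n_total,
                "ratio": s.ratio,
            }
            for s in fl_all
        ]
    )

    # --- per-gene PAL and differential PAL (replicates pooled per condition)
    if pal_frames:
        pal_long = pd.concat(pal_frames, ignore_index=True)
        gene_pal_df = (
            pal_long.groupby(["gene_id", "sample_id", "condition"])["polya_length"]
            .agg(n="size", median_pal="median")
            .reset_index()
            .sort_values(["gene_id", "sample_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        by_cond = {
            cond: {
                g: grp["polya_length"].to_numpy()
                for g, grp in pal_long[pal_long["condition"] == cond].groupby("gene_id")
            }
            for cond in conditions
        }
        dpal = differential_pal_table(
            by_cond[c1],
            by_cond[c2],
            c1,
            c2,
            alpha=config.alpha,
            fc_threshold=config.fc_threshold,
            min_reads=config.min_reads,
        )
    else:
        gene_pal_df = pd.DataFrame(
            columns=["gene_id", "sample_id", "condition", "n", "median_pal"]
        )
        dpal = pd.DataFrame()

    # --- PAS clustering and APA
    clusters_all = []
    apa_rows = []
    for gene_id in sorted(pas_reads):
        gene = gene_map[gene_id]
        clusters = build_gene_clusters(
            gene,
            pas_reads[gene_id],
            totals_assigned,
            max_gap=config.max_gap,
            min_support=config.min_support,
        )
        clusters_all.extend(clusters)
        res = call_apa(
            gene,
            clusters,
            sample_condition,
            (c1, c2),
            red_threshold=config.red_threshold,
            min_support=config.min_support,
        )
        apa_rows.append(
            {
                "gene_id": res.gene_id,
                "testable": res.testable,
                "reason": res.reason,
                "ppas": res.ppas_pos if res.ppas_pos is not None else -1,
                "dpas": res.dpas_pos if res.dpas_pos is not None else -1,
                f"p_{c1}": res.p1,
                f"d_{c1}": res.d1,
                f"p_{c2}": res.p2,
                f"d_{c2}": res.d2,
                f"red_{c1}": res.red_1,
                f"red_{c2}": res.red_2,
                "delta_red": res.delta_red,
                "significant": res.significant,
                "shorter_3putr_in": res.shorter_in,
            }
        )
    apa_df = pd.DataFrame(apa_rows)
    manifest["counts.genes_pal_tested"] = int(len(dpal))
    manifest["counts.genes_apa_tested"] = (
        int(apa_df["testable"].sum()) if len(apa_df) else 0
    )
    manifest["counts.genes_apa_not_testable"] = (
        int((~apa_df["testable"]).sum()) if len(apa_df) else 0
    )
    manifest["counts.pas_clusters_retained"] = len(clusters_all)

    # --- write bundle
    for sid, table in assignments.items():
        table.to_csv(outdir / f"{sid}.assignments.tsv", sep="\t", index=False)
    fl_df.to_csv(outdir / "full_length_summary.tsv", sep="\t", index=False)
    gene_pal_df.to_csv(outdir / "gene_pal.tsv", sep="\t", index=False)
    dpal.to_csv(outdir / "differential_pal.tsv", sep="\t", index=False)
    apa_df.to_csv(outdir / "apa_results.tsv", sep="\t", index=False)
    with open(outdir / "pas_clusters.bed", "w") as fh:
        fh.write(clusters_to_bed6(clusters_all))
    with open(outdir / "manifest.txt", "w") as fh:
        for k in sorted(manifest):
            fh.write(f"{k}={manifest[k]}\n")

    bundle = RunBundle(
        config=config,
        outdir=outdir,
        conditions=(c1, c2),
        assignments=assignments,
        full_length=fl_df,
        gene_pal=gene_pal_df,
        differential_pal=dpal,
        apa=apa_df,
        manifest=manifest,
    )
    summarize_run(bundle).to_csv(outdir / "condition_summary.tsv", sep="\t", index=False)
    return bundle


def summarize_run(bundle: RunBundle) -> pd.DataFrame:
    """One row per condition: full-length ratio, global PAL median, and
    counts of significant differential-PAL and APA genes by direction."""
    c1, c2 = bundle.conditions
    rows = []
    dpal, apa = bundle.differential_pal, bundle.apa
    for cond in bundle.conditions:
        pooled = bundle.full_length[bundle.full_length["sample_id"] == f"pooled:{cond}"]
        ratio = float(pooled["ratio"].iloc[0]) if len(pooled) else math.nan
        gp = bundle.gene_pal[bundle.gene_pal["condition"] == cond]
        global_med = float(gp["median_pal"].median()) if len(gp) else math.nan
        n_pal_longer = (
            int(((dpal["significant"]) & (dpal["longer_in"] == cond)).sum())
            if len(dpal)
            else 0
        )
        n_apa_shorter = (
            int(((apa["significant"]) & (apa["shorter_3putr_in"] == cond)).sum())
            if len(apa)
            else 0
        )
        rows.append(
            {
                "condition": cond,
                "full_length_ratio": ratio,
                "global_pal_median": global_med,
                "n_pal_longer": n_pal_longer,
                "n_apa_shorter_3putr": n_apa_shorter,
            }
        )
    df = pd.DataFrame(rows)
    if df["full_length_ratio"].isna().all() and df["global_pal_median"].isna().all():
        logger.warning("summary is all-NA: no reads survived filtering")
    return df
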