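"""Synthetic two-condition direct-RNA 3'-end data with full ground truth.

Emulates the statistical structure the downstream analyses assume: per-gene
poly(A)-length (PAL) distributions, two-site polyadenylation (PAS) usage
mixtures on the most-3' exon, 3'-end positional jitter, per-read QC
failure, and condition-specific 5'-completeness probabilities. Every latent
choice (gene, chosen site, jittered 3' end, PAL, completeness, QC tag) is
recorded in truth tables so each downstream statistic can be checked
against what was injected.

The default scenario mirrors the biology it stands in for qualitatively:
condition 1 ("callus"-like, undifferentiated) has the higher completeness
probability, longer PAL medians, and higher proximal-PAS usage (hence
shorter 3'UTRs) than condition 2 ("xylem"-like).

No sequence is simulated — alignments are genomic spans only, which is all
the 3'-end analyses consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation_io import GeneModel, GenomicInterval, write_gff3

_FAIL_TAGS = ("ADAPTER", "SUFFCLIP", "READ_FAILED_LOAD")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults define the standard scenario."""

    n_genes: int = 200
    n_chroms: int = 2
    seed: int = 42
    conditions: tuple[str, str] = ("callus", "xylem")
    n_replicates: int = 2
    reads_per_gene: int = 50  # per sample

    # genome layout
    gene_spacing: int = 2000
    exon_count_range: tuple[int, int] = (2, 4)
    exon_length_range: tuple[int, int] = (300, 800)
    intron_length_range: tuple[int, int] = (200, 500)
    cds_offset_range: tuple[int, int] = (30, 150)  # from transcript 5' end

    # 3'-end model
    pas_separation: int = 150  # proximal-to-distal distance (> cluster gap)
    pas_margin: int = 25  # distal site offset from the exon 3' edge
    jitter_sd: float = 3.0  # nt, rounded normal
    jitter_bound: int = 10  # hard clip keeps truth clusters cleanly apart

    # PAL model (log-normal; median parameterized)
    pal_base_range: tuple[float, float] = (60.0, 120.0)
    pal_sigma: float = 0.2
    pal_global_factor: float = 1.1  # condition-1 medians scaled up, all genes
    frac_pal_diff: float = 0.15
    pal_diff_fc: float = 2.0
    frac_pal_longer_in_c1: float = 0.8  # among differential genes

    # APA model
    null_prox_usage: float = 0.5
    frac_apa_shift: float = 0.15
    shifted_prox_usage: float = 0.8  # in the shorter-3'UTR condition
    frac_apa_shorter_in_c1: float = 0.75

    # nuisance
    completeness: tuple[float, float] = (0.8, 0.6)  # per condition
    qc_fail_prob: float = 0.05

    def __post_init__(self) -> None:
        for p in (
            *self.completeness,
            self.qc_fail_prob,
            self.null_prox_usage,
            self.shifted_prox_usage,
            self.frac_pal_diff,
            self.frac_apa_shift,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.pas_separation <= 24 + 2 * self.jitter_bound:
            raise ValueError("pas_separation must exceed max_gap + 2*jitter_bound")

    @property
    def sample_ids(self) -> list[tuple[str, str, int]]:
        """(sample_id, condition, replicate) in deterministic order."""
        out = []
        for ci, cond in enumerate(self.conditions):
            for rep in range(1, self.n_replicates + 1):
                out.append((f"{cond}_rep{rep}", cond, rep))
        return out

    @property
    def delta_red_target(self) -> float:
        """|log2(d/p)| shift injected into APA-shifted genes."""
        q_s, q_n = self.shifted_prox_usage, self.null_prox_usage
        return abs(math.log2((1 - q_s) / q_s) - math.log2((1 - q_n) / q_n))


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], pd.DataFrame, dict[str, int]]:
    """Lay out genes with known CDS starts and two truth PAS per gene.

    Returns the gene models, a per-gene truth table (effect flags, target
    PAL medians, PAS positions and usage proportions), and chromosome
    lengths for alignment headers.
    """
    rng = np.random.default_rng(config.seed)
    c1, c2 = config.conditions
    cursors = {f"chr{i + 1}": 1000 for i in range(config.n_chroms)}
    genes: list[GeneModel] = []
    rows = []
    for gi in range(config.n_genes):
        chrom = f"chr{gi % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        cds_offset = int(rng.integers(*config.cds_offset_range))
        # exon lengths in transcription order; first holds the start codon,
        # last must fit both PAS sites plus jitter headroom
        lengths = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, size=n_exons
        ).tolist()
        lengths[0] = max(lengths[0], cds_offset + 60)
        lengths[-1] = max(
            lengths[-1], config.pas_separation + config.pas_margin + config.jitter_bound + 40
        )
        introns = rng.integers(
            config.intron_length_range[0], config.intron_length_range[1] + 1, size=n_exons - 1
        ).tolist()
        genomic_lengths = lengths if strand == "+" else lengths[::-1]
        genomic_introns = introns if strand == "+" else introns[::-1]
        start = cursors[chrom]
        exons = []
        pos = start
        for i, L in enumerate(genomic_lengths):
            exons.append(GenomicInterval(chrom, pos, pos + L, strand))
            pos += L
            if i < len(genomic_introns):
                pos += genomic_introns[i]
        gene_end = exons[-1].end
        cursors[chrom] = gene_end + config.gene_spacing

        tx_first = exons[0] if strand == "+" else exons[-1]
        tx_last = exons[-1] if strand == "+" else exons[0]
        if strand == "+":
            cds_start = tx_first.start + cds_offset
            dist_pas = tx_last.end - 1 - config.pas_margin
            prox_pas = dist_pas - config.pas_separation
        else:
            cds_start = tx_first.end - 1 - cds_offset
            dist_pas = tx_last.start + config.pas_margin
            prox_pas = dist_pas + config.pas_separation

        gene_id = f"gene{gi:04d}"
        gene = GeneModel(
            gene_id=gene_id,
            interval=GenomicInterval(chrom, start, gene_end, strand),
            exons=tuple(exons),
            cds_start=cds_start,
            transcript_id=f"{gene_id}.t1",
        )
        genes.append(gene)

        # injected effects
        pal_base = float(rng.uniform(*config.pal_base_range))
        pal_diff = rng.random() < config.frac_pal_diff
        pal_longer_in = ""
        med = {c1: pal_base * config.pal_global_factor, c2: pal_base}
        if pal_diff:
            pal_longer_in = c1 if rng.random() < config.frac_pal_longer_in_c1 else c2
            med[pal_longer_in] *= config.pal_diff_fc
        apa_shift = rng.random() < config.frac_apa_shift
        apa_shorter_in = ""
        prox_usage = {c1: config.null_prox_usage, c2: config.null_prox_usage}
        if apa_shift:
            apa_shorter_in = c1 if rng.random() < config.frac_apa_shorter_in_c1 else c2
            prox_usage[apa_shorter_in] = config.shifted_prox_usage
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "tss": gene.tss,
                "cds_start": cds_start,
                "most3p_exon_start": gene.most3p_exon.start,
                "most3p_exon_end": gene.most3p_exon.end,
                "prox_pas": prox_pas,
                "dist_pas": dist_pas,
                f"pal_median_{c1}": med[c1],
                f"pal_median_{c2}": med[c2],
                "pal_diff": pal_diff,
                "pal_longer_in": pal_longer_in,
                f"prox_usage_{c1}": prox_usage[c1],
                f"prox_usage_{c2}": prox_usage[c2],
                "apa_shift": apa_shift,
                "apa_shorter_in": apa_shorter_in,
                "delta_red_target": config.delta_red_target if apa_shift else 0.0,
            }
        )
    chrom_lengths = {c: cur + 1000 for c, cur in cursors.items()}
    return genes, pd.DataFrame(rows), chrom_lengths


def simulate_sample(
    config: SyntheticConfig,
    genes: list[GeneModel],
    gene_truth: pd.DataFrame,
    sample_id: str,
    condition: str,
    sample_index: int,
) -> pd.DataFrame:
    """Simulate one sample's reads; returns the per-read truth table.

    Columns: read_id, chrom, start, end, strand (the alignment) plus the
    latent gene, chosen site, truth/jittered PAS, completeness, PAL and QC
    tag. Reads stay within their gene's span, so the latent gene is also
    the expected largest-overlap assignment.
    """
    rng = np.random.default_rng([config.seed, 7919 + sample_index])
    ci = config.conditions.index(condition)
    completeness = config.completeness[ci]
    truth = gene_truth.set_index("gene_id")
    frames = []
    n = config.reads_per_gene
    min_len = 30  # shortest truncated read
    for gene in genes:
        t = truth.loc[gene.gene_id]
        prox_p = float(t[f"prox_usage_{condition}"])
        median = float(t[f"pal_median_{condition}"])
        is_prox = rng.random(n) < prox_p
        site = np.where(is_prox, int(t["prox_pas"]), int(t["dist_pas"]))
        if config.jitter_sd > 0:
            jitter = np.rint(rng.normal(0.0, config.jitter_sd, n)).astype(int)
            jitter = np.clip(jitter, -config.jitter_bound, config.jitter_bound)
        else:
            jitter = np.zeros(n, dtype=int)
        pas_obs = site + jitter
        complete = rng.random(n) < completeness
        pal = np.round(rng.lognormal(math.log(median), config.pal_sigma, n), 2)
        qc_fail = rng.random(n) < config.qc_fail_prob
        tags = np.where(
            qc_fail, rng.choice(_FAIL_TAGS, size=n), "PASS"
        )
        cds = gene.cds_start
        if gene.strand == "+":
            hi = np.maximum(pas_obs - min_len, cds + 1)
            five = np.where(complete, gene.tss, rng.integers(cds + 1, hi + 1))
            start, end = five, pas_obs + 1
        else:
            lo = np.minimum(pas_obs + min_len, cds - 1)
            five = np.where(complete, gene.tss, rng.integers(lo, cds))
            start, end = pas_obs, five + 1
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [
                        f"{sample_id}:{gene.gene_id}:{j:04d}" for j in range(n)
                    ],
                    "chrom": gene.chrom,
                    "start": start.astype(int),
                    "end": end.astype(int),
                    "strand": gene.strand,
                    "gene_id": gene.gene_id,
                    "site": np.where(is_prox, "proximal", "distal"),
                    "pas_truth": site,
                    "pas_obs": pas_obs,
                    "complete": complete,
                    "pal": pal,
                    "qc_tag": tags,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(1, "sample_id", sample_id)
    df.insert(2, "condition", condition)
    return df


def write_alignment_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads[["read_id", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


def write_bam(reads: pd.DataFrame, chrom_lengths: dict[str, int], path: str | Path) -> None:
    """Emit the simulated spans as a coordinate-sorted, indexed BAM."""
    path = str(path)
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    ordered = reads.sort_values(["chrom", "start", "read_id"], kind="mergesort")
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for row in ordered.itertuples(index=False):
            seg = pysam.AlignedSegment()
            seg.query_name = row.read_id
            seg.flag = 16 if row.strand == "-" else 0
            seg.reference_id = tid[row.chrom]
            seg.reference_start = int(row.start)
            seg.mapping_quality = 60
            seg.cigartuples = [(0, int(row.end) - int(row.start))]
            bam.write(seg)
    pysam.index(path)


def write_polya_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    """Emit the nanopolish-polya report dialect (all reads, PASS and failed)."""
    df = pd.DataFrame(
        {
            "readname": reads["read_id"],
            "contig": reads["chrom"],
            "position": reads["start"],
            "leader_start": 0,
            "adapter_start": 10,
            "polya_start": 40,
            "transcript_start": 100,
            "read_rate": 70.0,
            "polya_length": reads["pal"],
            "qc_tag": reads["qc_tag"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ScenarioPaths:
    outdir: Path
    gff3: Path
    gene_truth: Path
    read_truth: Path
    sample_sheet: Path


def write_scenario(
    config: SyntheticConfig, outdir: str | Path, with_bam: bool = True
) -> ScenarioPaths:
    """Generate and write a full scenario: annotation, per-sample alignment
    TSV (and optionally BAM), poly(A) tables, truth tables and sample sheet.
    """
    from .alignment_ingest import Sample, SampleSheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, gene_truth, chrom_lengths = generate_annotation(config)
    gff3 = outdir / "annotation.gff3"
    write_gff3(genes, gff3)
    gene_truth_path = outdir / "gene_truth.tsv"
    gene_truth.to_csv(gene_truth_path, sep="\t", index=False)

    samples = []
    all_reads = []
    for si, (sample_id, condition, rep) in enumerate(config.sample_ids):
        reads = simulate_sample(config, genes, gene_truth, sample_id, condition, si)
        all_reads.append(reads)
        aln = outdir / f"{sample_id}.alignments.tsv"
        polya = outdir / f"{sample_id}.polya.tsv"
        write_alignment_tsv(reads, aln)
        write_polya_tsv(reads, polya)
        aln_path = aln
        if with_bam:
            bam = outdir / f"{sample_id}.bam"
            write_bam(reads, chrom_lengths, bam)
        samples.append(
            Sample(
                sample_id=sample_id,
                condition=condition,
                replicate=rep,
                alignment_path=str(aln_path),
                polya_path=str(polya),
            )
        )
    read_truth = pd.concat(all_reads, ignore_index=True)
    read_truth_path = outdir / "read_truth.tsv"
    read_truth.to_csv(read_truth_path, sep="\t", index=False)
    sheet = SampleSheet(tuple(samples))
    sheet_path = outdir / "sample_sheet.tsv"
    sheet.write_tsv(sheet_path)
    return ScenarioPaths(outdir, gff3, gene_truth_path, read_truth_path, sheet_path)


def null_config(seed: int = 42, **overrides) -> SyntheticConfig:
    """A no-effect variant of the default scenario: identical PAL
    distributions, identical PAS usage and completeness in both conditions.
    """
    base = SyntheticConfig(
        seed=seed,
        frac_pal_diff=0.0,
        frac_apa_shift=0.0,
        pal_global_factor=1.0,
        completeness=(0.7, 0.7),
    )
    return replace(base, **overrides)
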