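import filecmp
import math

import numpy as np
import pandas as pd
import pytest

from drs3p.annotation_io import read_gff3
from drs3p.pas_apa import cluster_pas
from drs3p.synthetic import (
    SyntheticConfig,
    generate_annotation,
    null_config,
    simulate_sample,
    write_scenario,
)


class TestConfig:
    def test_probability_validation(self):
        with pytest.raises(ValueError, match="probability"):
            SyntheticConfig(qc_fail_prob=1.5)

    def test_pas_separation_must_clear_cluster_gap(self):
        with pytest.raises(ValueError, match="pas_separation"):
            SyntheticConfig(pas_separation=30)

    def test_delta_red_target_of_default_shift(self):
        # usage 0.8/0.2 vs 0.5/0.5 -> |log2(1/4) - log2(1)| = 2
        assert SyntheticConfig().delta_red_target == pytest.approx(2.0)


class TestAnnotation:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_genes=10, seed=7)
        p1 = write_scenario(cfg, tmp_path / "a", with_bam=False)
        p2 = write_scenario(cfg, tmp_path / "b", with_bam=False)
        for name in ("annotation.gff3", "gene_truth.tsv", "read_truth.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_cds_start_inside_first_transcription_exon(self):
        genes, _, _ = generate_annotation(SyntheticConfig(n_genes=40, seed=1))
        for g in genes:
            first = g.exons[0] if g.strand == "+" else g.exons[-1]
            assert first.contains(g.cds_start)

    def test_truth_pas_on_most3p_exon_both_strands(self):
        cfg = SyntheticConfig(n_genes=40, seed=2)
        genes, truth, _ = generate_annotation(cfg)
        by_id = {g.gene_id: g for g in genes}
        minus_seen = False
        for row in truth.itertuples(index=False):
            exon = by_id[row.gene_id].most3p_exon
            assert exon.contains(row.prox_pas) and exon.contains(row.dist_pas)
            if row.strand == "-":
                minus_seen = True
                # most-3' exon is the lowest-coordinate exon on the minus strand
                assert exon.start == min(e.start for e in by_id[row.gene_id].exons)
                assert row.dist_pas < row.prox_pas
        assert minus_seen

    def test_written_gff3_parses_back(self, tmp_path):
        cfg = SyntheticConfig(n_genes=15, seed=4)
        paths = write_scenario(cfg, tmp_path, with_bam=False)
        assert len(read_gff3(paths.gff3)) == 15


class TestReads:
    def test_full_completeness_all_full_length(self):
        """With completeness probability 1 every read reaches the start codon."""
        from drs3p.full_length import classify_full_length
        from drs3p.alignment_ingest import ReadAlignment
        from drs3p.annotation_io import GenomicInterval

        cfg = SyntheticConfig(n_genes=20, seed=5, completeness=(1.0, 1.0), reads_per_gene=20)
        genes, truth, _ = generate_annotation(cfg)
        by_id = {g.gene_id: g for g in genes}
        df = simulate_sample(cfg, genes, truth, "s", "callus", 0)
        for row in df.itertuples(index=False):
            r = ReadAlignment(
                row.read_id, GenomicInterval(row.chrom, row.start, row.end, row.strand)
            )
            assert classify_full_length(r, by_id[row.gene_id], slack=0)

    def test_zero_jitter_exact_two_site_recovery(self):
        """jitter 0: clustering the observed 3' ends recovers exactly the two
        truth sites of every gene."""
        cfg = SyntheticConfig(n_genes=20, seed=6, jitter_sd=0.0, reads_per_gene=60)
        genes, truth, _ = generate_annotation(cfg)
        df = simulate_sample(cfg, genes, truth, "s", "xylem", 0)
        t = truth.set_index("gene_id")
        for gene_id, grp in df.groupby("gene_id"):
            pas = grp["pas_obs"].tolist()
            clusters = cluster_pas(pas)
            sites = sorted({t.loc[gene_id, "prox_pas"], t.loc[gene_id, "dist_pas"]})
            assert sorted({cl[0] for cl in clusters}) == sites
            assert all(len(set(cl)) == 1 for cl in clusters)

    def test_truth_table_consistency(self, tiny_scenario):
        """Every emitted read appears exactly once in the truth table, and the
        alignment files carry exactly the truth spans."""
        cfg, paths = tiny_scenario
        truth = pd.read_csv(paths.read_truth, sep="\t")
        assert truth["read_id"].is_unique
        n_expected = cfg.n_genes * cfg.reads_per_gene * len(cfg.sample_ids)
        assert len(truth) == n_expected
        for sid, _, _ in cfg.sample_ids:
            aln = pd.read_csv(paths.outdir / f"{sid}.alignments.tsv", sep="\t")
            sub = truth[truth["sample_id"] == sid]
            merged = aln.merge(sub, on="read_id", suffixes=("", "_t"))
            assert len(merged) == len(sub)
            assert (merged["start"] == merged["start_t"]).all()
            assert (merged["end"] == merged["end_t"]).all()

    def test_pal_median_calibration(self):
        """Sample PAL medians at depth 200 recover target medians 80 and 120
        within +/-5 nt for nearly all genes."""
        cfg = SyntheticConfig(
            n_genes=200,
            seed=9,
            reads_per_gene=200,
            frac_pal_diff=0.0,
            pal_global_factor=1.0,
            pal_base_range=(80.0, 80.0),
            qc_fail_prob=0.0,
        )
        hits = 0
        for target, cond in ((80.0, "callus"), (120.0, "xylem")):
            cfg_t = SyntheticConfig(
                **{
                    **cfg.__dict__,
                    "pal_base_range": (target, target),
                }
            )
            genes, truth, _ = generate_annotation(cfg_t)
            df = simulate_sample(cfg_t, genes, truth, "s", cond, 0)
            med = df.groupby("gene_id")["pal"].median()
            hits += int((abs(med - target) <= 5).sum())
        assert hits / 400 >= 0.95

    def test_pas_usage_converges_to_configured(self):
        """Empirical proximal usage is within 3 standard errors of the
        configured mixture for every gene."""
        cfg = SyntheticConfig(n_genes=50, seed=10, reads_per_gene=200, frac_apa_shift=0.3)
        genes, truth, _ = generate_annotation(cfg)
        df = simulate_sample(cfg, genes, truth, "s", "callus", 0)
        t = truth.set_index("gene_id")
        for gene_id, grp in df.groupby("gene_id"):
            p = float(t.loc[gene_id, "prox_usage_callus"])
            n = len(grp)
            emp = (grp["site"] == "proximal").mean()
            se = math.sqrt(p * (1 - p) / n)
            assert abs(emp - p) <= 3.5 * se + 1e-9

    def test_qc_fail_rate_near_configured(self, tiny_scenario):
        cfg, paths = tiny_scenario
        truth = pd.read_csv(paths.read_truth, sep="\t")
        frac = (truth["qc_tag"] != "PASS").mean()
        n = len(truth)
        se = math.sqrt(cfg.qc_fail_prob * (1 - cfg.qc_fail_prob) / n)
        assert abs(frac - cfg.qc_fail_prob) <= 4 * se


def test_null_config_has_no_injected_effects():
    cfg = null_config(seed=3)
    _, truth, _ = generate_annotation(cfg)
    assert not truth["pal_diff"].any()
    assert not truth["apa_shift"].any()
    assert (truth["pal_median_callus"] == truth["pal_median_xylem"]).all()
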