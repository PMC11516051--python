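import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from drs3p.alignment_ingest import ReadAlignment
from drs3p.annotation_io import GeneModel, GenomicInterval
from drs3p.pas_apa import (
    PASCluster,
    build_gene_clusters,
    call_apa,
    cluster_pas,
    extract_read_pas,
    red_score,
    rpm_normalize,
    select_representative,
)

from conftest import oracle_cluster_transitive_closure


def make_cluster(counts, strand="+", gene_id="g"):
    return PASCluster(
        gene_id=gene_id, chrom="chr1", strand=strand, member_counts=Counter(counts)
    )


class TestExtractPAS:
    def test_plus_read(self):
        r = ReadAlignment("r", GenomicInterval("chr1", 100, 600, "+"))
        assert extract_read_pas(r) == 599

    def test_minus_read(self):
        r = ReadAlignment("r", GenomicInterval("chr1", 100, 600, "-"))
        assert extract_read_pas(r) == 100

    def test_mirror_transform_maps_pas(self):
        """Reflecting the genome through a constant maps each read's PAS to
        its mirror image."""
        C = 100_000
        rng = np.random.default_rng(8)
        for _ in range(100):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(50, 900))
            strand = "+" if rng.random() < 0.5 else "-"
            r = ReadAlignment("r", GenomicInterval("chr1", s, e, strand))
            m = ReadAlignment(
                "r", GenomicInterval("chr1", C - e, C - s, "-" if strand == "+" else "+")
            )
            assert extract_read_pas(m) == C - 1 - extract_read_pas(r)


class TestClusterPAS:
    def test_documented_example(self):
        """Gaps of 10 and 20 chain; a 40-nt gap splits."""
        positions = [100] * 5 + [110] * 2 + [130] + [170] * 4
        got = cluster_pas(positions)
        assert got == [[100] * 5 + [110] * 2 + [130], [170] * 4]

    def test_single_position_singleton(self):
        assert cluster_pas([42]) == [[42]]

    def test_empty_input(self):
        assert cluster_pas([]) == []

    def test_chaining_joins_through_middle(self):
        """0 and 40 are >24 apart but join through 20: single-linkage."""
        assert cluster_pas([0, 20, 40]) == [[0, 20, 40]]

    def test_gap_exactly_24_same_cluster(self):
        assert cluster_pas([100, 124]) == [[100, 124]]
        assert cluster_pas([100, 125]) == [[100], [125]]

    def test_matches_union_find_oracle_randomized(self):
        rng = np.random.default_rng(13)
        for _ in range(500):
            n = int(rng.integers(0, 50))
            positions = rng.integers(0, 10_000, size=n).tolist()
            assert cluster_pas(positions) == oracle_cluster_transitive_closure(positions)

    @given(st.lists(st.integers(min_value=0, max_value=3000), max_size=60), st.randoms(use_true_random=False))
    def test_invariant_under_shuffles(self, positions, rnd):
        shuffled = list(positions)
        rnd.shuffle(shuffled)
        assert cluster_pas(shuffled) == cluster_pas(positions)

    def test_output_partitions_input(self):
        rng = np.random.default_rng(21)
        positions = rng.integers(0, 2000, size=200).tolist()
        clusters = cluster_pas(positions)
        flat = [p for cl in clusters for p in cl]
        assert sorted(flat) == sorted(positions)
        starts = [cl[0] for cl in clusters]
        assert starts == sorted(starts)


class TestRepresentative:
    def test_highest_count_retained(self):
        cl = select_representative(make_cluster({100: 5, 110: 2, 130: 1}))
        assert cl is not None and cl.representative_pos == 100 and cl.support == 8

    def test_support_below_three_rejected(self):
        assert select_representative(make_cluster({200: 1, 210: 1})) is None

    def test_support_exactly_three_retained(self):
        """'At least three' reads is inclusive."""
        cl = select_representative(make_cluster({200: 2, 210: 1}))
        assert cl is not None and cl.support == 3

    def test_tie_breaks_most_3prime(self):
        assert select_representative(make_cluster({300: 2, 320: 2}, "+")).representative_pos == 320
        assert select_representative(make_cluster({300: 2, 320: 2}, "-")).representative_pos == 300


class TestRPM:
    def test_basic_scaling(self):
        assert rpm_normalize(500, 1_000_000) == 500.0

    def test_upper_bound(self):
        assert rpm_normalize(1234, 1234) == 1e6

    def test_zero_total_fatal(self):
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)

    def test_rpm_conservation_over_clusters(self):
        """Summed RPM over retained clusters is at most 1e6 per sample, with
        equality when every assigned read lands in a retained cluster."""
        gene = make_apa_gene()
        rng = np.random.default_rng(3)
        pas = [("s1", int(p)) for p in rng.integers(1000, 1060, size=50)]
        clusters = build_gene_clusters(gene, pas, {"s1": 50})
        assert sum(cl.rpm["s1"] for cl in clusters) == pytest.approx(1e6)


def make_apa_gene(strand="+"):
    # single-exon gene spanning [900, 2000); most-3' exon is the whole span
    return GeneModel(
        gene_id="g",
        interval=GenomicInterval("chr1", 900, 2000, strand),
        exons=(GenomicInterval("chr1", 900, 2000, strand),),
        cds_start=950 if strand == "+" else 1999,
    )


def build_for_apa(p1, d1, p2, d2, strand="+", prox=1000, dist=1500):
    """Two-condition, one-sample-per-condition cluster frame with given counts."""
    gene = make_apa_gene(strand)
    pas = (
        [("s1", prox)] * p1
        + [("s1", dist)] * d1
        + [("s2", prox)] * p2
        + [("s2", dist)] * d2
    )
    totals = {"s1": p1 + d1, "s2": p2 + d2}
    clusters = build_gene_clusters(gene, pas, totals)
    return gene, clusters


SAMPLE_COND = {"s1": "c1", "s2": "c2"}


class TestCallAPA:
    def test_printed_formula_arithmetic(self):
        """p1=30,d1=10 vs p2=10,d2=30 gives RED -1.585 / +1.585, dRED 3.170,
        significant, shorter 3'UTR in condition 1."""
        gene, clusters = build_for_apa(30, 10, 10, 30)
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        assert res.testable and res.significant
        assert res.red_1 == pytest.approx(-1.585, abs=1e-3)
        assert res.red_2 == pytest.approx(1.585, abs=1e-3)
        assert res.delta_red == pytest.approx(3.170, abs=1e-3)
        assert res.shorter_in == "c1"

    def test_identical_usage_not_significant(self):
        gene, clusters = build_for_apa(20, 20, 20, 20)
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        assert res.testable and res.delta_red == 0.0 and not res.significant

    def test_proximal_distal_orientation_minus_strand(self):
        """On the minus strand the proximal site is the higher coordinate."""
        gene, clusters = build_for_apa(30, 10, 10, 30, strand="-", prox=1600, dist=1100)
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        assert res.ppas_pos == 1600 and res.dpas_pos == 1100
        assert res.shorter_in == "c1"

    def test_fewer_than_two_clusters_not_testable(self):
        gene, clusters = build_for_apa(30, 0, 30, 0)
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        assert not res.testable and "fewer_than_two" in res.reason

    def test_insufficient_condition_support_not_testable(self):
        gene, clusters = build_for_apa(30, 2, 30, 30)
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        assert not res.testable and res.reason == "insufficient_per_condition_support"

    def test_condition_swap_preserves_delta_flips_direction(self):
        gene, clusters = build_for_apa(40, 10, 15, 30)
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        swapped = call_apa(
            gene, clusters, {"s1": "c2", "s2": "c1"}, ("c1", "c2")
        )
        assert swapped.delta_red == pytest.approx(res.delta_red)
        assert {res.shorter_in, swapped.shorter_in} == {"c1", "c2"}

    def test_rpm_scale_invariance(self):
        """Scaling one sample's counts and total together leaves RED and
        delta-RED unchanged."""
        gene, clusters = build_for_apa(40, 10, 15, 30)
        base = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        gene2, clusters2 = build_for_apa(400, 100, 15, 30)
        scaled = call_apa(gene2, clusters2, SAMPLE_COND, ("c1", "c2"))
        assert scaled.red_1 == pytest.approx(base.red_1)
        assert scaled.delta_red == pytest.approx(base.delta_red)

    def test_two_most_abundant_clusters_selected(self):
        """A weak third site never displaces the two dominant clusters."""
        gene = make_apa_gene()
        pas = (
            [("s1", 1000)] * 30 + [("s1", 1500)] * 20 + [("s1", 1900)] * 4
            + [("s2", 1000)] * 10 + [("s2", 1500)] * 35 + [("s2", 1900)] * 5
        )
        clusters = build_gene_clusters(gene, pas, {"s1": 54, "s2": 50})
        assert len(clusters) == 3
        res = call_apa(gene, clusters, SAMPLE_COND, ("c1", "c2"))
        assert (res.ppas_pos, res.dpas_pos) == (1000, 1500)


def test_red_algebraic_identity():
    """|log2(d1/d2) - log2(p1/p2)| equals |log2(d1/p1) - log2(d2/p2)| on
    random positive quadruples (the two printed forms of the statistic)."""
    rng = np.random.default_rng(99)
    q = rng.uniform(0.01, 1000.0, size=(1000, 4))
    for p1, d1, p2, d2 in q:
        lhs = abs(math.log2(d1 / d2) - math.log2(p1 / p2))
        rhs = abs(red_score(d1, p1) - red_score(d2, p2))
        assert abs(lhs - rhs) < 1e-12
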