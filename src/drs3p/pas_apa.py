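"""Polyadenylation-site clustering and APA calling via the RED score.

Each read's polyadenylation site (PAS) is the genomic coordinate of its 3'
terminal aligned base. Per gene, sites within 24 nt of each other are
grouped into one cluster by single-linkage chaining over the sorted
positions; the member position with the highest read count is the
representative, and a cluster is retained only with support from at least
three reads. Counts are RPM-normalized against each sample's total of
assigned reads.

Alternative polyadenylation (APA) is assessed on the most-3' exon: the two
most abundant retained clusters define a proximal (pPAS, nearer the stop
codon in transcription order) and a distal (dPAS) site. The relative
expression difference per condition is RED = log2(dPAS/pPAS) on RPM, and a
gene is called significant when |RED_1 - RED_2| exceeds log2(1.3) — a >30%
change in the distal/proximal abundance ratio between conditions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation_io import GeneModel
from .alignment_ingest import ReadAlignment

DEFAULT_MAX_GAP = 24
DEFAULT_MIN_SUPPORT = 3
DEFAULT_RED_THRESHOLD = math.log2(1.3)


def extract_read_pas(read: ReadAlignment) -> int:
    """Genomic PAS position of a read: its 3' terminal aligned base."""
    return read.three_prime_pos


def cluster_pas(positions: Iterable[int], max_gap: int = DEFAULT_MAX_GAP) -> list[list[int]]:
    """Partition a multiset of genomic positions into PAS clusters.

    Single-linkage chaining: positions are sorted and a new cluster starts
    whenever the gap to the previous distinct position exceeds ``max_gap``.
    Clusters are returned in coordinate order; each is the sorted multiset
    of its member positions.
    """
    pos = sorted(positions)
    if not pos:
        return []
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


@dataclass
class PASCluster:
    """One clustered polyadenylation site for one gene."""

    gene_id: str
    chrom: str
    strand: str
    member_counts: Counter  # position -> pooled read count
    sample_counts: dict[str, int] = field(default_factory=dict)  # sample_id -> reads
    representative_pos: int | None = None
    rpm: dict[str, float] = field(default_factory=dict)  # sample_id -> RPM

    @property
    def span(self) -> tuple[int, int]:
        return min(self.member_counts), max(self.member_counts)

    @property
    def support(self) -> int:
        return sum(self.member_counts.values())


def select_representative(cluster: PASCluster, min_support: int = DEFAULT_MIN_SUPPORT) -> PASCluster | None:
    """Pick the highest-count member position; reject weakly supported clusters.

    The representative is the position with the maximal read count, ties
    broken toward the most 3' position in transcription order (highest
    coordinate on ``+``, lowest on ``-``). Returns ``None`` when total
    support falls below ``min_support`` ("at least three" reads retained).
    """
    if cluster.support < min_support:
        return None
    max_count = max(cluster.member_counts.values())
    candidates = [p for p, c in cluster.member_counts.items() if c == max_count]
    cluster.representative_pos = max(candidates) if cluster.strand == "+" else min(candidates)
    return cluster


def rpm_normalize(count: int, total_assigned: int) -> float:
    """Reads-per-million scaling against a sample's assigned-read total."""
    if total_assigned <= 0:
        raise ValueError("total assigned reads must be positive for RPM normalization")
    return count / total_assigned * 1e6


def build_gene_clusters(
    gene: GeneModel,
    read_pas: Sequence[tuple[str, int]],
    totals: Mapping[str, int],
    max_gap: int = DEFAULT_MAX_GAP,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[PASCluster]:
    """Cluster one gene's per-read PAS positions pooled over all samples.

    ``read_pas`` holds (sample_id, position) pairs; ``totals`` the per-sample
    assigned-read counts used as RPM denominators. Clusters are defined on
    the pooled positions so both conditions share one cluster frame, then
    counted and RPM-normalized per sample. Only retained (supported)
    clusters are returned, in coordinate order.
    """
    clusters_positions = cluster_pas([p for _, p in read_pas], max_gap=max_gap)
    out: list[PASCluster] = []
    for members in clusters_positions:
        lo, hi = members[0], members[-1]
        sample_counts: Counter = Counter()
        for sample_id, p in read_pas:
            if lo <= p <= hi:
                sample_counts[sample_id] += 1
        cl = PASCluster(
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            member_counts=Counter(members),
            sample_counts=dict(sample_counts),
        )
        cl = select_representative(cl, min_support=min_support)
        if cl is None:
            continue
        cl.rpm = {s: rpm_normalize(c, totals[s]) for s, c in cl.sample_counts.items()}
        out.append(cl)
    return out


@dataclass(frozen=True)
class APAResult:
    """Differential 3'UTR-length call for one gene."""

    gene_id: str
    testable: bool
    reason: str = ""
    ppas_pos: int | None = None
    dpas_pos: int | None = None
    p1: float = float("nan")  # proximal abundance (RPM), condition 1
    d1: float = float("nan")
    p2: float = float("nan")
    d2: float = float("nan")
    red_1: float = float("nan")
    red_2: float = float("nan")
    delta_red: float = float("nan")
    significant: bool = False
    shorter_in: str = ""  # condition label with the shorter 3'UTR


def red_score(distal: float, proximal: float) -> float:
    """Relative expression difference: log2 of distal over proximal abundance."""
    return math.log2(distal / proximal)


def call_apa(
    gene: GeneModel,
    clusters: Sequence[PASCluster],
    sample_condition: Mapping[str, str],
    conditions: tuple[str, str],
    red_threshold: float = DEFAULT_RED_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> APAResult:
    """Call APA on the most-3' exon from retained clusters of one gene.

    The two clusters with the highest RPM pooled across both conditions are
    kept; the one nearer the stop codon in transcription order is proximal.
    Each cluster must carry at least ``min_support`` reads in each condition
    (so both RED ratios rest on reliable counts); otherwise the gene is
    reported not-testable. Significance: |RED_1 - RED_2| > ``red_threshold``,
    with the shorter-3'UTR condition being the one with the smaller RED.
    """
    c1, c2 = conditions
    exon = gene.most3p_exon
    on_exon = [cl for cl in clusters if cl.representative_pos is not None and exon.contains(cl.representative_pos)]
    if len(on_exon) < 2:
        return APAResult(gene.gene_id, testable=False, reason="fewer_than_two_clusters_on_most3p_exon")

    def cond_rpm(cl: PASCluster, cond: str) -> float:
        return sum(r for s, r in cl.rpm.items() if sample_condition[s] == cond)

    def cond_count(cl: PASCluster, cond: str) -> int:
        return sum(c for s, c in cl.sample_counts.items() if sample_condition[s] == cond)

    ranked = sorted(
        on_exon,
        key=lambda cl: (-(cond_rpm(cl, c1) + cond_rpm(cl, c2)), cl.representative_pos),
    )
    top2 = ranked[:2]
    # proximal = nearer the stop codon, i.e. 5'-most in transcription order
    if gene.strand == "+":
        ppas, dpas = sorted(top2, key=lambda cl: cl.representative_pos)
    else:
        dpas, ppas = sorted(top2, key=lambda cl: cl.representative_pos)

    counts = {
        (cond, which): cond_count(cl, cond)
        for cond in (c1, c2)
        for which, cl in (("p", ppas), ("d", dpas))
    }
    if any(v < min_support for v in counts.values()):
        return APAResult(
            gene.gene_id,
            testable=False,
            reason="insufficient_per_condition_support",
            ppas_pos=ppas.representative_pos,
            dpas_pos=dpas.representative_pos,
        )

    p1, d1 = cond_rpm(ppas, c1), cond_rpm(dpas, c1)
    p2, d2 = cond_rpm(ppas, c2), cond_rpm(dpas, c2)
    red1, red2 = red_score(d1, p1), red_score(d2, p2)
    delta = abs(red1 - red2)
    significant = delta > red_threshold
    shorter = ""
    if red1 != red2:
        shorter = c1 if red1 < red2 else c2
    return APAResult(
        gene_id=gene.gene_id,
        testable=True,
        ppas_pos=ppas.representative_pos,
        dpas_pos=dpas.representative_pos,
        p1=p1,
        d1=d1,
        p2=p2,
        d2=d2,
        red_1=red1,
        red_2=red2,
        delta_red=delta,
        significant=significant,
        shorter_in=shorter,
    )


def clusters_to_bed6(clusters: Iterable[PASCluster]) -> str:
    """Retained clusters as BED6: name=gene:representative, score=support."""
    lines = []
    for cl in clusters:
        lo, hi = cl.span
        lines.append(
            f"{cl.chrom}\t{lo}\t{hi + 1}\t{cl.gene_id}:{cl.representative_pos}\t"
            f"{cl.support}\t{cl.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
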