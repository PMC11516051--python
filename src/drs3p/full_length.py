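"""Full-length read classification against annotated translation starts.

A direct-RNA read is sequenced 3'->5', so 5' truncation is the common
failure mode. A read is full-length when its 5' terminal aligned base
reaches the annotated translation start of its gene in transcription order
(an optional slack loosens the anchor); reads of genes without a CDS
annotation are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import math

from scipy import stats

from .annotation_io import GeneModel
from .alignment_ingest import ReadAlignment


def classify_full_length(read: ReadAlignment, gene: GeneModel, slack: int = 0) -> bool:
    """True iff the read's 5' end reaches the translation start.

    For ``+`` genes the 5' end must lie at or upstream of ``cds_start``
    (``five_prime_pos <= cds_start + slack``); mirrored for ``-`` genes.
    """
    if gene.strand == "+":
        return read.five_prime_pos <= gene.cds_start + slack
    return read.five_prime_pos >= gene.cds_start - slack


@dataclass(frozen=True)
class FullLengthSummary:
    sample_id: str
    condition: str
    n_full: int
    n_total: int

    @property
    def ratio(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.n_full / self.n_total


def full_length_ratio(
    reads: Iterable[ReadAlignment],
    genes: Mapping[str, GeneModel],
    sample_id: str,
    condition: str,
    slack: int = 0,
) -> FullLengthSummary:
    """Classify a sample's assigned reads and summarize the full-length ratio."""
    n_full = n_total = 0
    for read in reads:
        gene = genes.get(read.assigned_gene or "")
        if gene is None:
            continue
        n_total += 1
        if classify_full_length(read, gene, slack=slack):
            n_full += 1
    return FullLengthSummary(sample_id, condition, n_full, n_total)


def pool_summaries(summaries: Sequence[FullLengthSummary], condition: str) -> FullLengthSummary:
    """Pooled condition-level summary: (sum full)/(sum total) over replicates."""
    members = [s for s in summaries if s.condition == condition]
    return FullLengthSummary(
        sample_id=f"pooled:{condition}",
        condition=condition,
        n_full=sum(s.n_full for s in members),
        n_total=sum(s.n_total for s in members),
    )


def compare_full_length(
    a: FullLengthSummary, b: FullLengthSummary
) -> tuple[float, float]:
    """Ratio difference (a - b) and a two-proportion z-test p-value.

    The test is an auxiliary report; the ratio difference is the primary
    readout.
    """
    diff = a.ratio - b.ratio
    n1, n2 = a.n_total, b.n_total
    if n1 == 0 or n2 == 0:
        return diff, float("nan")
    p_pool = (a.n_full + b.n_full) / (n1 + n2)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return diff, 1.0
    z = diff / se
    p = 2 * stats.norm.sf(abs(z))
    return diff, float(p)
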