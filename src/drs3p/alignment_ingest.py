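"""Long-read alignment ingest and gene assignment.

Reads come either from a coordinate-sorted BAM (primary records only) or
from a plain TSV dialect (read_id, chrom, start, end, strand; 0-based
half-open). Each read is assigned to the single gene whose genomic span it
overlaps by the most bases, on the same strand — the gene-level behaviour
of long-read counting. Ties and no-overlap reads are left unassigned;
direct-RNA reads are strand-of-origin, so antisense overlap never counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from intervaltree import IntervalTree

from .annotation_io import GenomicInterval, GeneModel

logger = logging.getLogger(__name__)

ASSIGNED = "Assigned"
NO_FEATURE = "Unassigned_NoFeature"
AMBIGUITY = "Unassigned_Ambiguity"

_TSV_COLUMNS = ("read_id", "chrom", "start", "end", "strand")


class AlignmentInputError(ValueError):
    """Fatal problem with an alignment input file."""


@dataclass(frozen=True)
class ReadAlignment:
    """Primary alignment span of one long read.

    The 5'/3' terminal aligned bases are derived from the span and the
    alignment orientation: a ``+`` read enters at ``start`` and ends at
    ``end - 1``; a ``-`` read the reverse.
    """

    read_id: str
    interval: GenomicInterval
    assigned_gene: str | None = field(default=None)
    overlap_bp: int = field(default=0)
    status: str = field(default=NO_FEATURE)

    @property
    def read_strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime_pos(self) -> int:
        return self.interval.start if self.read_strand == "+" else self.interval.end - 1

    @property
    def three_prime_pos(self) -> int:
        return self.interval.end - 1 if self.read_strand == "+" else self.interval.start


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    replicate: int
    alignment_path: str
    polya_path: str | None = None


@dataclass(frozen=True)
class SampleSheet:
    """Maps input files to condition labels and replicates."""

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if not self.samples:
            raise ValueError("sample sheet is empty")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return tuple(seen)

    def by_condition(self, condition: str) -> tuple[Sample, ...]:
        return tuple(s for s in self.samples if s.condition == condition)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "condition", "replicate", "alignment_path"}
        missing = required - set(df.columns)
        if missing:
            raise AlignmentInputError(f"sample sheet missing column(s): {sorted(missing)}")
        samples = []
        for row in df.itertuples(index=False):
            polya = getattr(row, "polya_path", None)
            if polya is not None and (polya != polya or polya == ""):  # NaN / empty
                polya = None
            samples.append(
                Sample(
                    sample_id=row.sample_id,
                    condition=row.condition,
                    replicate=int(row.replicate),
                    alignment_path=row.alignment_path,
                    polya_path=polya,
                )
            )
        return cls(tuple(samples))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tcondition\treplicate\talignment_path\tpolya_path\n")
            for s in self.samples:
                fh.write(
                    f"{s.sample_id}\t{s.condition}\t{s.replicate}\t"
                    f"{s.alignment_path}\t{s.polya_path or ''}\n"
                )


def load_alignments(path: str | Path, min_mapq: int = 0) -> Iterator[ReadAlignment]:
    """Yield one ReadAlignment per primary record.

    Secondary and supplementary records are dropped; BAM input must be
    coordinate-sorted and indexed. ``min_mapq`` defaults to 0 (no filter);
    MAPQ applies only to BAM input (the TSV dialect carries none).
    """
    path = Path(path)
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        yield from _load_bam(path, min_mapq)
    else:
        yield from _load_tsv(path)


def _load_bam(path: Path, min_mapq: int) -> Iterator[ReadAlignment]:
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    af = pysam.AlignmentFile(str(path), mode)
    if mode == "rb":
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise AlignmentInputError(
                f"{path}: BAM is not coordinate-sorted (HD SO={so!r}); "
                "run `samtools sort` first"
            )
        if not af.has_index():
            raise AlignmentInputError(
                f"{path}: BAM index not found; run `samtools index {path}`"
            )
    for rec in af:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        strand = "-" if rec.is_reverse else "+"
        yield ReadAlignment(
            read_id=rec.query_name,
            interval=GenomicInterval(rec.reference_name, rec.reference_start, rec.reference_end, strand),
        )
    af.close()


def _load_tsv(path: Path) -> Iterator[ReadAlignment]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise AlignmentInputError(f"{path}: missing column(s): {missing}")
        idx = {c: header.index(c) for c in _TSV_COLUMNS}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            yield ReadAlignment(
                read_id=f[idx["read_id"]],
                interval=GenomicInterval(
                    f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]), f[idx["strand"]]
                ),
            )


def build_gene_index(genes: Sequence[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    """Interval trees over gene spans keyed by (chrom, strand)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        key = (g.chrom, g.strand)
        trees.setdefault(key, IntervalTree()).addi(g.interval.start, g.interval.end, g)
    return trees


def assign_reads_to_genes(
    reads: Iterable[ReadAlignment], genes: Sequence[GeneModel]
) -> Iterator[ReadAlignment]:
    """Assign each read to the same-strand gene with the largest span overlap.

    No overlapping gene -> Unassigned_NoFeature; a tie for maximum overlap
    between two or more genes -> Unassigned_Ambiguity. Assignment does not
    depend on the order genes are given in.
    """
    trees = build_gene_index(genes)
    for read in reads:
        tree = trees.get((read.interval.chrom, read.read_strand))
        best_bp = 0
        best_genes: list[str] = []
        if tree is not None:
            for hit in tree.overlap(read.interval.start, read.interval.end):
                bp = hit.data.interval.overlap(read.interval)
                if bp > best_bp:
                    best_bp, best_genes = bp, [hit.data.gene_id]
                elif bp == best_bp and bp > 0:
                    best_genes.append(hit.data.gene_id)
        if not best_genes:
            yield replace(read, status=NO_FEATURE, assigned_gene=None, overlap_bp=0)
        elif len(best_genes) > 1:
            yield replace(read, status=AMBIGUITY, assigned_gene=None, overlap_bp=0)
        else:
            yield replace(
                read, status=ASSIGNED, assigned_gene=best_genes[0], overlap_bp=best_bp
            )


def assignment_table(reads: Iterable[ReadAlignment]):
    """Assignment summary as a DataFrame (read_id, gene_id, status, overlap_bp)."""
    import pandas as pd

    rows = [
        {
            "read_id": r.read_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "strand": r.read_strand,
            "gene_id": r.assigned_gene or "",
            "status": r.status,
            "overlap_bp": r.overlap_bp,
        }
        for r in reads
    ]
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "end", "strand", "gene_id", "status", "overlap_bp"],
    )
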