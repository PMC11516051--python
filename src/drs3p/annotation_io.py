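"""Gene-annotation ingest.

Parses GFF3 gene models into strand-aware objects with a single internal
coordinate convention: 0-based, half-open, everywhere. Conversion to/from
the 1-based inclusive GFF3 convention happens only at the parse/write
boundary.

Multi-transcript genes are collapsed to one representative transcript (the
one with the longest summed exon length; ties broken by lexicographically
smallest transcript id) because all downstream positional rules — the
translation start used for full-length classification and the most-3' exon
used for APA — are applied per gene, not per isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Fatal problem in an annotation file (malformed coordinates etc.)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval on the same chromosome."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """One gene collapsed to a representative transcript.

    ``cds_start`` is the genomic coordinate (0-based) of the first base of
    the annotated start codon: the lowest CDS coordinate for ``+`` genes and
    the highest for ``-`` genes. ``exons`` are sorted by start coordinate
    regardless of strand.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    transcript_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(f"{self.gene_id}: exon on wrong chrom/strand")
            if ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            prev_end = ex.end
        if not any(ex.contains(self.cds_start) for ex in self.exons):
            raise ValueError(f"{self.gene_id}: cds_start {self.cds_start} not in any exon")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def most3p_exon(self) -> GenomicInterval:
        """Terminal exon in transcription order (strand-aware)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def tss(self) -> int:
        """Transcript 5' end (transcription start) in genomic coordinates."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1


def _validate_gff3_lines(path: Path) -> None:
    """Pre-scan for malformed coordinates so errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from None
            if end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed coordinates (end {end} < start {start})"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models.

    Genes lacking exons or CDS features are skipped with a warning; a
    feature whose end precedes its start is a fatal parse error naming the
    offending line.
    """
    path = Path(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        model = _collapse_gene(db, gene)
        if model is not None:
            genes.append(model)
    return genes


def _collapse_gene(db: gffutils.FeatureDB, gene) -> GeneModel | None:
    transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"))
    candidates: list[tuple[int, str, list, list]] = []
    if transcripts:
        for tx in transcripts:
            exons = list(db.children(tx, featuretype="exon", order_by="start"))
            cds = list(db.children(tx, featuretype="CDS", order_by="start"))
            if not exons or not cds:
                continue
            total = sum(e.end - e.start + 1 for e in exons)
            candidates.append((total, tx.id, exons, cds))
    else:
        exons = list(db.children(gene, featuretype="exon", order_by="start"))
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if exons and cds:
            candidates.append((sum(e.end - e.start + 1 for e in exons), gene.id, exons, cds))
    if not candidates:
        logger.warning("gene %s lacks exon or CDS features; skipped", gene.id)
        return None
    # representative transcript: longest summed exon length, tie -> smallest id
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, tx_id, exons, cds = candidates[0]
    strand = gene.strand
    exon_ivs = tuple(
        GenomicInterval(gene.seqid, e.start - 1, e.end, strand) for e in exons
    )
    if strand == "+":
        cds_start = min(c.start for c in cds) - 1
    else:
        cds_start = max(c.end for c in cds) - 1
    try:
        return GeneModel(
            gene_id=gene.id,
            interval=GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand),
            exons=exon_ivs,
            cds_start=cds_start,
            transcript_id=tx_id,
        )
    except ValueError as exc:
        logger.warning("gene %s has inconsistent structure (%s); skipped", gene.id, exc)
        return None


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back out as GFF3 (1-based inclusive).

    The start codon is emitted as a 3-bp CDS feature so that ``read_gff3``
    round-trips ``cds_start`` exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{iv.chrom}\tdrs3p\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            tx_id = g.transcript_id or f"{g.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\tdrs3p\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={tx_id};Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{iv.chrom}\tdrs3p\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t"
                    f"ID={tx_id}.exon{i};Parent={tx_id}\n"
                )
            if iv.strand == "+":
                c_lo, c_hi = g.cds_start, g.cds_start + 2
            else:
                c_lo, c_hi = g.cds_start - 2, g.cds_start
            fh.write(
                f"{iv.chrom}\tdrs3p\tCDS\t{c_lo + 1}\t{c_hi + 1}\t.\t{iv.strand}\t0\t"
                f"ID={tx_id}.cds;Parent={tx_id}\n"
            )


def to_bed12(genes: Sequence[GeneModel]) -> str:
    """Render gene models as BED12 text for inspection in a browser."""
    lines = []
    for g in genes:
        iv = g.interval
        starts = ",".join(str(ex.start - iv.start) for ex in g.exons) + ","
        sizes = ",".join(str(len(ex)) for ex in g.exons) + ","
        thick = g.cds_start
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    g.gene_id,
                    "0",
                    iv.strand,
                    str(thick),
                    str(thick + 1),
                    "0",
                    str(len(g.exons)),
                    sizes,
                    starts,
                ]
            )
        )
    return "\n".join(lines) + "\n"
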