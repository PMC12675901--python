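"""Interval data model, BED/GTF/bedGraph I/O, and overlap queries.

All internal coordinates are 0-based half-open ``[start, end)``. GTF input
(1-based inclusive) is converted at parse time. Chromosome names are matched
by exact string equality; no "chr" aliasing is performed, but
:func:`warn_if_disjoint_chromosomes` flags fixtures whose chromosome sets do
not intersect at all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: biotypes recognised on GTF gene records; anything else maps to "other"
KNOWN_BIOTYPES = frozenset(
    {"protein_coding", "rRNA", "snRNA", "miRNA", "snoRNA", "tRNA", "other"}
)


class MalformedRecordError(ValueError):
    """A text record violated the format contract; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains_point(self, chrom: str, position: int) -> bool:
        return self.chrom == chrom and self.start <= position < self.end


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with a biotype and a strand-aware TSS.

    TSS is the 5' end: ``start`` on the + strand, ``end - 1`` (the last base
    of the half-open interval) on the - strand.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} needs an explicit strand")
        if self.biotype not in KNOWN_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True, slots=True)
class EnhancerRecord:
    """Catalog enhancer: super-enhancer (SE) or typical enhancer (TE).

    Enhancers are unstranded (transcription at them is bidirectional);
    ``target_gene`` is the catalog's assigned target, or None.
    """

    enhancer_id: str
    interval: GenomicInterval
    klass: str
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in ("SE", "TE"):
            raise ValueError(f"enhancer class must be SE or TE, got {self.klass!r}")


@dataclass(frozen=True, slots=True)
class PeakRecord:
    """A ChIP-seq peak interval."""

    peak_id: str
    interval: GenomicInterval


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


def parse_bed(stream: TextIO | Iterable[str]) -> list[GenomicInterval]:
    """Parse BED3/BED6 text into intervals, in file order.

    Missing strand column yields strand ".". Raises
    :class:`MalformedRecordError` (with the 1-based line number) on bad
    coordinates.
    """
    out: list[GenomicInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise MalformedRecordError(f"expected >=3 columns, got {len(cols)}", lineno)
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise MalformedRecordError(f"non-integer coordinate: {exc}", lineno) from None
        name = cols[3] if len(cols) > 3 else ""
        try:
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
        except ValueError:
            raise MalformedRecordError(f"non-numeric score {cols[4]!r}", lineno) from None
        strand = cols[5] if len(cols) > 5 else "."
        try:
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
        except ValueError as exc:
            raise MalformedRecordError(str(exc), lineno) from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], stream: TextIO) -> None:
    """Write BED6 (tab-separated, newline-terminated)."""
    for iv in intervals:
        score = int(iv.score) if float(iv.score).is_integer() else iv.score
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
        )


def _gtf_attributes(field9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf_genes(stream: TextIO | Iterable[str]) -> list[GeneModel]:
    """Parse gene-level GTF records into :class:`GeneModel`.

    GTF is 1-based inclusive; coordinates become 0-based half-open
    ``(start-1, end)``. Records whose feature column is not ``gene`` are
    skipped. A gene record without a ``gene_id`` attribute is an error;
    an unknown ``gene_biotype`` is mapped to "other" with a warning.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise MalformedRecordError(f"expected 9 GTF columns, got {len(cols)}", lineno)
        if cols[2] != "gene":
            continue
        try:
            start1, end1 = int(cols[3]), int(cols[4])
        except ValueError:
            raise MalformedRecordError("non-integer coordinate", lineno) from None
        strand = cols[6]
        attrs = _gtf_attributes(cols[8])
        if "gene_id" not in attrs:
            raise MalformedRecordError("gene record lacks gene_id attribute", lineno)
        gene_id = attrs["gene_id"]
        if gene_id in seen:
            raise MalformedRecordError(f"duplicate gene_id {gene_id!r}", lineno)
        seen.add(gene_id)
        biotype = attrs.get("gene_biotype", attrs.get("gene_type", "other"))
        if biotype not in KNOWN_BIOTYPES:
            logger.warning("gene %s: unknown biotype %r mapped to 'other'", gene_id, biotype)
            biotype = "other"
        try:
            iv = GenomicInterval(cols[0], start1 - 1, end1, strand, name=gene_id)
        except ValueError as exc:
            raise MalformedRecordError(str(exc), lineno) from None
        genes.append(GeneModel(gene_id, iv, biotype))
    return genes


def write_gtf_genes(genes: Iterable[GeneModel], stream: TextIO, source: str = "degronseq") -> None:
    for g in genes:
        iv = g.interval
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        stream.write(
            f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
        )


def parse_bedgraph(stream: TextIO | Iterable[str]) -> list[tuple[GenomicInterval, float]]:
    """Parse a 4-column bedGraph (chrom, start, end, value; half-open)."""
    runs: list[tuple[GenomicInterval, float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise MalformedRecordError(f"expected 4 bedGraph columns, got {len(cols)}", lineno)
        try:
            start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
        except ValueError:
            raise MalformedRecordError("non-numeric bedGraph field", lineno) from None
        try:
            runs.append((GenomicInterval(cols[0], start, end), value))
        except ValueError as exc:
            raise MalformedRecordError(str(exc), lineno) from None
    return runs


def write_bedgraph(runs: Iterable[tuple[GenomicInterval, float]], stream: TextIO) -> None:
    for iv, value in runs:
        v = int(value) if float(value).is_integer() else value
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v}\n")


def parse_enhancer_bed(stream: TextIO | Iterable[str]) -> list[EnhancerRecord]:
    """Parse a BED6+2 enhancer catalog: columns 7 = class (SE/TE), 8 = target gene.

    A "." or missing target column means no catalog target assignment.
    """
    out: list[EnhancerRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            raise MalformedRecordError("enhancer BED needs >=7 columns (class in col 7)", lineno)
        try:
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]), ".", name=cols[3])
        except ValueError as exc:
            raise MalformedRecordError(str(exc), lineno) from None
        if cols[3] in seen:
            raise MalformedRecordError(f"duplicate enhancer id {cols[3]!r}", lineno)
        seen.add(cols[3])
        target = cols[7] if len(cols) > 7 and cols[7] != "." else None
        try:
            out.append(EnhancerRecord(cols[3], iv, cols[6], target))
        except ValueError as exc:
            raise MalformedRecordError(str(exc), lineno) from None
    return out


def write_enhancer_bed(enhancers: Iterable[EnhancerRecord], stream: TextIO) -> None:
    for e in enhancers:
        iv = e.interval
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.enhancer_id}\t0\t.\t"
            f"{e.klass}\t{e.target_gene or '.'}\n"
        )


# ---------------------------------------------------------------------------
# overlap engine
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval, strand_mode: str = "ignore") -> bool:
    """Half-open overlap test: same chrom and a.start < b.end and b.start < a.end.

    ``strand_mode`` is "ignore" (default), "same" or "opposite"; the stranded
    modes only ever match records with explicit +/- strands.
    """
    if a.chrom != b.chrom:
        return False
    if not (a.start < b.end and b.start < a.end):
        return False
    return _strand_ok(a.strand, b.strand, strand_mode)


def _strand_ok(sa: str, sb: str, mode: str) -> bool:
    if mode == "ignore":
        return True
    if mode == "same":
        return sa == sb and sa in ("+", "-")
    if mode == "opposite":
        return {sa, sb} == {"+", "-"}
    raise ValueError(f"strand_mode must be ignore/same/opposite, got {mode!r}")


def build_trees(subjects: list[GenomicInterval]) -> dict[str, IntervalTree]:
    """One IntervalTree per chromosome, payload = subject index."""
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(subjects):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees


def find_overlaps(
    queries: list[GenomicInterval],
    subjects: list[GenomicInterval],
    strand_mode: str = "ignore",
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs whose intervals overlap.

    Output is sorted by query index then subject index.
    """
    _strand_ok("+", "+", strand_mode)  # validate mode eagerly
    trees = build_trees(subjects)
    pairs: list[tuple[int, int]] = []
    for i, q in enumerate(queries):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        hits = sorted(hit.data for hit in tree.overlap(q.start, q.end))
        for j in hits:
            if _strand_ok(q.strand, subjects[j].strand, strand_mode):
                pairs.append((i, j))
    return pairs


def warn_if_disjoint_chromosomes(
    queries: Iterable[GenomicInterval], subjects: Iterable[GenomicInterval]
) -> bool:
    """Warn when query and subject chromosome sets do not intersect.

    Exact-string chromosome matching means a "chr1" vs "1" naming mismatch
    silently produces zero overlaps; this validator makes that loud.
    Returns True when a warning was issued.
    """
    qset = {iv.chrom for iv in queries}
    sset = {iv.chrom for iv in subjects}
    if qset and sset and not (qset & sset):
        warnings.warn(
            f"query chromosomes {sorted(qset)[:5]} and subject chromosomes "
            f"{sorted(sset)[:5]} are disjoint; check naming conventions",
            stacklevel=2,
        )
        return True
    return False


def nearest_tss(
    point: tuple[str, int],
    genes: list[GeneModel],
    max_distance: int | None = None,
) -> str | None:
    """Gene whose TSS is closest to ``point`` on the same chromosome.

    Ties break to the lexicographically smallest gene_id; returns None when
    no gene lies within ``max_distance`` (None = unlimited).
    """
    chrom, pos = point
    best: tuple[int, str] | None = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        d = abs(g.tss - pos)
        if max_distance is not None and d > max_distance:
            continue
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best else None
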