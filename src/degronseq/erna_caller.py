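"""De-novo transcript-unit calling from strand-specific coverage and
eRNA designation.

The procedure mirrors GRO-seq-style nascent transcript discovery: per
strand, maximal runs of positions at or above a depth cutoff are merged
across short gaps, short segments are discarded, and the surviving units
are filtered against the gene annotation (any-strand overlap with
protein-coding genes removes a unit — the opposite-strand case is the
"antisense region" exclusion — as does overlap with structural ncRNA
biotypes). A filtered intergenic unit whose TSS falls inside a catalog
enhancer is designated an eRNA; its putative target gene is the nearest
protein-coding TSS within a distance cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .genomic_core import (
    EnhancerRecord,
    GeneModel,
    GenomicInterval,
    build_trees,
    nearest_tss,
)

DEFAULT_MIN_COV = 2.0
DEFAULT_MAX_GAP = 250
DEFAULT_MIN_LENGTH = 200
DEFAULT_TARGET_DISTANCE = 100_000

#: structural ncRNA biotypes excluded from unit calling by default
DEFAULT_EXCLUDED_BIOTYPES = frozenset({"rRNA", "snRNA", "miRNA", "snoRNA"})


@dataclass
class CoverageTrack:
    """Strand-specific coverage as sorted, non-overlapping depth runs."""

    plus: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    minus: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for strand, runs in (("+", self.plus), ("-", self.minus)):
            runs.sort(key=lambda r: (r[0].chrom, r[0].start))
            prev = None
            for iv, depth in runs:
                if depth < 0:
                    raise ValueError(f"negative depth {depth} at {iv.chrom}:{iv.start}")
                if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                    raise ValueError(
                        f"overlapping runs on {strand} strand at {iv.chrom}:{iv.start}"
                    )
                prev = iv


@dataclass(frozen=True)
class TranscriptUnit:
    """A called unit; TSS is the strand-aware 5' end (as for genes)."""

    unit_id: str
    interval: GenomicInterval
    mean_depth: float

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class ERNARecord:
    """A transcript unit designated as an eRNA by TSS-in-enhancer."""

    unit_id: str
    unit: TranscriptUnit
    enhancer_id: str
    klass: str
    target_gene: str | None = None
    target_distance: int | None = None


def _segment_strand(
    runs: Sequence[tuple[GenomicInterval, float]],
    strand: str,
    min_cov: float,
    max_gap: int,
    min_length: int,
) -> list[TranscriptUnit]:
    # covered stretches at/above the cutoff, per chromosome, in order
    covered: dict[str, list[tuple[int, int, float]]] = {}
    for iv, depth in runs:
        if depth >= min_cov:
            covered.setdefault(iv.chrom, []).append((iv.start, iv.end, depth))
    units: list[TranscriptUnit] = []
    for chrom in sorted(covered):
        segs = covered[chrom]
        # merge adjacent/contiguous covered stretches, then bridge gaps <= max_gap
        merged: list[list[float]] = []  # [start, end, depth*bases]
        for start, end, depth in segs:
            if merged and start - merged[-1][1] <= max_gap:
                merged[-1][1] = end
                merged[-1][2] += depth * (end - start)
            else:
                merged.append([start, end, depth * (end - start)])
        for start, end, mass in merged:
            start, end = int(start), int(end)
            if end - start < min_length:
                continue
            units.append(
                TranscriptUnit(
                    unit_id="",  # assigned by caller
                    interval=GenomicInterval(chrom, start, end, strand),
                    mean_depth=mass / (end - start),
                )
            )
    return units


def call_units(
    track: CoverageTrack,
    min_cov: float = DEFAULT_MIN_COV,
    max_gap: int = DEFAULT_MAX_GAP,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[TranscriptUnit]:
    """Segment coverage into transcript units, per strand.

    Positions with depth >= min_cov form runs; runs separated by <= max_gap
    sub-threshold bases are merged; merged segments shorter than min_length
    are dropped. Unit ids are assigned in (chrom, start, strand) order.
    """
    if min_cov <= 0:
        raise ValueError("min_cov must be positive")
    if max_gap < 0 or min_length < 1:
        raise ValueError("max_gap must be >=0 and min_length >=1")
    units = _segment_strand(track.plus, "+", min_cov, max_gap, min_length)
    units += _segment_strand(track.minus, "-", min_cov, max_gap, min_length)
    units.sort(key=lambda u: (u.interval.chrom, u.interval.start, u.interval.strand))
    return [
        replace(u, unit_id=f"unit_{i + 1:05d}") for i, u in enumerate(units)
    ]


def exclude_annotated(
    units: Iterable[TranscriptUnit],
    genes: Sequence[GeneModel],
    excluded_biotypes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> tuple[list[TranscriptUnit], Counter]:
    """Drop units overlapping annotated genes; keep per-reason tallies.

    Removal reasons (first matching rule wins):
      * ``protein_coding``: any-strand overlap with a protein-coding gene —
        same-strand overlap is genic, opposite-strand is the antisense case;
        both are excluded.
      * ``excluded_biotype``: any-strand overlap with a gene whose biotype is
        in ``excluded_biotypes``.

    Returns (survivors, Counter of removal reasons incl. "retained").
    """
    gene_ivs = [g.interval for g in genes]
    trees = build_trees(gene_ivs)
    tally: Counter = Counter()
    survivors: list[TranscriptUnit] = []
    for unit in units:
        iv = unit.interval
        tree = trees.get(iv.chrom)
        hits = [genes[h.data] for h in tree.overlap(iv.start, iv.end)] if tree else []
        if any(g.biotype == "protein_coding" for g in hits):
            tally["protein_coding"] += 1
        elif any(g.biotype in excluded_biotypes for g in hits):
            tally["excluded_biotype"] += 1
        else:
            tally["retained"] += 1
            survivors.append(unit)
    return survivors, tally


def designate_ernas(
    units: Iterable[TranscriptUnit],
    enhancers: Sequence[EnhancerRecord],
) -> list[ERNARecord]:
    """Designate units whose TSS lies inside an enhancer as eRNAs.

    Containment is half-open (a TSS at the enhancer's exclusive end does
    not qualify). When several enhancers contain one TSS the enhancer whose
    midpoint is closest wins; residual ties break to the lexicographically
    smallest enhancer_id.
    """
    enh_ivs = [e.interval for e in enhancers]
    trees = build_trees(enh_ivs)
    out: list[ERNARecord] = []
    for unit in units:
        tss = unit.tss
        chrom = unit.interval.chrom
        tree = trees.get(chrom)
        if tree is None:
            continue
        containing = [enhancers[h.data] for h in tree.at(tss)]
        if not containing:
            continue
        best = min(
            containing,
            key=lambda e: (abs(e.interval.midpoint - tss), e.enhancer_id),
        )
        out.append(
            ERNARecord(
                unit_id=unit.unit_id,
                unit=unit,
                enhancer_id=best.enhancer_id,
                klass=best.klass,
            )
        )
    return out


def assign_targets(
    ernas: Iterable[ERNARecord],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_TARGET_DISTANCE,
) -> list[ERNARecord]:
    """Fill each eRNA's putative target: nearest protein-coding TSS.

    Targets farther than ``max_distance`` bases are left unassigned.
    """
    coding = [g for g in genes if g.biotype == "protein_coding"]
    tss_by_id = {g.gene_id: g.tss for g in coding}
    out: list[ERNARecord] = []
    for e in ernas:
        target = nearest_tss((e.unit.interval.chrom, e.unit.tss), coding, max_distance)
        dist = abs(tss_by_id[target] - e.unit.tss) if target else None
        out.append(replace(e, target_gene=target, target_distance=dist))
    return out
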