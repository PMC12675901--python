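"""Occupancy annotation, gene-enhancer classification, and direct-target
set logic.

This stage joins three inputs — an enhancer catalog with differential
calls, ChIP-seq peaks, and gene-level differential calls — into the
bookkeeping a depletion study reports: which enhancers the factor occupies,
how downregulated genes partition by the class of enhancer that targets
them (SE & TE / Only SE / Only TE / Not assigned), whether occupied
enhancers fall harder than unoccupied ones, and finally the intersection
lists that nominate putative direct targets:

  List 1: factor-bound genes downregulated in the early contrast.
  List 2: target genes of factor-bound, downregulated super-enhancers.
  List 3: target genes of factor-bound, downregulated typical enhancers.

The union of (List1 & List2) and (List1 & List3) is the direct-target set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffexpr import mann_whitney
from .genomic_core import (
    EnhancerRecord,
    GenomicInterval,
    PeakRecord,
    find_overlaps,
)

GENE_CLASSES = ("SE_and_TE", "Only_SE", "Only_TE", "Not_assigned")


@dataclass
class OccupancyTable:
    """Per-enhancer occupancy and differential status.

    ``table`` columns: enhancer_id (index), klass, bound, down_called, log2fc.
    """

    table: pd.DataFrame

    def bound_count(self, klass: str) -> int:
        t = self.table
        return int(((t["klass"] == klass) & t["bound"]).sum())

    def total(self, klass: str) -> int:
        return int((self.table["klass"] == klass).sum())


@dataclass(frozen=True)
class DirectTargetReport:
    list1: frozenset[str]
    list2: frozenset[str]
    list3: frozenset[str]
    overlap12: frozenset[str]
    overlap13: frozenset[str]
    union: frozenset[str]


def annotate_occupancy(
    enhancers: Sequence[EnhancerRecord],
    peaks: Sequence[PeakRecord],
    down_called: Mapping[str, bool] | None = None,
    log2fc: Mapping[str, float] | None = None,
) -> OccupancyTable:
    """Flag each catalog enhancer as bound (>=1 peak overlap, strand ignored).

    ``down_called`` and ``log2fc`` are optional per-enhancer annotations
    carried through for the bound-vs-unbound comparisons.
    """
    pairs = find_overlaps(
        [e.interval for e in enhancers], [p.interval for p in peaks], "ignore"
    )
    bound_idx = {i for i, _ in pairs}
    down_called = down_called or {}
    log2fc = log2fc or {}
    table = pd.DataFrame(
        {
            "klass": [e.klass for e in enhancers],
            "bound": [i in bound_idx for i in range(len(enhancers))],
            "down_called": [bool(down_called.get(e.enhancer_id, False)) for e in enhancers],
            "log2fc": [float(log2fc.get(e.enhancer_id, 0.0)) for e in enhancers],
        },
        index=pd.Index([e.enhancer_id for e in enhancers], name="enhancer_id"),
    )
    return OccupancyTable(table)


def classify_genes(
    down_genes: Iterable[str],
    se_target_map: Mapping[str, str],
    te_target_map: Mapping[str, str],
) -> pd.DataFrame:
    """Partition downregulated genes by the class of enhancers targeting them.

    The maps send enhancer_id -> target gene_id (the full catalogs, not
    just differential enhancers). Returns a DataFrame with gene_id index
    and a ``gene_class`` column over ``GENE_CLASSES``; the classes are
    exhaustive and mutually exclusive.
    """
    se_targets = set(se_target_map.values())
    te_targets = set(te_target_map.values())
    rows = {}
    for gene in sorted(down_genes):
        in_se, in_te = gene in se_targets, gene in te_targets
        if in_se and in_te:
            klass = "SE_and_TE"
        elif in_se:
            klass = "Only_SE"
        elif in_te:
            klass = "Only_TE"
        else:
            klass = "Not_assigned"
        rows[gene] = klass
    return pd.DataFrame(
        {"gene_class": pd.Series(rows, dtype="object")}
    ).rename_axis("gene_id")


def compare_bound_unbound(
    occupancy: OccupancyTable, klass: str
) -> tuple[int, int, float | None, float | None]:
    """Wilcoxon rank-sum on log2fc of bound vs unbound down-called enhancers.

    Restricted to down-called enhancers of the given class. Returns
    (n_bound, n_unbound, U, p); U and p are None (with a warning) when a
    group is empty.
    """
    t = occupancy.table
    sub = t[(t["klass"] == klass) & t["down_called"]]
    bound = sub.loc[sub["bound"], "log2fc"].to_numpy()
    unbound = sub.loc[~sub["bound"], "log2fc"].to_numpy()
    if bound.size == 0 or unbound.size == 0:
        warnings.warn(
            f"{klass}: bound ({bound.size}) or unbound ({unbound.size}) group empty; "
            "no test performed",
            stacklevel=2,
        )
        return bound.size, unbound.size, None, None
    u, p = mann_whitney(bound, unbound)
    return bound.size, unbound.size, u, p


def direct_targets(
    down_bound_genes: Iterable[str],
    occupancy: OccupancyTable,
    se_target_map: Mapping[str, str],
    te_target_map: Mapping[str, str],
) -> DirectTargetReport:
    """Intersect bound-down genes with targets of bound-down SEs and TEs."""
    list1 = frozenset(down_bound_genes)
    t = occupancy.table
    active = t[t["bound"] & t["down_called"]]
    list2 = frozenset(
        se_target_map[eid] for eid in active.index if eid in se_target_map
    )
    list3 = frozenset(
        te_target_map[eid] for eid in active.index if eid in te_target_map
    )
    overlap12 = list1 & list2
    overlap13 = list1 & list3
    return DirectTargetReport(
        list1=list1,
        list2=list2,
        list3=list3,
        overlap12=overlap12,
        overlap13=overlap13,
        union=overlap12 | overlap13,
    )


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (what figure legends print), not banker's."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage_report(pairs: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Tabulate (label, numerator, denominator) as percentages to 1 decimal.

    Raises on a zero denominator or a numerator outside [0, denominator].
    """
    rows = []
    for label, num, den in pairs:
        if den <= 0:
            raise ValueError(f"{label}: denominator must be positive, got {den}")
        if not 0 <= num <= den:
            raise ValueError(f"{label}: numerator {num} outside [0, {den}]")
        rows.append((label, num, den, round_half_away(100.0 * num / den, 1)))
    return pd.DataFrame(rows, columns=["label", "numerator", "denominator", "percent"])


@dataclass
class IntegrationReport:
    """Everything the integration stage computes, in one bundle."""

    occupancy: OccupancyTable
    gene_calls: pd.DataFrame
    enhancer_calls: pd.DataFrame
    gene_classes: pd.DataFrame
    class_counts: dict[str, int]
    direct: DirectTargetReport
    percentages: pd.DataFrame
    bound_unbound: dict[str, tuple[int, int, float | None, float | None]]


def run_integration(
    gene_de: pd.DataFrame,
    enhancer_de: pd.DataFrame,
    enhancers: Sequence[EnhancerRecord],
    peaks: Sequence[PeakRecord],
    gene_intervals: Mapping[str, GenomicInterval],
    gene_thresholds=None,
    enhancer_thresholds=None,
) -> IntegrationReport:
    """Full integration pass: calls, occupancy, classes, direct targets.

    ``gene_de`` / ``enhancer_de`` are differential tables (feature_id
    index; log2fc, pvalue, padj columns). Genes are called at fold change
    > 2 with adjusted p < 0.05, enhancers at fold change > 1.5 with raw
    p < 0.05, unless other thresholds are given. Enhancer target maps come
    from the catalog's target column.
    """
    from .diffexpr import ENHANCER_THRESHOLDS, GENE_THRESHOLDS, call_features

    gene_thresholds = gene_thresholds or GENE_THRESHOLDS
    enhancer_thresholds = enhancer_thresholds or ENHANCER_THRESHOLDS

    gene_calls = call_features(gene_de, gene_thresholds)
    enh_calls = call_features(enhancer_de, enhancer_thresholds)
    down_genes = set(gene_calls.index[gene_calls["call"] == "down"])
    up_genes = set(gene_calls.index[gene_calls["call"] == "up"])
    down_enh = {eid: (enh_calls.loc[eid, "call"] == "down") for eid in enh_calls.index}
    enh_lfc = {eid: float(enh_calls.loc[eid, "log2fc"]) for eid in enh_calls.index}

    occupancy = annotate_occupancy(enhancers, peaks, down_enh, enh_lfc)
    se_map = {e.enhancer_id: e.target_gene for e in enhancers if e.klass == "SE" and e.target_gene}
    te_map = {e.enhancer_id: e.target_gene for e in enhancers if e.klass == "TE" and e.target_gene}

    classes = classify_genes(down_genes, se_map, te_map)
    class_counts = {
        k: int((classes["gene_class"] == k).sum()) for k in GENE_CLASSES
    }

    bound = gene_bound_flags(gene_intervals, peaks)
    down_bound = {g for g in down_genes if bound.get(g)}
    up_bound = {g for g in up_genes if bound.get(g)}
    direct = direct_targets(down_bound, occupancy, se_map, te_map)

    t = occupancy.table
    n_se, n_te = occupancy.total("SE"), occupancy.total("TE")
    se_down = int(((t["klass"] == "SE") & t["down_called"]).sum())
    te_down = int(((t["klass"] == "TE") & t["down_called"]).sum())
    pct_pairs = [
        ("SE_bound", occupancy.bound_count("SE"), n_se),
        ("TE_bound", occupancy.bound_count("TE"), n_te),
        ("SE_down", se_down, n_se),
        ("TE_down", te_down, n_te),
    ]
    if down_genes:
        pct_pairs += [
            (f"down_genes_{k}", class_counts[k], len(down_genes)) for k in GENE_CLASSES
        ]
        pct_pairs.append(("down_genes_bound", len(down_bound), len(down_genes)))
    if up_genes:
        pct_pairs.append(("up_genes_bound", len(up_bound), len(up_genes)))
    percentages = percentage_report(pct_pairs)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bound_unbound = {
            klass: compare_bound_unbound(occupancy, klass) for klass in ("SE", "TE")
        }
    return IntegrationReport(
        occupancy=occupancy,
        gene_calls=gene_calls,
        enhancer_calls=enh_calls,
        gene_classes=classes,
        class_counts=class_counts,
        direct=direct,
        percentages=percentages,
        bound_unbound=bound_unbound,
    )


def gene_bound_flags(
    genes: Mapping[str, GenomicInterval], peaks: Sequence[PeakRecord]
) -> dict[str, bool]:
    """Per-gene factor-bound flag: >=1 peak overlapping the gene interval."""
    ids = list(genes)
    pairs = find_overlaps([genes[g] for g in ids], [p.interval for p in peaks], "ignore")
    bound = {i for i, _ in pairs}
    return {g: (i in bound) for i, g in enumerate(ids)}
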