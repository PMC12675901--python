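"""Deterministic generator of a miniature acute-depletion study.

Two kinds of dataset come out of this module and they serve different
purposes:

* The *statistical* simulators (:func:`simulate_annotation`,
  :func:`simulate_counts`, :func:`simulate_coverage`) draw a genome
  annotation, spike-in-bearing negative-binomial count matrices across
  three timepoints (0 h, 4 h, 24 h of depletion), and strand-specific
  coverage with planted transcript units. Their defaults encode the study
  conditions: a dominant global shutdown (most genes truly fall several
  fold after depletion), spike-ins at constant abundance, factor occupancy
  that deepens enhancer downregulation, and three replicates per
  timepoint. Recovery from these datasets is statistical — correct within
  tolerance, never exact.

* :func:`reference_fixture` is a *structural* dataset: catalog sizes,
  occupancy flags and differential calls are laid out by explicit
  construction so that the integration stage's bookkeeping (counts,
  percentages, intersection-list sizes) is exact and fast. It carries no
  count matrices; differential tables are written directly with values
  consistent with the intended calls.

Every stochastic draw flows from ``SimulationConfig.seed``; the same seed
reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import (
    EnhancerRecord,
    GeneModel,
    GenomicInterval,
    PeakRecord,
    find_overlaps,
    nearest_tss,
    write_bed,
    write_bedgraph,
    write_enhancer_bed,
    write_gtf_genes,
)
from .erna_caller import CoverageTrack, TranscriptUnit
from .quantify import CountMatrix, write_counts_tsv

TIMEPOINTS = ("0h", "4h", "24h")

#: biotypes sprinkled among the non-coding decoy genes
_NONCODING_BIOTYPES = ("rRNA", "snRNA", "miRNA", "snoRNA", "tRNA")


@dataclass
class SimulationConfig:
    """Knobs of the miniature study; defaults are the study conditions.

    ``frac_direct_down`` is the fraction of protein-coding genes that
    truly lose transcription after depletion (the global shutdown);
    ``down_fc_4h`` / ``down_fc_24h`` are their fold reductions at the two
    treated timepoints (the 24 h effect is deeper). ``bound_down_shift``
    is the extra log2 depression applied to factor-bound downregulated
    enhancers. Spike-in features have fold change 1 everywhere by
    construction.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 24_000_000
    n_genes: int = 2000
    n_noncoding: int = 60
    n_se: int = 20
    n_te: int = 120
    n_spikeins: int = 100
    replicates: int = 3
    nb_dispersion: float = 0.05
    frac_direct_down: float = 0.6
    down_fc_4h: float = 4.0
    down_fc_24h: float = 8.0
    frac_enh_bound: float = 0.5
    bound_down_shift: float = 1.0
    mean_gene_count: float = 200.0
    mean_spikein_count: float = 500.0
    n_planted_units: int = 30
    n_units_in_enhancers: int = 20
    planted_unit_depth: float = 5.0
    noise_depth: float = 1.0

    def __post_init__(self) -> None:
        for name in ("frac_direct_down", "frac_enh_bound"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.n_spikeins < 10:
            raise ValueError("n_spikeins must be >= 10")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_units_in_enhancers > self.n_planted_units:
            raise ValueError("n_units_in_enhancers cannot exceed n_planted_units")
        if min(self.down_fc_4h, self.down_fc_24h) <= 1:
            raise ValueError("down fold changes must exceed 1")


@dataclass
class Annotation:
    """Generated annotation bundle plus structural truth."""

    genes: list[GeneModel]
    enhancers: list[EnhancerRecord]
    peaks: list[PeakRecord]
    spikein_ids: list[str]
    bound_enhancer_ids: set[str]
    unit_slots: list[GenomicInterval]
    noise_slots: list[GenomicInterval]
    chrom_lengths: dict[str, int]

    @property
    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "protein_coding"]


@dataclass
class CountTruth:
    """Ground truth behind a simulated count matrix."""

    true_log2fc: pd.DataFrame  # features x {4h, 24h}
    down_gene_ids: set[str]
    size_factors: pd.Series
    spikein_ids: list[str]


@dataclass
class PlantedUnit:
    interval: GenomicInterval
    depth: float
    in_enhancer: bool
    enhancer_id: str | None = None

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out non-overlapping genes, enhancers, peaks and reserved slots.

    Features are shuffled then placed left to right with random gaps, so
    genes and enhancers interleave and every enhancer has a local
    nearest-TSS target. SE intervals are longer than TE intervals. A
    fraction ``frac_enh_bound`` of enhancers receive an overlapping peak.
    Raises when the features do not fit the configured chromosome length.
    """
    rng = _rng(config, 1)
    specs: list[tuple[str, int, int]] = []  # (kind, index, length)
    for i in range(config.n_genes):
        specs.append(("gene", i, int(rng.integers(2000, 8000))))
    for i in range(config.n_noncoding):
        specs.append(("noncoding", i, int(rng.integers(100, 1000))))
    for i in range(config.n_se):
        specs.append(("SE", i, int(rng.integers(8000, 15000))))
    for i in range(config.n_te):
        specs.append(("TE", i, int(rng.integers(1000, 2000))))
    n_extra_slots = config.n_planted_units + 10
    for i in range(n_extra_slots):
        specs.append(("slot", i, 1500))
    rng.shuffle(specs)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = int(np.ceil(len(specs) / config.n_chromosomes))
    genes: list[GeneModel] = []
    enhancers_raw: list[tuple[str, GenomicInterval]] = []  # (klass, interval)
    slots: list[GenomicInterval] = []
    for c, chrom in enumerate(chroms):
        cursor = 10_000
        for kind, i, length in specs[c * per_chrom : (c + 1) * per_chrom]:
            cursor += int(rng.integers(5000, 20000))
            start, end = cursor, cursor + length
            if end > config.chrom_length:
                raise ValueError(
                    f"features do not fit on {chrom}; increase chrom_length "
                    f"(needed > {end})"
                )
            cursor = end
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"gene_{i + 1:05d}"
                genes.append(
                    GeneModel(gid, GenomicInterval(chrom, start, end, strand, gid))
                )
            elif kind == "noncoding":
                strand = "+" if rng.random() < 0.5 else "-"
                biotype = _NONCODING_BIOTYPES[i % len(_NONCODING_BIOTYPES)]
                gid = f"nc_{i + 1:04d}"
                genes.append(
                    GeneModel(gid, GenomicInterval(chrom, start, end, strand, gid), biotype)
                )
            elif kind in ("SE", "TE"):
                enhancers_raw.append((kind, GenomicInterval(chrom, start, end)))
            else:
                slots.append(GenomicInterval(chrom, start, end))

    coding = [g for g in genes if g.biotype == "protein_coding"]
    enhancers: list[EnhancerRecord] = []
    se_i = te_i = 0
    for klass, iv in sorted(enhancers_raw, key=lambda e: (e[1].chrom, e[1].start)):
        if klass == "SE":
            se_i += 1
            eid = f"SE_{se_i:04d}"
        else:
            te_i += 1
            eid = f"TE_{te_i:04d}"
        target = nearest_tss((iv.chrom, int(iv.midpoint)), coding, None)
        enhancers.append(EnhancerRecord(eid, iv, klass, target))

    bound_ids = {
        e.enhancer_id for e in enhancers if rng.random() < config.frac_enh_bound
    }
    peaks = []
    for e in enhancers:
        if e.enhancer_id in bound_ids:
            mid = int(e.interval.midpoint)
            peaks.append(
                PeakRecord(
                    f"peak_{len(peaks) + 1:05d}",
                    GenomicInterval(e.interval.chrom, mid - 100, mid + 100),
                )
            )

    spikein_ids = [f"spike_{i + 1:04d}" for i in range(config.n_spikeins)]
    return Annotation(
        genes=genes,
        enhancers=enhancers,
        peaks=peaks,
        spikein_ids=spikein_ids,
        bound_enhancer_ids=bound_ids,
        unit_slots=slots[: config.n_planted_units],
        noise_slots=slots[config.n_planted_units :],
        chrom_lengths={c: config.chrom_length for c in chroms},
    )


def self_audit(annotation: Annotation) -> None:
    """Re-derive the recorded truth from the emitted records; raise on mismatch.

    Checks: no two placed features overlap; every enhancer's recorded
    target equals the nearest protein-coding TSS; recorded bound flags
    equal actual peak overlap.
    """
    ivs = (
        [g.interval for g in annotation.genes]
        + [e.interval for e in annotation.enhancers]
        + annotation.unit_slots
        + annotation.noise_slots
    )
    pairs = find_overlaps(ivs, ivs, "ignore")
    if any(i != j for i, j in pairs):
        raise AssertionError("placed features overlap")
    coding = annotation.coding_genes
    for e in annotation.enhancers:
        expect = nearest_tss((e.interval.chrom, int(e.interval.midpoint)), coding, None)
        if expect != e.target_gene:
            raise AssertionError(f"{e.enhancer_id}: target {e.target_gene} != {expect}")
    hits = find_overlaps(
        [e.interval for e in annotation.enhancers],
        [p.interval for p in annotation.peaks],
        "ignore",
    )
    derived_bound = {annotation.enhancers[i].enhancer_id for i, _ in hits}
    if derived_bound != annotation.bound_enhancer_ids:
        raise AssertionError("bound flags do not match peak overlap")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-8:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    config: SimulationConfig, annotation: Annotation
) -> tuple[CountMatrix, CountTruth]:
    """Draw NB counts for genes, enhancers and spike-ins across timepoints.

    counts ~ NB(mean = s_j * q_f * 2^lfc_f(t), dispersion alpha). A
    ``frac_direct_down`` subset of protein-coding genes carries the
    depletion effect (1/down_fc_4h at 4 h, deeper at 24 h); the same
    fraction of enhancers is downregulated, with factor-bound ones
    depressed a further ``bound_down_shift`` log2 units. Spike-ins keep
    fold change 1 and constant baseline. True per-sample size factors are
    drawn log-uniform in [0.5, 2].
    """
    rng = _rng(config, 2)
    gene_ids = [g.gene_id for g in annotation.coding_genes]
    enh_ids = [e.enhancer_id for e in annotation.enhancers]
    feature_ids = gene_ids + enh_ids + annotation.spikein_ids

    q = np.concatenate(
        [
            rng.lognormal(np.log(config.mean_gene_count), 1.0, len(gene_ids)),
            rng.lognormal(np.log(config.mean_gene_count / 4), 1.0, len(enh_ids)),
            rng.lognormal(np.log(config.mean_spikein_count), 0.5, config.n_spikeins),
        ]
    )

    n_down = int(round(config.frac_direct_down * len(gene_ids)))
    down_genes = set(rng.choice(gene_ids, size=n_down, replace=False))
    down_enh = {eid for eid in enh_ids if rng.random() < config.frac_direct_down}

    lfc = pd.DataFrame(0.0, index=feature_ids, columns=["4h", "24h"])
    for tp, fc in (("4h", config.down_fc_4h), ("24h", config.down_fc_24h)):
        lfc.loc[list(down_genes), tp] = -np.log2(fc)
        for eid in down_enh:
            shift = (
                config.bound_down_shift
                if eid in annotation.bound_enhancer_ids
                else 0.0
            )
            lfc.loc[eid, tp] = -np.log2(fc) - shift

    sample_ids = [
        f"{tp}_rep{r + 1}" for tp in TIMEPOINTS for r in range(config.replicates)
    ]
    conditions = {s: s.split("_")[0] for s in sample_ids}
    size = np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(sample_ids)))

    mat = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    lfc_np = lfc.to_numpy()
    for j, sample in enumerate(sample_ids):
        tp = conditions[sample]
        fold = np.ones(len(feature_ids))
        if tp != "0h":
            fold = 2.0 ** lfc_np[:, 0 if tp == "4h" else 1]
        mat[:, j] = _nb_draw(rng, size[j] * q * fold, config.nb_dispersion)

    counts = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
    flags = pd.Series(
        [fid in set(annotation.spikein_ids) for fid in feature_ids], index=feature_ids
    )
    matrix = CountMatrix(counts, flags, conditions)
    truth = CountTruth(
        true_log2fc=lfc,
        down_gene_ids=down_genes,
        size_factors=pd.Series(size, index=sample_ids),
        spikein_ids=list(annotation.spikein_ids),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def simulate_coverage(
    config: SimulationConfig, annotation: Annotation
) -> tuple[CoverageTrack, list[PlantedUnit]]:
    """Plant rectangular transcript units on a noisy coverage background.

    ``n_units_in_enhancers`` units start inside enhancer intervals (their
    TSS is enhancer-contained — the designed eRNA truth); the rest sit in
    reserved intergenic slots. Background noise runs at ``noise_depth``
    (below any sensible calling cutoff) occupy further reserved slots so
    no noise ever touches a planted unit.
    """
    rng = _rng(config, 3)
    unit_len = 1000
    planted: list[PlantedUnit] = []
    eligible = [e for e in annotation.enhancers if len(e.interval) >= 300]
    if len(eligible) < config.n_units_in_enhancers:
        raise ValueError("not enough enhancers to host the requested units")
    chosen = rng.choice(len(eligible), size=config.n_units_in_enhancers, replace=False)
    for k in sorted(chosen):
        e = eligible[k]
        strand = "+" if rng.random() < 0.5 else "-"
        depth = config.planted_unit_depth * float(rng.uniform(1.0, 2.0))
        if strand == "+":
            start = e.interval.start + 50
            iv = GenomicInterval(e.interval.chrom, start, start + unit_len, strand)
        else:
            end = e.interval.end - 50
            iv = GenomicInterval(e.interval.chrom, end - unit_len, end, strand)
        planted.append(PlantedUnit(iv, depth, True, e.enhancer_id))

    n_out = config.n_planted_units - config.n_units_in_enhancers
    for slot in annotation.unit_slots[:n_out]:
        strand = "+" if rng.random() < 0.5 else "-"
        depth = config.planted_unit_depth * float(rng.uniform(1.0, 2.0))
        iv = GenomicInterval(slot.chrom, slot.start, slot.start + unit_len, strand)
        planted.append(PlantedUnit(iv, depth, False))

    plus = [(p.interval, p.depth) for p in planted if p.interval.strand == "+"]
    minus = [(p.interval, p.depth) for p in planted if p.interval.strand == "-"]
    for slot in annotation.noise_slots:
        iv = GenomicInterval(slot.chrom, slot.start, slot.end)
        plus.append((GenomicInterval(iv.chrom, iv.start, iv.end, "+"), config.noise_depth))
        minus.append((GenomicInterval(iv.chrom, iv.start, iv.end, "-"), config.noise_depth))
    track = CoverageTrack(plus=plus, minus=minus)
    return track, planted


# ---------------------------------------------------------------------------
# reference fixture (structural)
# ---------------------------------------------------------------------------


@dataclass
class ReferenceFixture:
    """Structurally constructed dataset for the integration bookkeeping.

    Genes, enhancers and peaks are real interval records on a synthetic
    chromosome; the differential tables carry deterministic log2fc / p
    values consistent with the intended calls at the standard thresholds
    (genes: fold change > 2, adjusted p < 0.05; enhancers: fold change >
    1.5, raw p < 0.05).
    """

    genes: list[GeneModel]
    enhancers: list[EnhancerRecord]
    peaks: list[PeakRecord]
    gene_de: pd.DataFrame
    enhancer_de: pd.DataFrame


def _de_row(log2fc: float, pvalue: float, padj: float) -> dict:
    return {
        "baseMean": 100.0,
        "log2fc": log2fc,
        "se": 0.2,
        "pvalue": pvalue,
        "padj": padj,
        "call": "ns",
    }


def reference_fixture() -> ReferenceFixture:
    """A fixed dataset wired to the canonical integration bookkeeping.

    Catalog: 231 super-enhancers and 8,563 typical enhancers, of which 169
    and 4,577 respectively carry an overlapping peak; 604 downregulated
    genes whose enhancer-class partition is 20 (SE & TE) / 22 (Only SE) /
    311 (Only TE) / 251 (Not assigned); 288 of the down genes and 7 of the
    22 up genes are peak-overlapped; the bound-and-down enhancer targets
    intersect the bound-down genes in 26 (SE branch) and 86 (TE branch)
    genes sharing exactly one member, a 111-gene union.
    """
    chrom = "chrF1"
    slot = 12_000

    down_ids = [f"d_{i:04d}" for i in range(1, 605)]
    up_ids = [f"u_{i:02d}" for i in range(1, 23)]
    filler_ids = [f"f_{i:04d}" for i in range(1, 1001)]

    # partition of the 604 down genes by targeting-enhancer class
    grp_a = down_ids[:20]      # SE & TE
    grp_b = down_ids[20:42]    # Only SE
    grp_c = down_ids[42:353]   # Only TE
    grp_n = down_ids[353:]     # Not assigned (251)

    # gene-level factor binding: 288 bound down genes
    bound_genes = set(
        grp_a                      # 20  (SE-branch overlap members d1..d20)
        + grp_b[:6]                # 6   (SE-branch overlap members d21..d26)
        + grp_c[:85]               # 85  (TE-branch overlap members d43..d127)
        + grp_n[:177]              # 177 (bound down genes with no enhancer)
    )
    bound_genes |= set(up_ids[:7])  # 7 of 22 up genes bound

    # enhancer catalog: (klass, id, target, bound, down)
    enh_spec: list[tuple[str, str, str | None, bool, bool]] = []
    se_n = 0

    def add_se(target: str | None, bound: bool, down: bool) -> None:
        nonlocal se_n
        se_n += 1
        enh_spec.append(("SE", f"SE_{se_n:04d}", target, bound, down))

    for g in grp_a:
        add_se(g, True, True)               # 20 bound+down SEs -> overlap12 seeds
    for g in grp_b[:6]:
        add_se(g, True, True)               # 6 more -> overlap12 = 26
    for g in grp_b[6:]:
        add_se(g, True, False)              # bound, not down
    for k in range(189):                    # remaining SEs target filler genes
        target = filler_ids[k % len(filler_ids)]
        if k < 30:
            add_se(target, True, True)
        elif k < 78:
            add_se(target, False, True)
        elif k < 175:
            add_se(target, True, False)
        else:
            add_se(target, False, False)

    te_n = 0

    def add_te(target: str | None, bound: bool, down: bool) -> None:
        nonlocal te_n
        te_n += 1
        enh_spec.append(("TE", f"TE_{te_n:04d}", target, bound, down))

    add_te(grp_a[0], True, True)            # the one gene shared by both branches
    for g in grp_c[:85]:
        add_te(g, True, True)               # overlap13 = 86
    for g in grp_a[1:]:
        add_te(g, True, False)              # SE&TE genes' TEs: bound, not down
    for g in grp_c[85:]:
        add_te(g, False, True)              # down TEs on unbound genes
    for k in range(8232):                   # remaining TEs target filler genes
        target = filler_ids[(k + 200) % len(filler_ids)]
        if k < 400:
            add_te(target, True, True)
        elif k < 888:
            add_te(target, False, True)
        elif k < 4960:
            add_te(target, True, False)
        else:
            add_te(target, False, False)

    # --- lay intervals on a slot grid ---------------------------------
    genes: list[GeneModel] = []
    gene_de_rows: dict[str, dict] = {}
    peaks: list[PeakRecord] = []
    cursor = 0

    def next_slot() -> int:
        nonlocal cursor
        cursor += slot
        return cursor

    for i, gid in enumerate(down_ids):
        start = next_slot()
        genes.append(GeneModel(gid, GenomicInterval(chrom, start, start + 4000, "+", gid)))
        gene_de_rows[gid] = _de_row(-1.2 - 0.001 * i, 1e-5, 1e-4)
    for i, gid in enumerate(up_ids):
        start = next_slot()
        genes.append(GeneModel(gid, GenomicInterval(chrom, start, start + 4000, "+", gid)))
        gene_de_rows[gid] = _de_row(1.3 + 0.01 * i, 1e-5, 1e-4)
    for i, gid in enumerate(filler_ids):
        start = next_slot()
        genes.append(GeneModel(gid, GenomicInterval(chrom, start, start + 4000, "+", gid)))
        gene_de_rows[gid] = _de_row(0.05, 0.5, 0.8)

    for g in genes:
        if g.gene_id in bound_genes:
            s = g.interval.start + 100
            peaks.append(
                PeakRecord(f"pk_{len(peaks) + 1:05d}", GenomicInterval(chrom, s, s + 200))
            )

    enhancers: list[EnhancerRecord] = []
    enh_de_rows: dict[str, dict] = {}
    for i, (klass, eid, target, bound, down) in enumerate(enh_spec):
        start = next_slot()
        length = 6000 if klass == "SE" else 2000
        enhancers.append(
            EnhancerRecord(eid, GenomicInterval(chrom, start, start + length), klass, target)
        )
        if bound:
            s = start + 100
            peaks.append(
                PeakRecord(f"pk_{len(peaks) + 1:05d}", GenomicInterval(chrom, s, s + 200))
            )
        if down:
            # bound enhancers fall harder: the occupancy-vs-depth contrast
            base = -1.8 if bound else -1.0
            enh_de_rows[eid] = _de_row(base - 0.003 * (i % 97), 1e-3, 5e-3)
        else:
            enh_de_rows[eid] = _de_row(-0.1, 0.6, 0.9)

    gene_de = pd.DataFrame.from_dict(gene_de_rows, orient="index").rename_axis("feature_id")
    enh_de = pd.DataFrame.from_dict(enh_de_rows, orient="index").rename_axis("feature_id")
    return ReferenceFixture(genes, enhancers, peaks, gene_de, enh_de)


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate and write the full simulated study to ``out_dir``.

    Emits genes.gtf, enhancers.bed, peaks.bed, spikeins.txt, counts.tsv,
    cov_plus.bedGraph, cov_minus.bedGraph and truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    matrix, truth = simulate_counts(config, annotation)
    track, planted = simulate_coverage(config, annotation)

    with open(out / "genes.gtf", "w") as fh:
        write_gtf_genes(annotation.genes, fh)
    with open(out / "enhancers.bed", "w") as fh:
        write_enhancer_bed(annotation.enhancers, fh)
    with open(out / "peaks.bed", "w") as fh:
        write_bed([p.interval for p in annotation.peaks], fh)
    with open(out / "spikeins.txt", "w") as fh:
        fh.write("\n".join(annotation.spikein_ids) + "\n")
    with open(out / "counts.tsv", "w") as fh:
        write_counts_tsv(matrix, fh)
    with open(out / "cov_plus.bedGraph", "w") as fh:
        write_bedgraph(track.plus, fh)
    with open(out / "cov_minus.bedGraph", "w") as fh:
        write_bedgraph(track.minus, fh)
    truth_obj = {
        "true_log2fc": {tp: truth.true_log2fc[tp].to_dict() for tp in ("4h", "24h")},
        "down_gene_ids": sorted(truth.down_gene_ids),
        "size_factors": truth.size_factors.to_dict(),
        "bound_enhancer_ids": sorted(annotation.bound_enhancer_ids),
        "planted_units": [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "strand": p.interval.strand,
                "depth": p.depth,
                "in_enhancer": p.in_enhancer,
                "enhancer_id": p.enhancer_id,
            }
            for p in planted
        ],
        "config": asdict(config),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True)
    return out
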