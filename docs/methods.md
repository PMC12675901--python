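# Methods

## Scientific setting

`degronseq` models the analysis of an acute transcription-factor depletion
experiment in mouse embryonic stem cells: the factor (e.g. OCT4 tagged with
an auxin-inducible degron) is destroyed within minutes to hours, and nascent
RNA-seq at 0 h, 4 h and 24 h of induction reads out the immediate
transcriptional consequences. Because depletion of a master regulator
collapses much of the transcriptome at once, ordinary library-size
normalization is invalid — it would rescale the global loss away. The
experimental remedy is exogenous spike-in RNA added in fixed amounts per
sample; the computational counterpart, implemented here, is estimating
sample scaling factors from the spike-in features only.

The pipeline has four analysis stages over a shared interval engine:

1. **quantify** — interval-overlap read counting into a features × samples
   count matrix carrying spike-in flags and condition labels.
2. **diffexpr** — spike-in-calibrated size factors, negative-binomial Wald
   tests, Benjamini–Hochberg adjustment, threshold calling, and the
   Wilcoxon rank-sum test used for group comparisons.
3. **erna_caller** — de-novo transcript-unit segmentation from
   strand-specific coverage, annotation-based exclusion, eRNA designation
   by TSS-in-enhancer containment, and nearest-TSS target assignment.
4. **integrate_report** — ChIP-seq occupancy annotation, the 4-way
   gene–enhancer-class partition, bound-vs-unbound depth comparisons, and
   the direct-target intersection lists.

## Coordinate and interval conventions

All internal coordinates are 0-based half-open `[start, end)`; GTF input
(1-based inclusive) is converted at parse time. The TSS of a −-strand
feature is `end − 1`, the last base of the half-open interval. Overlap is
`a.start < b.end and b.start < a.end` on the same chromosome, with strand
ignored unless a stranded mode is requested. Chromosome names match by
exact string equality; a validator warns when query and subject chromosome
sets are disjoint (the symptom of a `chr1` vs `1` naming mismatch).
Enhancers are unstranded (strand `"."`) and all enhancer queries ignore
strand, reflecting bidirectional enhancer transcription.

## Normalization

Size factors are median-of-ratios: the pseudo-reference is the per-feature
geometric mean across samples over features with no zero count in any
sample; the raw factor of sample *j* is the median of `count[f, j] / ref_f`;
factors are rescaled to geometric mean 1. With `use_spikeins_only=True`
(the default for depletion data) only spike-in features enter the
reference, which makes the factors exactly invariant to any rescaling of
the endogenous rows — the property that lets a global shutdown appear as a
global shutdown rather than be normalized away. The package deliberately
also exposes `all_features` normalization so the bias it induces under
shutdown conditions can be measured (the acceptance script reports both).

## Differential expression model

Counts follow the NB2 parameterisation, `Var = μ + αμ²`. Per-feature
dispersion α is method-of-moments on size-factor-normalized counts:
within-group means and variances (ddof = 1) are pooled across groups
weighted by replicates − 1, and `α = max(ε, (var − mean)/mean²)` with
`ε = 1e−8` (also assigned to all-zero and constant features). There is no
trend fitting, shrinkage or outlier refitting: the package keeps the NB
Wald machinery minimal and fully documented, because the scientifically
load-bearing choices in this analysis are the spike-in calibration and the
calling thresholds, not dispersion moderation.

The test statistic is `log2fc / se` with
`log2fc = log2((m_T + ½)/(m_C + ½))` on normalized group means (the ½
pseudocount prevents infinite fold changes) and the delta-method standard
error

    se² = (1/ln2)² · [ (1/m_T + α)/n_T + (1/m_C + α)/n_C ].

Because both the dispersion and the group means enter the SE as estimates
with `n_T + n_C − 2` residual degrees of freedom, the statistic is referred
to a Student t with that df rather than the standard normal. This is the
standard finite-sample treatment of a Wald statistic with estimated
variance; empirically it brings the null type-I error at 3 vs 3 replicates
to ≈ 0.05 (the normal reference gives ≈ 0.11) and the null p-value
distribution to within KS ≈ 0.02 of uniform. Features with zero counts
everywhere are reported with `log2fc = 0`, `p = 1`, call `ns`.

Calling uses a fold-change threshold on the natural scale and a
significance column: genes at fold change > 2 with BH-adjusted p < 0.05;
enhancer/eRNA transcripts at fold change > 1.5 with raw p < 0.05;
repeat-class features at fold change > 1.5 with adjusted p < 0.05. "Fold
change > 2" is interpreted symmetrically as `|log2fc| ≥ 1`.

The Wilcoxon rank-sum (Mann–Whitney U) test enumerates the full labeling
distribution when `n₁ + n₂ ≤ 12` and the pooled values are tie-free
(two-sided p = `2·min(P(U ≤ u), P(U ≥ u))`, capped at 1); larger or tied
samples use the normal approximation with tie and continuity corrections.

## eRNA calling

Segmentation operates per strand on run-length coverage: positions with
depth ≥ `min_cov` form runs, runs separated by ≤ `max_gap` sub-threshold
bases merge, and merged segments shorter than `min_length` are discarded.
Defaults `min_cov = 2` (normalized depth), `max_gap = 250` bases,
`min_length = 200` bases are declared tool parameters — GRO-seq-style peak
callers do not publish a canonical set — and are CLI-exposed.

Exclusion removes any unit overlapping a protein-coding gene on either
strand (same-strand overlap is genic signal, opposite-strand overlap is the
antisense case; both disqualify a unit as intergenic) or overlapping a
structural ncRNA gene (default excluded biotypes: rRNA, snRNA, miRNA,
snoRNA — deliberately not tRNA). Gene-body overlap, not exon-level overlap,
is used. Per-reason removal tallies are returned so
`|input| = |retained| + Σ removed` is checkable.

A surviving unit is an eRNA iff its TSS lies inside an enhancer interval
(half-open containment, so a TSS at the exclusive end does not qualify).
When several enhancers contain one TSS, the enhancer whose midpoint is
nearest wins, ties broken by lexicographic id — an invented tie-break for a
case the source procedure never discusses. Targets are the nearest
protein-coding TSS within 100 kb (default), with lexicographic tie-break.

## Integration and direct-target logic

An enhancer is *bound* iff ≥ 1 ChIP-seq peak overlaps it; a gene is bound
iff a peak overlaps the gene body. Downregulated genes partition 4-ways by
the class of catalog enhancers whose target column names them: both SE and
TE, only SE, only TE, or neither. Enhancer→target maps come from the
catalog's target column when present and are otherwise re-derived by
nearest TSS. The direct-target lists are pure set algebra: List 1 =
bound ∩ down genes; List 2/3 = targets of bound ∩ down-called SEs/TEs; the
direct-target set is `(L1∩L2) ∪ (L1∩L3)`. Percentages are rounded half
away from zero to one decimal, matching how such tables are printed.

## Synthetic data: what it emulates and what it does not

`simulate_annotation` packs non-overlapping genes (plus a sprinkling of
structural-ncRNA decoys), SE/TE catalogs (SE intervals longer than TE) and
peaks onto a small genome by shuffled left-to-right placement with random
gaps; every enhancer's target is its nearest protein-coding TSS, and
`self_audit` re-derives all recorded truth from the emitted records.
`simulate_counts` draws NB counts with mean `s_j · q_f · FC_f(t)`: true
size factors log-uniform in [0.5, 2]; 60% of genes (default
`frac_direct_down`) truly down 4-fold at 4 h and 8-fold at 24 h; the same
fraction of enhancers down, with bound enhancers depressed an extra 1 log2
unit (`bound_down_shift`); spike-ins flat. `simulate_coverage` plants
rectangular units (20 of 30 starting inside enhancers, by default) plus
sub-threshold background noise in reserved slots.

The generator emulates the *statistical structure* the analysis assumes —
NB replicate noise, constant spike-ins, a dominant shutdown, occupancy
correlated with depth of downregulation — not real data's messiness: no
overlapping genes, no ragged coverage profiles, no mappability artifacts,
no partial-overlap ambiguity (features are planted non-overlapping). A
passing suite therefore demonstrates correctness of the machinery and its
calibration under the stated model, not robustness to annotation or
alignment pathologies.

`reference_fixture()` is different in kind: it *constructs* a catalog of
231 SEs / 8,563 TEs, 604 down and 22 up genes, peaks and differential
tables so that occupancy fractions (169 and 4,577 bound), the 4-way
partition (20/22/311/251), the 288 bound-down genes and the 26- and
86-gene intersection branches (sharing exactly one gene, union 111) emerge
from the real overlap and set machinery. The one-gene overlap between the
two branches is an assumption the fixture encodes; only the union size
constrains it. Quantities with no printed counterpart (e.g. how many TEs
are down-called, 1,200 here) are invented consistently. The fixture is the
exact acceptance surface; the statistical configs are the honest one.

## Problem sizes and numerical choices

Default simulations use 2,000 genes, 140 enhancers, 100 spike-ins and 3
replicates per timepoint — small enough that the full suite runs in
seconds on one core while every statistical check retains power (e.g. the
shutdown calibration bound of ±0.1 on the median null log2fc is resolved
with ~800 null genes). Sub-seeds for the annotation, count and coverage
stages are derived from the one config seed, so stages are independently
reproducible. Ties in nearest-TSS and enhancer-containment break
lexicographically; BH uses a stable mergesort so equal p-values keep input
order; percentage rounding is decimal-based (`ROUND_HALF_UP` on `repr` of
the float) to avoid binary-float surprises at the printed precision.

## Known limitations

- Dispersion estimation at 2–3 replicates is noisy; the t reference
  absorbs most but not all of the resulting anticonservatism, and no
  information is shared across features.
- Multi-overlap reads count toward every overlapped feature; quantification
  over overlapping annotations will double-count (synthetic annotations are
  non-overlapping by construction).
- The eRNA caller does not detect divergent bidirectional pairs or
  deconvolve overlapping units on the same strand.
- Enhancer catalogs and their SE/TE split are inputs, not outputs: the
  package classifies and intersects against a given catalog, it does not
  call enhancers.
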