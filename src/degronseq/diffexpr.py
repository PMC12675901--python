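"""Spike-in-calibrated size factors and negative-binomial Wald tests.

The model is the standard NB2 parameterisation: counts K ~ NB with
E[K] = mu and Var[K] = mu + alpha * mu^2, where alpha >= 0 is the
per-feature dispersion. Size factors use median-of-ratios against a
geometric-mean pseudo-reference; when computed on spike-in features only
they are insensitive to global shifts in endogenous transcription — the
property that makes acute-depletion experiments (where most of the
transcriptome genuinely falls) quantifiable at all. Library-size or
all-feature normalisation silently renormalises a global shutdown away.

Dispersion is method-of-moments on normalized counts pooled within
condition groups; the Wald statistic is log2fc / se with a delta-method
standard error. Deliberately minimal: no dispersion trend shrinkage, no
outlier refitting, no independent filtering — the calibration decision
(spike-ins) and the calling thresholds carry the scientific weight here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix

#: dispersion floor; also assigned to degenerate (all-zero / constant) features
EPSILON_DISPERSION = 1e-8

#: pseudocount added to group means before taking the log2 ratio
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample scaling factors, geometric mean normalized to 1."""

    factors: pd.Series
    method: str  # "spikein" or "all_features"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Differential-call thresholds.

    fc_threshold is on the natural scale (2.0 means |log2fc| >= 1);
    use_adjusted selects BH-adjusted p (gene-style calls) vs raw p
    (enhancer/eRNA-style calls).
    """

    fc_threshold: float = 2.0
    alpha: float = 0.05
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


GENE_THRESHOLDS = Thresholds(2.0, 0.05, use_adjusted=True)
ENHANCER_THRESHOLDS = Thresholds(1.5, 0.05, use_adjusted=False)
REPEAT_THRESHOLDS = Thresholds(1.5, 0.05, use_adjusted=True)


def size_factors(matrix: CountMatrix, use_spikeins_only: bool = True) -> SizeFactors:
    """Median-of-ratios size factors, optionally on spike-in features only.

    Reference r_f = geometric mean of feature f across samples, over
    features with no zero count anywhere; raw factor s_j = median over
    those features of count[f,j] / r_f; factors are rescaled so their
    geometric mean is exactly 1.
    """
    counts = matrix.counts
    if use_spikeins_only:
        counts = counts.loc[matrix.is_spikein]
        if counts.empty:
            raise ValueError("spike-in normalization requested but no spike-in features present")
    eligible = counts.loc[(counts > 0).all(axis=1)]
    if eligible.empty:
        kind = "spike-in " if use_spikeins_only else ""
        raise ValueError(
            f"no {kind}feature has nonzero counts in every sample; "
            "add more spike-ins or samples with coverage"
        )
    logc = np.log(eligible.to_numpy(dtype=float))
    log_ref = logc.mean(axis=1)
    raw = np.exp(np.median(logc - log_ref[:, None], axis=0))
    factors = raw / stats.gmean(raw)
    return SizeFactors(
        pd.Series(factors, index=counts.columns),
        "spikein" if use_spikeins_only else "all_features",
    )


def normalized_counts(matrix: CountMatrix, factors: SizeFactors) -> pd.DataFrame:
    return matrix.counts / factors.factors.reindex(matrix.counts.columns)


def estimate_dispersion(
    matrix: CountMatrix, factors: SizeFactors, groups: dict[str, list[str]]
) -> pd.Series:
    """Method-of-moments NB dispersion per feature, pooled within groups.

    For each group with >=2 replicates the within-group sample mean and
    variance (ddof=1) of normalized counts are computed; pooling averages
    them weighted by (replicates - 1). alpha = max(eps, (var - mean)/mean^2).
    All-zero or constant features get alpha = eps.
    """
    norm = normalized_counts(matrix, factors)
    usable = {g: s for g, s in groups.items() if len(s) >= 2}
    if not usable:
        raise ValueError("dispersion estimation needs >=2 replicates in at least one group")
    num_var = np.zeros(len(norm))
    num_mean = np.zeros(len(norm))
    wsum = 0.0
    for samples in usable.values():
        sub = norm[samples].to_numpy()
        w = len(samples) - 1
        num_var += w * sub.var(axis=1, ddof=1)
        num_mean += w * sub.mean(axis=1)
        wsum += w
    pooled_var = num_var / wsum
    pooled_mean = num_mean / wsum
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(pooled_mean > 0, alpha, EPSILON_DISPERSION)
    alpha = np.maximum(alpha, EPSILON_DISPERSION)
    return pd.Series(alpha, index=norm.index)


def wald_test(
    matrix: CountMatrix,
    factors: SizeFactors,
    dispersions: pd.Series,
    control: str,
    treated: str,
) -> pd.DataFrame:
    """Negative-binomial Wald test of treated vs control group means.

    Returns a DataFrame with feature_id index and columns baseMean, log2fc,
    se, pvalue, padj (BH over features with a defined p), call ("ns" until
    :func:`call_features` fills it).

    log2fc = log2((m_T + c) / (m_C + c)) with pseudocount c = 0.5 on the
    normalized group means. The standard error is the delta method applied
    to the log2 ratio of the two group means of NB variables:

        Var(mean_g) = (mu + alpha mu^2) / n_g        (NB2 variance / replicates)
        Var(log2 mean_g) ~= Var(mean_g) / (mean_g ln 2)^2 = (1/mu + alpha) / (n_g ln2^2)
        se^2 = (1/ln2)^2 [ (1/m_T + alpha)/n_T + (1/m_C + alpha)/n_C ]

    Because both the dispersion and the group means enter the SE as
    estimates with n_T + n_C - 2 residual degrees of freedom, z = log2fc/se
    is referred to a Student t with that df (two-sided) rather than the
    standard normal — the usual finite-sample adjustment of a Wald
    statistic with estimated variance; the normal is used when df < 1.
    Features with zero counts in every sample of both groups get p = 1
    and log2fc = 0.
    """
    ctrl = matrix.samples_for(control)
    trt = matrix.samples_for(treated)
    if not ctrl or not trt:
        raise ValueError(f"both groups need >=1 sample (control={ctrl}, treated={trt})")
    norm = normalized_counts(matrix, factors)
    m_c = norm[ctrl].mean(axis=1).to_numpy()
    m_t = norm[trt].mean(axis=1).to_numpy()
    alpha = dispersions.reindex(norm.index).to_numpy()
    base_mean = norm[ctrl + trt].mean(axis=1).to_numpy()

    log2fc = np.log2((m_t + PSEUDOCOUNT) / (m_c + PSEUDOCOUNT))
    ln2sq = math.log(2) ** 2
    with np.errstate(divide="ignore"):
        var = (
            (1.0 / (m_t + PSEUDOCOUNT) + alpha) / len(trt)
            + (1.0 / (m_c + PSEUDOCOUNT) + alpha) / len(ctrl)
        ) / ln2sq
    se = np.sqrt(var)
    z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    df = len(ctrl) + len(trt) - 2
    if df >= 1:
        pvalue = 2 * stats.t.sf(np.abs(z), df)
    else:
        pvalue = 2 * stats.norm.sf(np.abs(z))

    dead = (base_mean == 0)
    log2fc = np.where(dead, 0.0, log2fc)
    pvalue = np.where(dead, 1.0, pvalue)

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
        },
        index=norm.index,
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["call"] = "ns"
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_features(results: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Fill the call column: up / down / ns by fold change and significance.

    down iff log2fc <= -log2(fc_threshold) and the significance column
    (padj when use_adjusted else pvalue) < alpha; up symmetric; else ns.
    Returns a copy with the call column set.
    """
    out = results.copy()
    lfc_cut = math.log2(thresholds.fc_threshold)
    sig = out["padj"] if thresholds.use_adjusted else out["pvalue"]
    down = (out["log2fc"] <= -lfc_cut) & (sig < thresholds.alpha)
    up = (out["log2fc"] >= lfc_cut) & (sig < thresholds.alpha)
    out["call"] = np.select([down, up], ["down", "up"], default="ns")
    return out


def called_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    return {
        label: set(results.index[results["call"] == label])
        for label in ("up", "down", "ns")
    }


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)
# ---------------------------------------------------------------------------

EXACT_MAX_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (U of x) with a two-sided p-value.

    Exact path: when n1 + n2 <= 12 and the pooled values contain no ties,
    the full C(n1+n2, n1) labeling distribution of U is enumerated and
    p = 2 * min(P(U <= u), P(U >= u)), capped at 1. Otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = stats.rankdata(pooled)
    u_x = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        order = np.argsort(pooled)
        # rank sum over all labelings of which positions belong to sample x
        rank_of = np.empty(n1 + n2)
        rank_of[order] = np.arange(1, n1 + n2 + 1)
        us = np.array(
            [sum(rank_of[list(c)]) - n1 * (n1 + 1) / 2 for c in combinations(range(n1 + n2), n1)]
        )
        p = 2 * min((us <= u_x).mean(), (us >= u_x).mean())
        return float(u_x), float(min(p, 1.0))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_x), float(res.pvalue)
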