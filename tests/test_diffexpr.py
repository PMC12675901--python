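"""Statistics core: size factors, NB Wald calibration, BH, Mann-Whitney."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degronseq.diffexpr import (
    GENE_THRESHOLDS,
    SizeFactors,
    Thresholds,
    bh_adjust,
    call_features,
    estimate_dispersion,
    mann_whitney,
    size_factors,
    wald_test,
)
from degronseq.quantify import CountMatrix


def make_matrix(values, samples, spike_rows=(), conditions=None):
    counts = pd.DataFrame(
        values, index=[f"f{i}" for i in range(len(values))], columns=samples
    )
    flags = pd.Series([i in spike_rows for i in range(len(values))], index=counts.index)
    return CountMatrix(counts, flags, conditions or {})


def nb_matrix(rng, mu, samples, alpha, spike_mean=500.0, n_spike=50, factors=None):
    """NB counts for given per-feature means plus Poisson spike-ins."""
    factors = np.ones(len(samples)) if factors is None else np.asarray(factors)
    n = 1 / alpha
    rows = np.column_stack(
        [rng.negative_binomial(n, n / (n + mu * f)) for f in factors]
    )
    spikes = np.column_stack([rng.poisson(spike_mean * f, n_spike) for f in factors])
    counts = pd.DataFrame(
        np.vstack([rows, spikes]),
        index=[f"g{i}" for i in range(len(mu))] + [f"sp{i}" for i in range(n_spike)],
        columns=samples,
    )
    flags = pd.Series([False] * len(mu) + [True] * n_spike, index=counts.index)
    conds = {s: s.split("_")[0] for s in samples}
    return CountMatrix(counts, flags, conds)


SAMPLES = [f"{c}_rep{r}" for c in ("0h", "4h") for r in (1, 2, 3)]
GROUPS = {"0h": SAMPLES[:3], "4h": SAMPLES[3:]}


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        m = make_matrix([[10, 10], [30, 30]], ["a", "b"], spike_rows=(0, 1))
        sf = size_factors(m, True)
        np.testing.assert_allclose(sf.factors, [1.0, 1.0])

    def test_hand_computed_two_sample_example(self):
        # sample B has exactly twice sample A for every spike-in; after
        # geometric-mean rescaling the factors are (1/sqrt(2), sqrt(2))
        m = make_matrix([[10, 20], [20, 40], [40, 80]], ["A", "B"], spike_rows=(0, 1, 2))
        sf = size_factors(m, True)
        np.testing.assert_allclose(sf.factors, [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_poisson_depth_recovery_within_5pct(self, rng):
        true = np.array([1.0, 0.5, 2.0])
        spikes = np.column_stack([rng.poisson(500 * f, 100) for f in true])
        m = CountMatrix(
            pd.DataFrame(spikes, index=[f"sp{i}" for i in range(100)], columns=list("abc")),
            pd.Series(True, index=[f"sp{i}" for i in range(100)]),
        )
        sf = size_factors(m, True)
        expect = true / stats.gmean(true)
        np.testing.assert_allclose(sf.factors, expect, rtol=0.05)

    def test_spikein_factors_ignore_global_shifts(self, rng):
        m = nb_matrix(rng, rng.lognormal(5, 1, 200), SAMPLES, 0.05)
        base = size_factors(m, True).factors.to_numpy()
        scaled = m.counts.copy()
        scaled.loc[~m.is_spikein, SAMPLES[3:]] = (
            scaled.loc[~m.is_spikein, SAMPLES[3:]] // 8
        )
        m2 = CountMatrix(scaled, m.is_spikein, m.conditions)
        after = size_factors(m2, True).factors.to_numpy()
        np.testing.assert_allclose(base, after, atol=1e-9)

    def test_no_eligible_spikein_is_an_error(self):
        m = make_matrix([[0, 5], [3, 0]], ["a", "b"], spike_rows=(0, 1))
        with pytest.raises(ValueError, match="spike-in"):
            size_factors(m, True)

    def test_geometric_mean_is_one(self, rng):
        m = nb_matrix(rng, rng.lognormal(5, 1, 100), SAMPLES, 0.1)
        sf = size_factors(m, False)
        assert math.isclose(stats.gmean(sf.factors), 1.0, rel_tol=1e-9)


class TestDispersion:
    def test_poisson_counts_hit_floor_mostly(self, rng):
        m = nb_matrix(rng, np.full(300, 500.0), SAMPLES, 1e-12)
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES), "all_features")
        d = estimate_dispersion(m, sf, GROUPS)[:300]
        # Poisson variance ~= mean, so most moment estimates collapse to the floor
        assert float(d.median()) < 0.01

    def test_constant_feature_gets_floor(self):
        m = make_matrix([[7, 7, 7, 7]], list("abcd"), conditions=dict.fromkeys("abcd", "0h"))
        sf = SizeFactors(pd.Series(1.0, index=list("abcd")), "all_features")
        d = estimate_dispersion(m, sf, {"0h": list("abcd")})
        assert d.iloc[0] == pytest.approx(1e-8)

    def test_recovery_with_50_replicates(self, rng):
        samples = [f"0h_rep{r}" for r in range(50)]
        m = nb_matrix(rng, np.full(500, 200.0), samples, 0.1)
        sf = SizeFactors(pd.Series(1.0, index=samples), "all_features")
        d = estimate_dispersion(m, sf, {"0h": samples})[:500]
        assert 0.05 <= float(d.median()) <= 0.2


class TestWald:
    def test_identical_groups_are_null(self):
        m = make_matrix(
            [[10, 10, 10, 10, 10, 10], [55, 55, 55, 55, 55, 55]],
            SAMPLES,
            conditions={s: s.split("_")[0] for s in SAMPLES},
        )
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES), "all_features")
        disp = pd.Series(0.05, index=m.counts.index)
        res = wald_test(m, sf, disp, "0h", "4h")
        assert (res["log2fc"] == 0).all()
        assert (res["pvalue"] > 0.99).all()

    def test_degenerate_group_errors(self, rng):
        m = nb_matrix(rng, np.full(5, 100.0), SAMPLES[:3], 0.05)
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES[:3]), "all_features")
        with pytest.raises(ValueError, match="group"):
            wald_test(m, sf, pd.Series(0.05, index=m.counts.index), "0h", "4h")

    def test_null_type_one_error_calibrated(self, rng):
        m = nb_matrix(rng, rng.lognormal(np.log(200), 1.0, 2000), SAMPLES, 0.05)
        sf = size_factors(m, True)
        disp = estimate_dispersion(m, sf, GROUPS)
        res = wald_test(m, sf, disp, "0h", "4h").iloc[:2000]
        rate = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.08
        ks = stats.kstest(res["pvalue"], "uniform").statistic
        assert ks < 0.05

    def test_fourfold_decrease_recovered(self, rng):
        mu = np.full(500, 200.0)
        n = 1 / 0.05
        ctrl = np.column_stack([rng.negative_binomial(n, n / (n + mu)) for _ in range(3)])
        trt = np.column_stack([rng.negative_binomial(n, n / (n + mu / 4)) for _ in range(3)])
        spikes = np.column_stack([rng.poisson(500, 50) for _ in range(6)])
        counts = pd.DataFrame(
            np.vstack([np.hstack([ctrl, trt]), spikes]),
            index=[f"g{i}" for i in range(500)] + [f"sp{i}" for i in range(50)],
            columns=SAMPLES,
        )
        m = CountMatrix(
            counts,
            pd.Series([False] * 500 + [True] * 50, index=counts.index),
            {s: s.split("_")[0] for s in SAMPLES},
        )
        sf = size_factors(m, True)
        disp = estimate_dispersion(m, sf, GROUPS)
        res = wald_test(m, sf, disp, "0h", "4h").iloc[:500]
        assert abs(float(res["log2fc"].median()) + 2) < 0.3

    def test_all_zero_feature_reported_ns(self):
        m = make_matrix(
            [[0] * 6, [9, 8, 10, 9, 8, 10]],
            SAMPLES,
            conditions={s: s.split("_")[0] for s in SAMPLES},
        )
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES), "all_features")
        res = wald_test(m, sf, pd.Series(0.05, index=m.counts.index), "0h", "4h")
        assert res.loc["f0", "pvalue"] == 1.0
        assert res.loc["f0", "log2fc"] == 0.0


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_stepped_example(self):
        # p(i) * n / i = 0.04 at every rank; the running minimum keeps 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels_and_permutation_equivariant(self, rng):
        from statsmodels.stats.multitest import multipletests

        for n in (1, 2, 10, 1000, 10_000):
            p = rng.uniform(size=n)
            mine = bh_adjust(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(mine, ref, rtol=1e-12)
            perm = rng.permutation(n)
            np.testing.assert_allclose(bh_adjust(p[perm]), mine[perm], rtol=1e-12)
        assert (bh_adjust(rng.uniform(size=100)) >= 0).all()


class TestCallFeatures:
    def frame(self, rows):
        df = pd.DataFrame(rows, columns=["log2fc", "pvalue", "padj"])
        df["call"] = "ns"
        return df

    def test_threshold_rules(self):
        df = self.frame([[-1.2, 1e-3, 0.01], [-0.9, 1e-4, 0.001], [1.1, 1e-3, 0.01]])
        out = call_features(df, GENE_THRESHOLDS)
        assert out["call"].tolist() == ["down", "ns", "up"]

    def test_raw_p_mode(self):
        df = self.frame([[-0.7, 0.01, 0.5]])
        assert call_features(df, Thresholds(1.5, 0.05, use_adjusted=False))["call"].iloc[0] == "down"
        assert call_features(df, Thresholds(1.5, 0.05, use_adjusted=True))["call"].iloc[0] == "ns"

    def test_partition_is_exhaustive(self, rng):
        df = self.frame(
            np.column_stack(
                [rng.normal(0, 2, 500), rng.uniform(size=500), rng.uniform(size=500)]
            )
        )
        out = call_features(df, GENE_THRESHOLDS)
        assert out["call"].isin(["up", "down", "ns"]).all()
        assert len(out) == 500


class TestMannWhitney:
    def test_small_exact_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_path_matches_scipy_exact(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 13 - n1))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            _, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(float(ref), abs=1e-12)

    def test_approx_close_to_exact_at_n15(self, rng):
        for _ in range(50):
            vals = rng.permutation(np.arange(1.0, 31.0))
            x, y = vals[:15], vals[15:]
            _, p = mann_whitney(x, y)  # approximate path (n too large for enumeration)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert abs(p - float(ref)) <= 0.02
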