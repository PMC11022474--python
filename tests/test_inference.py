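"""Correlation, dependent-correlation, quintile and Wald-test statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietscore as ds
from dietscore.exceptions import CollinearityError, ConvergenceError, DegenerateInputError


class TestSpearmanCI:
    def test_identity_and_antitone(self):
        x = np.arange(20.0)
        assert ds.spearman_ci(x, x).rho == pytest.approx(1.0)
        assert ds.spearman_ci(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 3.0, 1.0, 4.0, 6.0, 7.0, 6.0, 9.0])
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        res = ds.spearman_ci(x, y)
        assert res.rho == pytest.approx(expected)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_fisher_interval_uses_rank_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        res = ds.spearman_ci(x, y)
        z = np.arctanh(res.rho)
        half = 1.959963984540054 * np.sqrt(1.06 / 97)
        assert res.ci_low == pytest.approx(np.tanh(z - half))
        assert res.ci_high == pytest.approx(np.tanh(z + half))

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            ds.spearman_ci(np.ones(10), np.arange(10.0))


class TestCompareDependentCorrelations:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = ds.compare_dependent_correlations(x, x, y)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_analytic_and_permutation_agree_on_small_sample(self):
        rng = np.random.default_rng(2)
        n = 50
        latent = rng.normal(size=n)
        x1 = latent + rng.normal(size=n)
        x2 = latent + rng.normal(size=n)
        y = latent + rng.normal(size=n)
        pa = ds.compare_dependent_correlations(x1, x2, y, method="analytic").p
        pp = ds.compare_dependent_correlations(
            x1, x2, y, method="permutation", n_perm=10_000, seed=7
        ).p
        assert pp == pytest.approx(pa, abs=0.02)

    def test_detects_a_genuinely_stronger_metric(self):
        rng = np.random.default_rng(3)
        n = 400
        y = rng.normal(size=n)
        strong = y + 0.5 * rng.normal(size=n)
        weak = y + 2.0 * rng.normal(size=n)
        res = ds.compare_dependent_correlations(strong, weak, y)
        assert res.p < 0.001 and res.rho1 > res.rho2

    def test_permutation_reproducible_with_seed(self):
        rng = np.random.default_rng(4)
        x1, x2, y = rng.normal(size=(3, 40))
        p1 = ds.compare_dependent_correlations(x1, x2, y, method="permutation",
                                               n_perm=500, seed=5).p
        p2 = ds.compare_dependent_correlations(x1, x2, y, method="permutation",
                                               n_perm=500, seed=5).p
        assert p1 == p2


class TestAssignQuintiles:
    def test_uniform_grid_splits_evenly(self):
        labels = ds.assign_quintiles(np.arange(1.0, 101.0))
        assert np.bincount(labels, minlength=6)[1:].tolist() == [20] * 5

    def test_boundary_ties_take_the_lower_quintile(self):
        values = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        cuts = np.percentile(values, [20, 40, 60, 80])
        labels = ds.assign_quintiles(values)
        for v, l in zip(values, labels):
            assert l == 1 + int(np.sum(cuts < v))

    def test_all_equal_values_warn_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ds.assign_quintiles(np.ones(50))

    def test_weighted_quintiles_balance_weight_shares(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=2000)
        weights = rng.uniform(0.2, 3.0, 2000)
        labels = ds.assign_quintiles(values, weights)
        shares = np.array([weights[labels == q].sum() for q in range(1, 6)]) / weights.sum()
        assert np.all(np.abs(shares - 0.2) <= weights.max() / weights.sum() + 1e-12)


def _simulate_quintile_outcome(rng, n, slope, intercept=0.0):
    q = rng.integers(1, 6, size=n)
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * (q - 1))))
    return (rng.random(n) < p).astype(int), q


class TestQuintileLogistic:
    def test_covariate_free_ors_equal_contingency_cross_products(self):
        rng = np.random.default_rng(8)
        y, q = _simulate_quintile_outcome(rng, 3000, slope=-0.3, intercept=0.5)
        res = ds.quintile_logistic(y, q)
        for j in (2, 3, 4, 5):
            a1 = ((q == j) & (y == 1)).sum()
            a0 = ((q == j) & (y == 0)).sum()
            b1 = ((q == 1) & (y == 1)).sum()
            b0 = ((q == 1) & (y == 0)).sum()
            expected = (a1 * b0) / (a0 * b1)
            assert res.or_by_quintile[j][0] == pytest.approx(expected, rel=1e-6)

    def test_null_outcome_gives_or_near_one(self):
        rng = np.random.default_rng(9)
        y, q = _simulate_quintile_outcome(rng, 4000, slope=0.0)
        res = ds.quintile_logistic(y, q)
        for j in (2, 3, 4, 5):
            lo, hi = res.or_by_quintile[j][1], res.or_by_quintile[j][2]
            assert lo < 1.2 and hi > 0.8  # interval near 1

    def test_trend_slope_recovered_within_ci(self):
        rng = np.random.default_rng(10)
        y, q = _simulate_quintile_outcome(rng, 10_000, slope=-0.35, intercept=0.3)
        res = ds.quintile_logistic(y, q)
        lo, hi = res.trend_slope_ci
        assert lo <= -0.35 <= hi
        assert res.p_trend < 1e-6

    def test_covariate_adjustment_accepts_categoricals(self):
        rng = np.random.default_rng(11)
        y, q = _simulate_quintile_outcome(rng, 1500, slope=-0.3, intercept=0.4)
        cov = pd.DataFrame(
            {
                "age_range": rng.choice(["10-19", "20-59", "60+"], 1500),
                "income": rng.choice(["i1", "i2", "i3", "i4", "i5"], 1500),
            }
        )
        res = ds.quintile_logistic(y, q, covariates=cov)
        assert res.or_by_quintile[1][0] == 1.0
        assert res.p_trend < 0.01

    def test_separation_raises_convergence_error(self):
        q = np.tile([1, 2, 3, 4, 5], 20)
        y = (q >= 4).astype(int)  # outcome perfectly determined by quintile
        with pytest.raises(ConvergenceError):
            ds.quintile_logistic(y, q)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(DegenerateInputError):
            ds.quintile_logistic(np.ones(100), np.tile([1, 2, 3, 4, 5], 20))


class TestCompareMetricsWald:
    def test_identical_quintiles_raise_collinearity(self):
        rng = np.random.default_rng(12)
        y, q = _simulate_quintile_outcome(rng, 500, slope=-0.2)
        with pytest.raises(CollinearityError):
            ds.compare_metrics_wald(y, q, q)

    def test_power_exceeds_alpha_and_grows_with_effect_gap(self):
        alpha, reps, n = 0.05, 60, 1200
        rejections = {}
        for gap_idx, (sa, sb) in enumerate([(-0.5, -0.25), (-0.8, -0.1)]):
            rng = np.random.default_rng(100 + gap_idx)
            hits = 0
            for _ in range(reps):
                latent = rng.normal(size=n)
                qa = ds.assign_quintiles(latent + 0.6 * rng.normal(size=n))
                qb = ds.assign_quintiles(latent + 0.6 * rng.normal(size=n))
                logit = 0.2 + sa * (qa - 1) + sb * (qb - 1)
                y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
                try:
                    _, p = ds.compare_metrics_wald(y, qa, qb)
                except ConvergenceError:
                    continue
                hits += p < alpha
            rejections[gap_idx] = hits / reps
        assert rejections[0] > alpha
        assert rejections[1] > rejections[0]


class TestAdequacyLinearTrend:
    def test_constant_outcome_gives_zero_deltas(self):
        q = np.tile([1, 2, 3, 4, 5], 30)
        res = ds.adequacy_linear_trend(np.full(150, 0.6), q)
        for j in (2, 3, 4, 5):
            assert res.deltas[j][0] == pytest.approx(0.0, abs=1e-12)
        assert res.trend_slope == pytest.approx(0.0, abs=1e-12)

    def test_covariate_free_deltas_equal_group_mean_differences(self):
        rng = np.random.default_rng(13)
        q = rng.integers(1, 6, 800)
        y = 0.4 + 0.05 * q + rng.normal(0, 0.1, 800)
        res = ds.adequacy_linear_trend(y, q)
        means = {j: y[q == j].mean() for j in range(1, 6)}
        for j in (2, 3, 4, 5):
            assert res.deltas[j][0] == pytest.approx(means[j] - means[1], rel=1e-9)

    def test_linear_trend_recovered_within_ci(self):
        rng = np.random.default_rng(14)
        q = rng.integers(1, 6, 5000)
        y = 0.5 + 0.04 * (q - 1) + rng.normal(0, 0.15, 5000)
        res = ds.adequacy_linear_trend(y, q)
        se = 0.15 / np.sqrt(5000)  # loose scale check only
        assert res.trend_slope == pytest.approx(0.04, abs=10 * se)
        assert res.p_trend < 1e-6
        assert res.delta_q5_p < 1e-6

    def test_joint_delta_comparison_rejects_identical_metrics(self):
        rng = np.random.default_rng(15)
        q = rng.integers(1, 6, 300)
        y = rng.normal(size=300)
        with pytest.raises(CollinearityError):
            ds.compare_metrics_delta(y, q, q)
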