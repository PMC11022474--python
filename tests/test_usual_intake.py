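"""Variance decomposition, shrinkage and the residual energy adjustment."""

import numpy as np
import pandas as pd
import pytest

import dietscore as ds
from dietscore.exceptions import DegenerateInputError


def _repeat_data(rng, n, k, sigma_b, sigma_w, mu=10.0):
    person = np.repeat(np.arange(n), k)
    effects = rng.normal(0, sigma_b, n)
    values = mu + effects[person] + rng.normal(0, sigma_w, n * k)
    return person, values


class TestEstimateComponents:
    def test_identical_days_give_zero_within_variance(self):
        persons = ["a", "a", "b", "b", "c", "c"]
        values = [5.0, 5.0, 8.0, 8.0, 2.0, 2.0]
        comp = ds.estimate_components(persons, values)
        assert comp.sigma2_within == 0.0
        assert comp.lambda_k(2) == 1.0

    def test_identical_persons_give_zero_between_variance(self):
        persons = ["a", "a", "b", "b", "c", "c"]
        values = [4.0, 6.0, 4.0, 6.0, 4.0, 6.0]
        comp = ds.estimate_components(persons, values)
        assert comp.sigma2_between == 0.0
        assert comp.lambda_k(2) == 0.0

    def test_recovers_known_components_within_10pct(self):
        rng = np.random.default_rng(42)
        persons, values = _repeat_data(rng, 2000, 2, sigma_b=1.0, sigma_w=1.0)
        comp = ds.estimate_components(persons, values)
        assert comp.sigma2_between == pytest.approx(1.0, rel=0.10)
        assert comp.sigma2_within == pytest.approx(1.0, rel=0.10)

    def test_lambda_bounded_and_monotone_in_k(self):
        rng = np.random.default_rng(1)
        persons, values = _repeat_data(rng, 200, 2, sigma_b=0.7, sigma_w=1.3)
        comp = ds.estimate_components(persons, values)
        lams = [comp.lambda_k(k) for k in range(1, 8)]
        assert all(0.0 <= l <= 1.0 for l in lams)
        assert all(a <= b for a, b in zip(lams, lams[1:]))

    def test_single_recall_everywhere_is_an_error(self):
        with pytest.raises(DegenerateInputError, match="two or more recalls"):
            ds.estimate_components(["a", "b", "c"], [1.0, 2.0, 3.0])

    def test_log_transform_round_trip_at_lambda_one(self):
        persons = ["a", "a", "b", "b"]
        values = [10.0, 10.0, 40.0, 40.0]
        comp = ds.estimate_components(persons, values, transform="log")
        assert comp.sigma2_within == 0.0
        usual = ds.shrink_to_usual(np.log(np.array([10.0, 40.0]) + 1.0), 2, comp)
        assert usual == pytest.approx([10.0, 40.0])


class TestShrinkToUsual:
    def test_no_noise_limit_returns_person_mean(self):
        comp = ds.VarianceComponents("identity", 0.0, 10.0, 1.0, 0.0, 100)
        assert ds.shrink_to_usual(13.0, 2, comp) == pytest.approx(13.0)

    def test_all_noise_limit_returns_population_mean(self):
        comp = ds.VarianceComponents("identity", 0.0, 10.0, 0.0, 2.0, 100)
        assert ds.shrink_to_usual(13.0, 2, comp) == pytest.approx(10.0)

    def test_shrinkage_reduces_variance_across_persons(self):
        rng = np.random.default_rng(7)
        persons, values = _repeat_data(rng, 500, 2, sigma_b=0.8, sigma_w=1.2)
        daily = pd.DataFrame({"person_id": persons, "x": values})
        usual, comp = ds.usual_intakes(daily, "x")
        raw_means = daily.groupby("person_id")["x"].mean()
        assert usual.var() < raw_means.var()


class TestEnergyAdjust:
    def test_proportional_nutrient_collapses_to_its_mean(self):
        e = pd.Series([1500.0, 2000.0, 2500.0, 3000.0], index=list("abcd"))
        nut = 0.03 * e
        adj = ds.energy_adjust(nut, e)
        assert np.allclose(adj, nut.mean())

    def test_independent_nutrient_is_left_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        idx = [f"p{i}" for i in range(500)]
        e = pd.Series(rng.normal(2000, 300, 500), index=idx)
        nut = pd.Series(rng.normal(50, 10, 500), index=idx)
        adj = ds.energy_adjust(nut, e)
        assert adj.var() == pytest.approx(nut.var(), rel=0.05)

    def test_six_point_fixture_matches_closed_form_regression(self):
        e = pd.Series([1600.0, 1800.0, 2000.0, 2200.0, 2400.0, 2600.0],
                      index=list("abcdef"))
        nut = pd.Series([40.0, 50.0, 45.0, 60.0, 55.0, 70.0], index=list("abcdef"))
        slope = ((e - e.mean()) * (nut - nut.mean())).sum() / ((e - e.mean()) ** 2).sum()
        intercept = nut.mean() - slope * e.mean()
        residuals = nut - (intercept + slope * e)
        expected = residuals + intercept + slope * e.mean()
        adj = ds.energy_adjust(nut, e)
        assert np.allclose(adj, expected)

    def test_adjusted_values_exactly_orthogonal_to_energy(self):
        rng = np.random.default_rng(9)
        idx = [f"p{i}" for i in range(800)]
        e = pd.Series(rng.normal(2000, 250, 800), index=idx)
        nut = pd.Series(20 + 0.02 * e + rng.normal(0, 8, 800), index=idx)
        adj = ds.energy_adjust(nut, e)
        r = np.corrcoef(adj, e)[0, 1]
        assert abs(r) < 1e-10

    def test_constant_energy_is_an_error(self):
        e = pd.Series([2000.0] * 4, index=list("abcd"))
        nut = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(DegenerateInputError, match="constant"):
            ds.energy_adjust(nut, e)
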