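"""Synthetic-population generator: determinism, coupling, toy fixture."""

import io

import numpy as np
import pandas as pd
import pytest

import dietscore as ds
from dietscore.exceptions import ConfigError
from dietscore.simulate import GDQS_TO_MDDW, _GROUP_DEFAULTS


class TestSimulatePopulation:
    def test_same_seed_gives_byte_identical_output(self):
        params = ds.SimulationParams(n_persons=60, seed=21)
        frames = []
        for _ in range(2):
            records, _, _ = ds.simulate_population(params)
            buf = io.StringIO()
            records.to_csv(buf, index=False)
            frames.append(buf.getvalue())
        assert frames[0] == frames[1]

    def test_different_seeds_differ(self):
        a, _, _ = ds.simulate_population(ds.SimulationParams(n_persons=40, seed=1))
        b, _, _ = ds.simulate_population(ds.SimulationParams(n_persons=40, seed=2))
        assert not a.equals(b)

    def test_every_item_is_mapped_and_days_are_two(self, small_population):
        records, gmap, _ = small_population
        assert set(records["item_id"]) <= set(gmap.gdqs_group)
        assert set(records["recall_day"]) == {1, 2}

    def test_zero_inflation_matches_group_parameters(self, small_population):
        """Groups configured with heavy zero-inflation are rarely consumed."""
        records, gmap, truth = small_population
        n_days = records.groupby(["person_id", "recall_day"]).ngroups
        groups = records["item_id"].map(gmap.gdqs_group)
        for g, (p_zero, _, _) in _GROUP_DEFAULTS.items():
            days_with = records[groups == g].groupby(["person_id", "recall_day"]).ngroups
            observed_zero = 1 - days_with / n_days
            assert observed_zero == pytest.approx(p_zero, abs=0.12)

    def test_infeasible_upf_coupling_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            ds.SimulationParams(upf_quality_correlation=-0.95)

    def test_zero_coupling_yields_null_odds_ratios_downstream(self, requirements, table):
        params = ds.SimulationParams(
            n_persons=800, seed=31, inadequacy_log_or_step=0.0
        )
        records, gmap, truth = ds.simulate_population(params)
        scores = ds.score_population(records, gmap, table)
        _, adeq, _ = ds.run_adequacy(records, requirements)
        df = scores.merge(adeq, on="person_id")
        res = ds.quintile_logistic(
            df["inadequate"].astype(int), ds.assign_quintiles(df["gdqs"].to_numpy())
        )
        for j in (2, 3, 4, 5):
            lo, hi = res.or_by_quintile[j][1:]
            assert lo < 1.0 < hi or (0.6 < res.or_by_quintile[j][0] < 1.6)

    def test_quality_drives_gdqs_and_upf_in_opposite_directions(self, small_population, table):
        records, gmap, truth = small_population
        scores = ds.score_population(records, gmap, table).set_index("person_id")
        q = truth.quality.loc[scores.index]
        assert ds.spearman_ci(q, scores["gdqs"]).rho > 0.3
        assert ds.spearman_ci(q, scores["upf_pct_energy"]).rho < -0.05

    def test_energy_variance_components_recovered(self):
        params = ds.SimulationParams(n_persons=2000, seed=41)
        records, _, _ = ds.simulate_population(params)
        daily = ds.daily_nutrient_totals(records)
        comp = ds.estimate_components(
            daily["person_id"], daily["energy_kcal"], transform="log", shift=0.0
        )
        assert comp.sigma2_between == pytest.approx(params.energy_sigma2_between, rel=0.10)
        assert comp.sigma2_within == pytest.approx(params.energy_sigma2_within, rel=0.10)

    def test_covariates_have_expected_schema(self, small_population):
        _, _, truth = small_population
        cols = set(truth.covariates.columns)
        assert {"person_id", "sex", "age_range", "locality", "income",
                "region", "supplement", "diet_change", "weight"} <= cols


class TestToyFixture:
    def test_hand_computed_scores_reproduced(self, toy, table):
        records, gmap, expected = toy
        scores = ds.score_population(records, gmap, table).set_index("person_id")
        best = scores.loc["p_best"]
        assert (best["gdqs"], best["gdqs_plus"], best["gdqs_minus"], best["risk"]) == (
            49.0, 32.0, 17.0, "low",
        )
        staple = scores.loc["p_staple"]
        assert staple["gdqs"] == expected["p_staple"]["gdqs"]
        assert staple["risk"] == "high"
        assert staple["mddw_score"] == expected["p_staple"]["mddw"]
        assert staple["upf_pct_energy"] == 0.0
        assert scores.loc["p_upf", "upf_pct_energy"] == pytest.approx(25.0)
        assert scores.loc["p_mddw6", "mddw_score"] == 6
        assert scores.loc["p_mddw6", "meets_mdd"]

    def test_mddw_mapping_covers_all_25_groups(self):
        assert set(GDQS_TO_MDDW) == set(_GROUP_DEFAULTS)
        used = {g for g in GDQS_TO_MDDW.values() if g is not None}
        assert used <= set(ds.MDDW_GROUPS)
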