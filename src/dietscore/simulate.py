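"""Synthetic two-recall dietary datasets with known ground truth.

The generator emulates the structure of a two-day 24-h-recall survey so the
whole pipeline is testable without any survey download:

* a latent person-level diet-quality factor ``q ~ N(0, 1)`` loads positively
  on healthy food-group consumption and negatively on unhealthy groups;
* group gram amounts are zero-inflated lognormal per person-day (real recall
  data show heavy zero-intake prevalence for many groups, which the
  zero-inflation reproduces);
* the overall-inadequacy outcome is drawn from a logistic model linear in
  the person's quality-quintile code 0..4 with a configurable log-odds slope
  (the "target odds ratio per quintile step"); nutrient usual intakes are
  then placed above or below their requirement consistently with the drawn
  status, with controllable between/within-person log-scale variances, so
  that the usual-intake and adequacy stages can reconstruct the outcome;
* the ultra-processed energy share is coupled to ``q`` on the log-odds
  (logit) scale at a configurable correlation;
* sociodemographic covariates and person weights are drawn from
  configurable categorical distributions.

Identical seeds produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ScoringTable, default_scoring_table
from .core import MDDW_GROUPS, GroupMap, records_to_frame, FoodRecord
from .exceptions import ConfigError

#: GDQS group -> MDD-W group (None: contributes to no MDD-W group).
GDQS_TO_MDDW = {
    "whole_grains": "grains_white_roots_tubers_plantains",
    "refined_grains_baked_goods": "grains_white_roots_tubers_plantains",
    "white_roots_tubers": "grains_white_roots_tubers_plantains",
    "legumes": "pulses",
    "nuts_seeds": "nuts_seeds",
    "low_fat_dairy": "dairy",
    "high_fat_dairy": "dairy",
    "fish_shellfish": "meat_poultry_fish",
    "poultry_game_meat": "meat_poultry_fish",
    "red_meat": "meat_poultry_fish",
    "processed_meat": "meat_poultry_fish",
    "eggs": "eggs",
    "dark_green_leafy_vegetables": "dark_green_leafy_vegetables",
    "deep_orange_vegetables": "other_vitamin_a_rich",
    "deep_orange_fruits": "other_vitamin_a_rich",
    "deep_orange_tubers": "other_vitamin_a_rich",
    "cruciferous_vegetables": "other_vegetables",
    "other_vegetables": "other_vegetables",
    "citrus_fruits": "other_fruits",
    "other_fruits": "other_fruits",
    "liquid_oils": None,
    "sugar_sweetened_beverages": None,
    "juice": None,
    "sweets_ice_cream": None,
    "purchased_deep_fried_foods": None,
}

#: NOVA class per synthetic GDQS group (4 = ultra-processed).
GDQS_NOVA = {
    "sugar_sweetened_beverages": 4,
    "sweets_ice_cream": 4,
    "processed_meat": 4,
    "purchased_deep_fried_foods": 4,
    "refined_grains_baked_goods": 3,
    "juice": 3,
    "liquid_oils": 2,
}

# (p_zero, median grams when consumed, day log-sd) per group; zero-inflation
# is heavy for the groups real recall surveys rarely capture in one day.
_GROUP_DEFAULTS = {
    "dark_green_leafy_vegetables": (0.75, 25, 0.5),
    "cruciferous_vegetables": (0.90, 30, 0.5),
    "deep_orange_vegetables": (0.92, 25, 0.5),
    "other_vegetables": (0.45, 60, 0.5),
    "deep_orange_fruits": (0.90, 80, 0.5),
    "citrus_fruits": (0.80, 60, 0.5),
    "other_fruits": (0.65, 80, 0.5),
    "legumes": (0.35, 60, 0.5),
    "deep_orange_tubers": (0.93, 40, 0.5),
    "nuts_seeds": (0.95, 12, 0.5),
    "whole_grains": (0.90, 15, 0.5),
    "liquid_oils": (0.30, 6, 0.4),
    "fish_shellfish": (0.85, 60, 0.5),
    "poultry_game_meat": (0.60, 70, 0.5),
    "low_fat_dairy": (0.90, 100, 0.5),
    "eggs": (0.60, 35, 0.5),
    "white_roots_tubers": (0.70, 70, 0.5),
    "processed_meat": (0.60, 30, 0.5),
    "refined_grains_baked_goods": (0.05, 180, 0.4),
    "sugar_sweetened_beverages": (0.35, 180, 0.6),
    "juice": (0.60, 120, 0.5),
    "sweets_ice_cream": (0.50, 30, 0.6),
    "purchased_deep_fried_foods": (0.75, 40, 0.5),
    "red_meat": (0.35, 80, 0.5),
    "high_fat_dairy": (0.60, 60, 0.6),
}

_ROLE_LOADINGS = {"healthy": (0.9, 0.3), "unhealthy": (-0.6, -0.2),
                  "unhealthy_excess": (-0.3, -0.1)}  # (logit, log-amount)

#: nutrient -> (log-scale mean at the requirement, default units)
_NUTRIENT_SCALE = {
    "protein": 38.0,
    "fiber": 25.0,
    "calcium": 800.0,
    "iron": 9.0,
    "zinc": 6.8,
    "vitamin_a": 500.0,
    "folate": 320.0,
    "vitamin_b12": 2.0,
}


@dataclass(frozen=True)
class NutrientSim:
    """Log-scale generation parameters for one nutrient's daily intake."""

    scale: float  # natural-scale level around the requirement
    sigma2_between: float = 0.0225
    sigma2_within: float = 0.09

    def __post_init__(self):
        if self.scale <= 0 or self.sigma2_between <= 0 or self.sigma2_within <= 0:
            raise ConfigError("nutrient scale and variances must be positive")


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters of the synthetic population."""

    n_persons: int = 2000
    recalls_per_person: int = 2
    seed: int = 0
    # zero-inflated lognormal group intakes: group -> (p_zero, median g, log sd)
    group_params: dict = field(default_factory=lambda: dict(_GROUP_DEFAULTS))
    nutrient_params: dict = field(
        default_factory=lambda: {n: NutrientSim(s) for n, s in _NUTRIENT_SCALE.items()}
    )
    # outcome model: logit P(inadequate) = intercept + slope * quintile_code(q)
    inadequacy_log_or_step: float = -0.55
    inadequacy_intercept: float = 0.8
    # log-scale gap separating adequate from inadequate nutrient placement
    adequacy_separation: float = 0.8
    # target correlation between q and the UPF share on the logit scale
    upf_quality_correlation: float = -0.20
    upf_logit_mean: float = -1.35  # ~20% mean energy share
    upf_logit_sd: float = 0.8
    energy_mean_kcal: float = 2000.0
    energy_sigma2_between: float = 0.04
    energy_sigma2_within: float = 0.0225

    def __post_init__(self):
        if self.n_persons < 2:
            raise ConfigError("n_persons must be >= 2")
        if self.recalls_per_person < 1:
            raise ConfigError("recalls_per_person must be >= 1")
        if abs(self.upf_quality_correlation) > 0.8:
            raise ConfigError(
                "infeasible UPF coupling: |target correlation| > 0.8 cannot be "
                "reached through the noisy share model"
            )
        for g, (p0, med, sd) in self.group_params.items():
            if not (0.0 <= p0 <= 1.0):
                raise ConfigError(f"group {g!r}: zero-inflation probability not in [0, 1]")
            if med <= 0 or sd <= 0:
                raise ConfigError(f"group {g!r}: amount parameters must be positive")
        if self.energy_sigma2_between <= 0 or self.energy_sigma2_within <= 0:
            raise ConfigError("energy variance components must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    params: SimulationParams
    quality: pd.Series  # latent factor per person
    quintile_code: pd.Series  # 0..4, quintile of the latent factor
    inadequate: pd.Series  # generated outcome per person
    covariates: pd.DataFrame  # person-level covariates incl. survey weight
    logit_intercept: float
    logit_slope: float
    upf_logit_corr_target: float


def _quality_quintile_code(q: np.ndarray) -> np.ndarray:
    cuts = np.percentile(q, [20, 40, 60, 80])
    return np.searchsorted(np.sort(cuts), q, side="left")


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sociodemographic covariates with population-survey-like frequencies."""
    return pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], n, p=[0.49, 0.51]),
            "age_range": rng.choice(["10-19", "20-59", "60+"], n, p=[0.18, 0.64, 0.18]),
            "locality": rng.choice(["urban", "rural"], n, p=[0.86, 0.14]),
            "income": rng.choice(
                ["i1", "i2", "i3", "i4", "i5"], n, p=[0.41, 0.34, 0.12, 0.07, 0.06]
            ),
            "region": rng.choice(
                ["north", "northeast", "southeast", "south", "midwest"],
                n,
                p=[0.08, 0.27, 0.43, 0.14, 0.08],
            ),
            "supplement": rng.choice(["no", "yes"], n, p=[0.81, 0.19]),
            "diet_change": rng.choice(["no", "yes"], n, p=[0.86, 0.14]),
            "weight": np.exp(rng.normal(0.0, 0.3, n)),
        }
    )


def default_group_map(items_per_group: int = 2) -> GroupMap:
    """Synthetic item map: ``items_per_group`` item ids per GDQS group."""
    gdqs, mddw, nova = {}, {}, {}
    for group in _GROUP_DEFAULTS:
        for j in range(items_per_group):
            item = f"{group}_{chr(ord('a') + j)}"
            gdqs[item] = group
            mddw[item] = GDQS_TO_MDDW[group]
            nova[item] = GDQS_NOVA.get(group, 1)
    return GroupMap(gdqs_group=gdqs, mddw_group=mddw, nova_class=nova)


def simulate_population(
    params: SimulationParams | None = None,
) -> tuple[pd.DataFrame, GroupMap, SimulationTruth]:
    """Generate a two-recall population with known ground truth.

    Returns the long-format record frame, the synthetic item map, and the
    truth record (latent quality, generated outcome, covariates, coupling
    parameters).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    n, k = params.n_persons, params.recalls_per_person
    persons = np.array([f"p{i:05d}" for i in range(n)])

    q = rng.normal(0.0, 1.0, n)
    qcode = _quality_quintile_code(q)
    covars = simulate_covariates(n, rng)
    covars.insert(0, "person_id", persons)

    # outcome: logistic in the quality-quintile code
    logit = params.inadequacy_intercept + params.inadequacy_log_or_step * qcode
    inadequate = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # nutrient usual intakes placed consistently with the outcome
    sep = params.adequacy_separation
    usual_log = {}
    for nut, spec in params.nutrient_params.items():
        shift = np.where(inadequate, -sep / 2.0, sep / 2.0)
        b = rng.normal(0.0, np.sqrt(spec.sigma2_between), n)
        usual_log[nut] = np.log(spec.scale) + shift + b

    # energy usual intake (no coupling to the outcome)
    e_person = np.log(params.energy_mean_kcal) + rng.normal(
        0.0, np.sqrt(params.energy_sigma2_between), n
    )

    # UPF share on the logit scale, correlated with q at the target level
    t = params.upf_quality_correlation
    c = params.upf_logit_sd * t / np.sqrt(max(1.0 - t**2, 1e-12))
    upf_person = params.upf_logit_mean + c * q  # noise added per day below

    group_names = list(params.group_params)
    table_roles = {g.name: g.role for g in default_scoring_table().groups}
    records = []
    for i in range(n):
        for day in range(1, k + 1):
            day_groups = []
            for g in group_names:
                p0, med, sd = params.group_params[g]
                role = table_roles.get(g, "healthy")
                load_c, load_a = _ROLE_LOADINGS[role]
                # consumption probability on the logit scale, shifted by quality
                base = np.log((1 - p0) / p0) if 0 < p0 < 1 else (30.0 if p0 == 0 else -30.0)
                p_consume = 1.0 / (1.0 + np.exp(-(base + load_c * q[i])))
                if rng.random() >= p_consume:
                    continue
                grams = float(np.exp(np.log(med) + load_a * q[i] + sd * rng.normal()))
                item = f"{g}_{'a' if rng.random() < 0.5 else 'b'}"
                day_groups.append((g, item, grams))
            if not day_groups:  # guarantee a non-empty day (staple fallback)
                day_groups.append(("refined_grains_baked_goods",
                                   "refined_grains_baked_goods_a", 150.0))

            energy = float(
                np.exp(e_person[i] + rng.normal(0.0, np.sqrt(params.energy_sigma2_within)))
            )
            share_logit = upf_person[i] + np.sqrt(1 - (c / params.upf_logit_sd) ** 2) \
                * params.upf_logit_sd * rng.normal()
            upf_share = 1.0 / (1.0 + np.exp(-share_logit))

            upf_items = [d for d in day_groups if GDQS_NOVA.get(d[0], 1) == 4]
            other_items = [d for d in day_groups if GDQS_NOVA.get(d[0], 1) != 4]
            energies = {}
            if upf_items and other_items:
                upf_g = sum(d[2] for d in upf_items)
                oth_g = sum(d[2] for d in other_items)
                for g_, item, grams in upf_items:
                    energies[item] = energy * upf_share * grams / upf_g
                for g_, item, grams in other_items:
                    energies[item] = energy * (1 - upf_share) * grams / oth_g
            else:
                tot_g = sum(d[2] for d in day_groups)
                for g_, item, grams in day_groups:
                    energies[item] = energy * grams / tot_g

            day_nutrients = {
                nut: float(
                    np.exp(
                        usual_log[nut][i]
                        - spec.sigma2_within / 2.0
                        + np.sqrt(spec.sigma2_within) * rng.normal()
                    )
                )
                for nut, spec in params.nutrient_params.items()
            }
            for g_, item, grams in day_groups:
                frac = energies[item] / energy
                records.append(
                    FoodRecord(
                        person_id=persons[i],
                        recall_day=day,
                        item_id=item,
                        grams=round(grams, 4),
                        energy_kcal=round(energies[item], 4),
                        nutrients={
                            nut: round(v * frac, 6) for nut, v in day_nutrients.items()
                        },
                    )
                )

    frame = records_to_frame(records)
    truth = SimulationTruth(
        params=params,
        quality=pd.Series(q, index=persons, name="quality"),
        quintile_code=pd.Series(qcode, index=persons, name="quintile_code"),
        inadequate=pd.Series(inadequate, index=persons, name="inadequate"),
        covariates=covars,
        logit_intercept=params.inadequacy_intercept,
        logit_slope=params.inadequacy_log_or_step,
        upf_logit_corr_target=t,
    )
    return frame, default_group_map(), truth


def make_toy_fixture() -> tuple[pd.DataFrame, GroupMap, dict]:
    """Tiny printed dataset (4 persons) with hand-computable expected scores.

    Expected values are derived by hand from the packaged default scoring
    table and returned alongside the records:

    * ``p_best``: every healthy group at its top category, unhealthy groups
      absent (zero-intake = maximum points), both excess groups at their
      moderate (peak) category -> GDQS 49 (32 + 17), low risk.
    * ``p_staple``: a single 300 g refined-grain staple -> GDQS 14
      (0 healthy + 6 x 2 remaining unhealthy + 1 + 1 excess-at-zero), high
      risk; MDD-W 1; UPF share 0 %.
    * ``p_upf``: 500 kcal class-4 soda out of 2000 kcal total -> 25 % UPF.
    * ``p_mddw6``: six MDD-W groups above 15 g -> MDD-W 6.
    """
    rows = [
        # p_best: healthy groups at their upper cut-off (top category)
        ("p_best", "dark_green_leafy_vegetables_a", 37, 15),
        ("p_best", "cruciferous_vegetables_a", 36, 10),
        ("p_best", "deep_orange_vegetables_a", 45, 15),
        ("p_best", "other_vegetables_a", 114, 30),
        ("p_best", "deep_orange_fruits_a", 122, 60),
        ("p_best", "citrus_fruits_a", 69, 30),
        ("p_best", "other_fruits_a", 107, 60),
        ("p_best", "legumes_a", 42, 55),
        ("p_best", "deep_orange_tubers_a", 63, 55),
        ("p_best", "nuts_seeds_a", 13, 75),
        ("p_best", "whole_grains_a", 13, 45),
        ("p_best", "liquid_oils_a", 7.5, 66),
        ("p_best", "fish_shellfish_a", 71, 90),
        ("p_best", "poultry_game_meat_a", 44, 70),
        ("p_best", "low_fat_dairy_a", 132, 60),
        ("p_best", "eggs_a", 32, 46),
        ("p_best", "red_meat_a", 20, 45),  # moderate category: peak points
        ("p_best", "high_fat_dairy_a", 50, 55),
        # p_staple
        ("p_staple", "refined_grains_baked_goods_a", 300, 390),
        # p_upf
        ("p_upf", "sugar_sweetened_beverages_a", 400, 500),
        ("p_upf", "refined_grains_baked_goods_a", 300, 1500),
        # p_mddw6
        ("p_mddw6", "eggs_a", 40, 60),
        ("p_mddw6", "legumes_a", 50, 65),
        ("p_mddw6", "low_fat_dairy_a", 200, 90),
        ("p_mddw6", "poultry_game_meat_a", 100, 150),
        ("p_mddw6", "dark_green_leafy_vegetables_a", 20, 8),
        ("p_mddw6", "other_fruits_a", 120, 70),
    ]
    records = [
        FoodRecord(person_id=p, recall_day=1, item_id=item, grams=float(g),
                   energy_kcal=float(e))
        for p, item, g, e in rows
    ]
    expected = {
        "p_best": {"gdqs": 49.0, "gdqs_plus": 32.0, "gdqs_minus": 17.0, "risk": "low"},
        "p_staple": {"gdqs": 14.0, "gdqs_plus": 0.0, "gdqs_minus": 14.0,
                     "risk": "high", "mddw": 1, "upf_share": 0.0},
        "p_upf": {"upf_share": 25.0},
        "p_mddw6": {"mddw": 6, "meets_mdd": True},
    }
    return records_to_frame(records), default_group_map(), expected
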