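"""End-to-end orchestration of the scoring → adequacy → validation stages.

The diet metrics are computed from the *first* recall day by convention
(repeat-day scoring is exposed through ``day``), while usual-intake
estimation uses every recall day available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adequacy import adequacy_table
from .config import AnalysisConfig, RequirementTable, ScoringTable
from .core import MDDW_GROUPS, GroupMap, daily_nutrient_totals, iter_person_days
from .gdqs import score_gdqs
from .inference import (
    assign_quintiles,
    compare_dependent_correlations,
    compare_metrics_wald,
    quintile_logistic,
    spearman_ci,
)
from .mddw import score_mddw
from .core import aggregate_group_grams
from .upf import upf_energy_share
from .usual_intake import estimate_usual_intakes


def score_population(
    records: pd.DataFrame,
    group_map: GroupMap,
    table: ScoringTable,
    config: AnalysisConfig | None = None,
    *,
    day: int = 1,
) -> pd.DataFrame:
    """Per-person GDQS(+/−), risk, MDD-W and UPF share for one recall day."""
    config = config or AnalysisConfig()
    rows = []
    for (person, recall_day), sub in iter_person_days(records):
        if recall_day != day:
            continue
        gdqs_grams = aggregate_group_grams(sub, group_map, table.group_names, which="gdqs")
        g = score_gdqs(gdqs_grams, table, config)
        mddw_grams = aggregate_group_grams(sub, group_map, MDDW_GROUPS, which="mddw")
        m = score_mddw(mddw_grams, config)
        u = upf_energy_share(sub, group_map)
        rows.append(
            {
                "person_id": person,
                "gdqs": g.gdqs,
                "gdqs_plus": g.gdqs_plus,
                "gdqs_minus": g.gdqs_minus,
                "risk": g.risk,
                "mddw_score": m.score,
                "meets_mdd": m.meets_mdd,
                "upf_pct_energy": u.upf_share,
            }
        )
    return pd.DataFrame(rows)


def run_adequacy(
    records: pd.DataFrame,
    requirements: RequirementTable,
    config: AnalysisConfig | None = None,
    *,
    log_transformed=("vitamin_a", "vitamin_b12", "folate", "iron", "zinc", "calcium"),
    weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Usual-intake estimation plus per-person adequacy.

    Returns (usual-intake tidy frame, adequacy frame, variance components).
    """
    config = config or AnalysisConfig()
    daily = daily_nutrient_totals(records)
    present = [n for n in config.nutrients if n in daily.columns]
    missing = set(config.nutrients) - set(present)
    if missing:
        raise KeyError(f"records carry no column for nutrient(s): {sorted(missing)}")
    usual, components = estimate_usual_intakes(
        daily, present, log_transformed=[n for n in log_transformed if n in present],
        weights=weights,
    )
    adequacy = adequacy_table(usual, requirements, config)
    return usual, adequacy, components


def validate_metrics(
    scores: pd.DataFrame,
    adequacy: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    weights=None,
    config: AnalysisConfig | None = None,
) -> dict:
    """The validation analyses: correlations, quintile ORs, cross-metric Wald.

    ``scores`` and ``adequacy`` are joined on person_id; covariates (if
    given) must carry a person_id column too.
    """
    config = config or AnalysisConfig()
    df = scores.merge(adequacy, on="person_id", how="inner")
    cov = None
    if covariates is not None:
        df = df.merge(covariates, on="person_id", how="inner")
        cov = df[[c for c in config.covariates if c in df.columns]]
    w = df["weight"].to_numpy() if (weights is True and "weight" in df.columns) else weights
    if w is not None and not isinstance(w, np.ndarray):
        w = np.asarray(w, dtype=float)

    out = {"n": len(df)}
    out["rho_gdqs_upf"] = spearman_ci(df["gdqs"], df["upf_pct_energy"])
    out["rho_mddw_upf"] = spearman_ci(df["mddw_score"], df["upf_pct_energy"])
    out["rho_gdqs_mpa"] = spearman_ci(df["gdqs"], df["mpa"])
    out["rho_mddw_mpa"] = spearman_ci(df["mddw_score"], df["mpa"])
    out["wolfe_gdqs_vs_mddw_mpa"] = compare_dependent_correlations(
        df["gdqs"], df["mddw_score"], df["mpa"]
    )

    q_gdqs = assign_quintiles(df["gdqs"].to_numpy(), w)
    q_mddw = assign_quintiles(df["mddw_score"].to_numpy(), w)
    y = df["inadequate"].astype(int).to_numpy()
    out["or_gdqs"] = quintile_logistic(y, q_gdqs, covariates=cov, weights=w)
    out["or_mddw"] = quintile_logistic(y, q_mddw, covariates=cov, weights=w)
    out["p_difference"] = compare_metrics_wald(y, q_gdqs, q_mddw, covariates=cov, weights=w)[1]
    return out
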