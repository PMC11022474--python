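"""Global Diet Quality Score (GDQS) scoring.

The GDQS scores daily gram intake of 25 food groups (0–49 overall).  Sixteen
"healthy" groups contribute the GDQS+ sub-metric (0–32): more intake never
lowers their points.  Seven "unhealthy" groups plus two "unhealthy in
excessive amounts" groups (red meat, high-fat dairy — moderate intake scores
highest) contribute the GDQS− sub-metric (0–17).  Scores map to diet-risk
categories: high risk below 15, moderate in [15, 23), low at or above 23.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import (
    HEALTHY,
    UNHEALTHY,
    UNHEALTHY_EXCESS,
    AnalysisConfig,
    GroupSpec,
    ScoringTable,
)
from .exceptions import ConfigError

RISK_HIGH = "high"
RISK_MODERATE = "moderate"
RISK_LOW = "low"


@dataclass(frozen=True)
class GdqsResult:
    gdqs: float
    gdqs_plus: float
    gdqs_minus: float
    per_group_points: dict
    risk: str


def categorize_and_point(grams: float, group_spec: GroupSpec) -> float:
    """Points awarded for a gram amount in one food group.

    The consumption category is found by cut-off bracketing (left-closed,
    right-open intervals); the category's configured points are returned.
    """
    return group_spec.points[group_spec.category(grams)]


def classify_risk(gdqs: float, config: AnalysisConfig | None = None) -> str:
    """Diet-risk category from a GDQS value (high < 15 <= moderate < 23 <= low)."""
    config = config or AnalysisConfig()
    if not (0.0 <= gdqs <= 49.0):
        raise ValueError(f"GDQS must lie in [0, 49], got {gdqs}")
    if gdqs < config.gdqs_high_cut:
        return RISK_HIGH
    if gdqs < config.gdqs_low_cut:
        return RISK_MODERATE
    return RISK_LOW


def score_gdqs(
    day_grams,
    table: ScoringTable,
    config: AnalysisConfig | None = None,
) -> GdqsResult:
    """Score one person-day from its per-group gram totals.

    ``day_grams`` maps every group of ``table`` to grams/day (0 allowed).
    GDQS+ sums the healthy groups' points, GDQS− the unhealthy and
    unhealthy-in-excess groups', and GDQS = GDQS+ + GDQS−.
    """
    config = config or AnalysisConfig()
    missing = [g.name for g in table.groups if g.name not in day_grams]
    if missing:
        raise ConfigError(f"day_grams missing group(s): {missing}")

    per_group = {g.name: categorize_and_point(float(day_grams[g.name]), g) for g in table.groups}
    plus = sum(per_group[g.name] for g in table.by_role(HEALTHY))
    minus = sum(
        per_group[g.name]
        for g in table.groups
        if g.role in (UNHEALTHY, UNHEALTHY_EXCESS)
    )
    total = plus + minus
    return GdqsResult(
        gdqs=total,
        gdqs_plus=plus,
        gdqs_minus=minus,
        per_group_points=per_group,
        risk=classify_risk(total, config),
    )


def category_tally(day_grams_by_person: pd.DataFrame, table: ScoringTable) -> pd.DataFrame:
    """Per-group tally of consumption categories across person-days.

    Utility for zero/low/moderate/high intake prevalence summaries: rows are
    groups, columns category indices, values counts of person-days.
    """
    rows = {}
    for g in table.groups:
        cats = day_grams_by_person[g.name].map(g.category)
        rows[g.name] = cats.value_counts().reindex(range(len(g.points)), fill_value=0)
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out.columns.name = "category"
    return out
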