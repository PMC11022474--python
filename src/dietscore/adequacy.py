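"""Probability of nutrient adequacy (full-probability method) and the MPA.

For a nutrient with an estimated average requirement (EAR), the probability
that a person's usual intake meets their own requirement is the requirement
distribution's CDF evaluated at the usual intake — normal with mean EAR and
sd = CV x EAR, or a tabulated curve for skewed requirements (e.g. iron in
menstruating women).  Nutrients without an EAR can instead use a capped
reference ratio min(1, usual / reference), flagged as non-probabilistic.

The mean probability of adequacy (MPA) averages the per-nutrient
probabilities over the configured nutrient set (eight by default); the
overall-inadequacy outcome is MPA strictly below the cutoff (default 0.5 —
an MPA of exactly 0.5 is classified adequate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, RequirementEntry, RequirementTable
from .exceptions import ConfigError


@dataclass(frozen=True)
class AdequacyResult:
    person_id: str
    pa: dict  # nutrient -> probability in [0, 1]
    mpa: float
    inadequate: bool


def probability_of_adequacy(usual: float, req: RequirementEntry) -> float:
    """Probability that a usual intake meets the nutrient's requirement."""
    if usual < 0:
        raise ValueError("usual intake must be non-negative")
    if req.mode == "reference_ratio":
        return min(1.0, usual / req.ratio_reference)
    if req.curve is not None:
        xs = np.array([a for a, _ in req.curve])
        ys = np.array([b for _, b in req.curve])
        # outside the tabulated range the curve saturates at its end values
        return float(np.interp(usual, xs, ys))
    return float(stats.norm.cdf(usual, loc=req.ear, scale=req.cv * req.ear))


def overall_inadequacy(pa_map: dict, config: AnalysisConfig | None = None) -> tuple[float, bool]:
    """MPA (unweighted mean over the configured nutrients) and the outcome.

    The outcome is *inadequacy*: MPA strictly below the cutoff.
    """
    config = config or AnalysisConfig()
    missing = [n for n in config.nutrients if n not in pa_map]
    if missing:
        raise ConfigError(f"probability of adequacy missing for nutrient(s): {missing}")
    mpa = float(np.mean([pa_map[n] for n in config.nutrients]))
    return mpa, mpa < config.mpa_cutoff


def adequacy_table(
    usual: pd.DataFrame,
    requirements: RequirementTable,
    config: AnalysisConfig | None = None,
    *,
    intake_column: str = "energy_adjusted",
) -> pd.DataFrame:
    """Per-person adequacy from a tidy usual-intake frame.

    ``usual`` has columns person_id, nutrient and the intake column (the
    energy-adjusted usual intake by default).  Returns one row per person
    with pa_<nutrient> columns, mpa and the binary inadequate outcome.
    """
    config = config or AnalysisConfig()
    for nut in config.nutrients:
        if nut not in requirements:
            raise ConfigError(f"no requirement configured for nutrient {nut!r}")
    wide = usual.pivot(index="person_id", columns="nutrient", values=intake_column)
    missing = set(config.nutrients) - set(wide.columns)
    if missing:
        raise ConfigError(f"usual intakes missing nutrient(s): {sorted(missing)}")
    out = pd.DataFrame(index=wide.index)
    for nut in config.nutrients:
        req = requirements[nut]
        intakes = wide[nut].clip(lower=0.0)
        out[f"pa_{nut}"] = [probability_of_adequacy(v, req) for v in intakes]
    out["mpa"] = out[[f"pa_{n}" for n in config.nutrients]].mean(axis=1)
    out["inadequate"] = out["mpa"] < config.mpa_cutoff
    out.attrs["non_probabilistic"] = [
        n for n in config.nutrients if requirements[n].mode == "reference_ratio"
    ]
    return out.reset_index()
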