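"""Usual-intake estimation from repeated 24-h recalls.

A single recall day mixes the person's habitual ("usual") intake with large
day-to-day noise.  With repeated recalls the two variance components are
separable: this module fits a one-way random-effects decomposition on a
monotone transformed scale (identity, or shifted-log for skewed nutrients)
by the method of moments, then predicts each person's usual intake as the
best linear predictor — the person's recall mean shrunk toward the
population mean by

    lambda_k = sigma2_between / (sigma2_between + sigma2_within / k)

for k recalls.  Usual intakes are then energy-adjusted by the residual
method: the nutrient is regressed on usual energy and each person keeps
their residual plus the value expected at the reference (mean) energy.

This estimator is a transparent stand-in for covariate-based measurement
error models (e.g. the NCI method): it provides the usual-intake level and
ranking the downstream adequacy and validation analyses need, and its
substitution is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DataError, DegenerateInputError

METHOD_NOTE = (
    "usual intakes estimated by one-way random-effects shrinkage (BLUP) on a "
    "transformed scale; energy adjustment by the residual method"
)


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effects decomposition of daily intakes on the transformed scale."""

    transform: str  # 'identity' or 'log' (shifted log)
    shift: float
    mu: float
    sigma2_between: float
    sigma2_within: float
    n_persons: int

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")

    def lambda_k(self, k: int) -> float:
        """Shrinkage weight for a person observed on k recall days."""
        denom = self.sigma2_between + self.sigma2_within / k
        if denom == 0.0:
            return 1.0  # no variation anywhere: the mean is exact
        return self.sigma2_between / denom


def _apply_transform(x, transform: str, shift: float):
    x = np.asarray(x, dtype=float)
    if transform == "log":
        return np.log(x + shift)
    return x


def _invert_transform(z, transform: str, shift: float):
    z = np.asarray(z, dtype=float)
    if transform == "log":
        return np.maximum(np.exp(z) - shift, 0.0)
    return z


def estimate_components(
    persons,
    amounts,
    *,
    transform: str = "identity",
    shift: float = 1.0,
) -> VarianceComponents:
    """Method-of-moments one-way random-effects fit to repeated daily amounts.

    ``persons``/``amounts`` are parallel arrays (one entry per person-day).
    Persons with a single recall contribute to the population mean only; the
    variance split needs at least one person with >= 2 recalls.  For
    unbalanced designs the standard ANOVA coefficient
    n0 = (N - sum n_i^2 / N) / (m - 1) replaces the common recall count, and
    a negative between-person moment estimate is truncated at zero.
    """
    df = pd.DataFrame({"person": np.asarray(persons), "y": _apply_transform(amounts, transform, shift)})
    if df["y"].isna().any() or not np.isfinite(df["y"]).all():
        raise DataError("non-finite transformed amounts (log of negative value?)")

    person_means = df.groupby("person")["y"].mean()
    counts = df.groupby("person")["y"].size()
    mu = float(person_means.mean())  # every person weighs equally in the mean

    multi = counts.index[counts >= 2]
    if len(multi) == 0:
        raise DegenerateInputError(
            "cannot separate within- from between-person variance: "
            "no person has two or more recalls"
        )
    sub = df[df["person"].isin(multi)]
    n_i = counts.loc[multi].to_numpy(dtype=float)
    m = len(multi)
    N = float(n_i.sum())
    means_i = person_means.loc[multi]

    centered = sub["y"] - sub["person"].map(means_i)
    ss_within = float((centered**2).sum())
    ms_within = ss_within / (N - m) if N > m else 0.0

    if m < 2:
        sigma2_between = 0.0
    else:
        grand = float((n_i * means_i.to_numpy()).sum() / N)
        ms_between = float((n_i * (means_i.to_numpy() - grand) ** 2).sum() / (m - 1))
        n0 = (N - float((n_i**2).sum()) / N) / (m - 1)
        sigma2_between = max(0.0, (ms_between - ms_within) / n0)

    return VarianceComponents(
        transform=transform,
        shift=shift,
        mu=mu,
        sigma2_between=sigma2_between,
        sigma2_within=ms_within,
        n_persons=int(len(counts)),
    )


def shrink_to_usual(person_mean, k, components: VarianceComponents):
    """Best-linear-predictor usual intake from a transformed-scale recall mean.

    usual = inverse-transform( mu + lambda_k * (person_mean - mu) ).
    Accepts scalars or aligned arrays of means and recall counts.
    """
    person_mean = np.asarray(person_mean, dtype=float)
    k = np.asarray(k)
    lam = np.vectorize(components.lambda_k)(k)
    z = components.mu + lam * (person_mean - components.mu)
    out = _invert_transform(z, components.transform, components.shift)
    return float(out) if out.ndim == 0 else out


def usual_intakes(
    daily: pd.DataFrame,
    column: str,
    *,
    transform: str = "identity",
    shift: float = 1.0,
) -> tuple[pd.Series, VarianceComponents]:
    """Per-person usual intake for one column of person-day totals.

    ``daily`` has one row per person-day with a ``person_id`` column.
    Returns (usual intake indexed by person, fitted components).
    """
    comp = estimate_components(
        daily["person_id"], daily[column], transform=transform, shift=shift
    )
    z = _apply_transform(daily[column], transform, shift)
    g = pd.DataFrame({"person_id": daily["person_id"], "z": z}).groupby("person_id")["z"]
    means, ks = g.mean(), g.size()
    usual = pd.Series(
        shrink_to_usual(means.to_numpy(), ks.to_numpy(), comp),
        index=means.index,
        name=f"usual_{column}",
    )
    return usual, comp


def energy_adjust(
    nutrient_usual: pd.Series,
    energy_usual: pd.Series,
    *,
    weights: pd.Series | None = None,
    reference_energy: float | None = None,
) -> pd.Series:
    """Residual-method energy adjustment of per-person usual intakes.

    Regresses nutrient on energy ((weighted) least squares) and returns
    residual + fitted value at the reference energy (default: the (weighted)
    mean energy).  Adjusted values are exactly uncorrelated with energy.
    """
    if not nutrient_usual.index.equals(energy_usual.index):
        nutrient_usual, energy_usual = nutrient_usual.align(energy_usual, join="inner")
        if len(nutrient_usual) == 0:
            raise DataError("nutrient and energy series share no persons")
    e = energy_usual.to_numpy(dtype=float)
    y = nutrient_usual.to_numpy(dtype=float)
    if np.ptp(e) == 0:
        raise DegenerateInputError("energy is constant: residual adjustment undefined")
    X = sm.add_constant(e)
    if weights is not None:
        w = weights.reindex(nutrient_usual.index).to_numpy(dtype=float)
        fit = sm.WLS(y, X, weights=w).fit()
        ref = float(np.average(e, weights=w)) if reference_energy is None else reference_energy
    else:
        fit = sm.OLS(y, X).fit()
        ref = float(e.mean()) if reference_energy is None else reference_energy
    adjusted = fit.resid + fit.params[0] + fit.params[1] * ref
    return pd.Series(adjusted, index=nutrient_usual.index, name=nutrient_usual.name)


def estimate_usual_intakes(
    daily: pd.DataFrame,
    nutrients,
    *,
    log_transformed=(),
    shift: float = 1.0,
    weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full usual-intake stage: shrink every nutrient and energy-adjust it.

    ``daily`` holds person-day totals (columns ``person_id``, ``energy_kcal``
    and one per nutrient).  Nutrients named in ``log_transformed`` are fitted
    on the shifted-log scale.  Returns a tidy frame (person_id, nutrient,
    raw_mean, usual, energy_adjusted) and the per-nutrient components.
    """
    energy_usual, energy_comp = usual_intakes(daily, "energy_kcal")
    components = {"energy_kcal": energy_comp}
    blocks = []
    for nut in nutrients:
        tf = "log" if nut in log_transformed else "identity"
        usual, comp = usual_intakes(daily, nut, transform=tf, shift=shift)
        components[nut] = comp
        adjusted = energy_adjust(usual, energy_usual, weights=weights)
        raw = daily.groupby("person_id")[nut].mean()
        blocks.append(
            pd.DataFrame(
                {
                    "person_id": usual.index,
                    "nutrient": nut,
                    "raw_mean": raw.loc[usual.index].to_numpy(),
                    "usual": usual.to_numpy(),
                    "energy_adjusted": adjusted.to_numpy(),
                }
            )
        )
    out = pd.concat(blocks, ignore_index=True)
    out.attrs["method"] = METHOD_NOTE
    return out, components
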