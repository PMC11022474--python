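#!/usr/bin/env python
"""Metric validation: correlations, quintile odds ratios, cross-metric tests.

Reads results/scores.csv, results/adequacy.csv and the simulated covariates;
writes results/validation.json and a quintile odds-ratio figure.
"""

import json
from pathlib import Path

import pandas as pd

import dietscore as ds

ROOT = Path(__file__).resolve().parents[1] / "results"

scores = pd.read_csv(ROOT / "scores.csv", dtype={"person_id": str})
adequacy = pd.read_csv(ROOT / "adequacy.csv", dtype={"person_id": str})
covariates = pd.read_csv(ROOT / "sim" / "covariates.csv", dtype={"person_id": str})

res = ds.validate_metrics(scores, adequacy, covariates=covariates)

print(f"n = {res['n']} persons")
for key, label in [("rho_gdqs_upf", "GDQS vs UPF share"),
                   ("rho_mddw_upf", "MDD-W vs UPF share"),
                   ("rho_gdqs_mpa", "GDQS vs MPA"),
                   ("rho_mddw_mpa", "MDD-W vs MPA")]:
    c = res[key]
    print(f"  Spearman {label:20s} rho = {c.rho:+.3f} "
          f"(95% CI {c.ci_low:+.3f}, {c.ci_high:+.3f})")

w = res["wolfe_gdqs_vs_mddw_mpa"]
print(f"  dependent-correlation comparison (GDQS vs MDD-W on MPA): "
      f"z = {w.statistic:+.2f}, p = {w.p:.4f}  [{w.method}]")

for metric in ("gdqs", "mddw"):
    m = res[f"or_{metric}"]
    ors = ", ".join(
        f"Q{j} {m.or_by_quintile[j][0]:.2f} ({m.or_by_quintile[j][1]:.2f}-"
        f"{m.or_by_quintile[j][2]:.2f})" for j in (2, 3, 4, 5)
    )
    print(f"  {metric.upper():5s} inadequacy OR (Q1 ref): {ors}; "
          f"p-trend = {m.p_trend:.2e}")
print(f"  cross-metric Wald p-difference (Q5 effects): {res['p_difference']:.4f}")

payload = {
    "n": res["n"],
    **{k: vars(res[k]) for k in
       ("rho_gdqs_upf", "rho_mddw_upf", "rho_gdqs_mpa", "rho_mddw_mpa")},
    "wolfe_gdqs_vs_mddw_mpa": {"statistic": w.statistic, "p": w.p, "method": w.method},
    "or_gdqs": {str(k): v for k, v in res["or_gdqs"].or_by_quintile.items()},
    "p_trend_gdqs": res["or_gdqs"].p_trend,
    "or_mddw": {str(k): v for k, v in res["or_mddw"].or_by_quintile.items()},
    "p_trend_mddw": res["or_mddw"].p_trend,
    "p_difference": res["p_difference"],
}
(ROOT / "validation.json").write_text(json.dumps(payload, indent=2))
print(f"wrote {ROOT / 'validation.json'}")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for metric, color, off in (("gdqs", "tab:red", -0.08), ("mddw", "tab:blue", 0.08)):
        m = res[f"or_{metric}"]
        qs = [1, 2, 3, 4, 5]
        ors = [m.or_by_quintile[j][0] for j in qs]
        los = [m.or_by_quintile[j][1] for j in qs]
        his = [m.or_by_quintile[j][2] for j in qs]
        x = [q + off for q in qs]
        ax.errorbar(x[1:], ors[1:],
                    yerr=[[o - l for o, l in zip(ors[1:], los[1:])],
                          [h - o for o, h in zip(ors[1:], his[1:])]],
                    fmt="o", color=color, capsize=3, label=metric.upper())
        ax.plot(x[:1], ors[:1], "s", color=color)
    ax.axhline(1.0, ls="--", c="grey", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("metric quintile")
    ax.set_ylabel("OR for overall nutrient inadequacy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(ROOT / "or_quintiles.png", dpi=150)
    print(f"wrote {ROOT / 'or_quintiles.png'}")
except ImportError:
    pass
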