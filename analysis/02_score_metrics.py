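#!/usr/bin/env python
"""Score the five diet metrics (GDQS, GDQS+, GDQS−, MDD-W, UPF share) per person.

Reads results/sim/, writes results/scores.csv and prints a dietary-
characteristics summary in the style of a survey descriptive table.
"""

from pathlib import Path

import dietscore as ds
from dietscore.io import read_group_map, read_recalls, write_table

ROOT = Path(__file__).resolve().parents[1] / "results"

records = read_recalls(ROOT / "sim" / "recalls.csv")
gmap = read_group_map(ROOT / "sim" / "group_map.csv")
table = ds.default_scoring_table()

report = ds.validate_scoring_table(table)
assert report.ok, report.failures
print(f"scoring table validated: max {report.max_total} "
      f"({report.max_healthy} healthy + {report.max_unhealthy} unhealthy)")

scores = ds.score_population(records, gmap, table)  # first-recall convention
write_table(scores, ROOT / "scores.csv")

print(f"\nDietary characteristics (n = {len(scores)} persons, first recall):")
print(f"  GDQS (0-49):        {scores['gdqs'].mean():5.2f} "
      f"(SD {scores['gdqs'].std():.2f})")
for risk, label in [("high", "high risk (< 15)"), ("moderate", "moderate risk (15-23)"),
                    ("low", "low risk (>= 23)")]:
    print(f"    {label:22s} {100 * (scores['risk'] == risk).mean():5.1f}%")
print(f"  MDD-W (0-10):       {scores['mddw_score'].mean():5.2f}")
print(f"    MDD-W >= 5         {100 * scores['meets_mdd'].mean():5.1f}%")
print(f"  UPF (% energy):     {scores['upf_pct_energy'].mean():5.1f}%")
print(f"\nwrote {ROOT / 'scores.csv'}")
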