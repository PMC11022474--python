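"""Core data model: food records, the item → group map, gram aggregation.

Recall records live in a long-format :class:`pandas.DataFrame` (one row per
consumed item within a person-day) with the fixed columns
``person_id, recall_day, item_id, grams, energy_kcal`` followed by one column
per nutrient (amounts are the item's contribution to that day, in the
nutrient's native units).  Units are grams/day and kcal/day at the I/O
boundary; no unit inference is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, UnmappedItemError

REQUIRED_COLUMNS = ("person_id", "recall_day", "item_id", "grams", "energy_kcal")

#: The ten food groups of the MDD-W indicator.
MDDW_GROUPS = (
    "grains_white_roots_tubers_plantains",
    "pulses",
    "nuts_seeds",
    "dairy",
    "meat_poultry_fish",
    "eggs",
    "dark_green_leafy_vegetables",
    "other_vitamin_a_rich",
    "other_vegetables",
    "other_fruits",
)


@dataclass(frozen=True)
class FoodRecord:
    """One consumed item within a person-day."""

    person_id: str
    recall_day: int
    item_id: str
    grams: float
    energy_kcal: float
    nutrients: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.grams < 0:
            raise DataError(f"grams must be non-negative, got {self.grams}")
        if self.energy_kcal < 0:
            raise DataError(f"energy must be non-negative, got {self.energy_kcal}")
        if self.recall_day not in (1, 2):
            raise DataError(f"recall_day must be 1 or 2, got {self.recall_day}")


def records_to_frame(records) -> pd.DataFrame:
    """Stack FoodRecords into the canonical long-format frame."""
    nutrients = sorted({n for r in records for n in r.nutrients})
    rows = [
        {
            "person_id": r.person_id,
            "recall_day": r.recall_day,
            "item_id": r.item_id,
            "grams": r.grams,
            "energy_kcal": r.energy_kcal,
            **{n: r.nutrients.get(n, 0.0) for n in nutrients},
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + nutrients)


def frame_to_records(df: pd.DataFrame) -> list[FoodRecord]:
    nutrients = nutrient_columns(df)
    return [
        FoodRecord(
            person_id=str(row.person_id),
            recall_day=int(row.recall_day),
            item_id=str(row.item_id),
            grams=float(row.grams),
            energy_kcal=float(row.energy_kcal),
            nutrients={n: float(getattr(row, n)) for n in nutrients},
        )
        for row in df.itertuples(index=False)
    ]


def nutrient_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in REQUIRED_COLUMNS]


@dataclass(frozen=True)
class GroupMap:
    """item_id → GDQS group, MDD-W group (or None) and NOVA class (1–4).

    NOVA class 4 marks ultra-processed foods; the class is an input
    annotation, never inferred from descriptions.
    """

    gdqs_group: dict
    mddw_group: dict
    nova_class: dict

    def __post_init__(self):
        bad = {i: c for i, c in self.nova_class.items() if c not in (1, 2, 3, 4)}
        if bad:
            raise DataError(f"NOVA class must be 1..4; offending items: {sorted(bad)[:10]}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroupMap":
        missing = {"item_id", "gdqs_group", "mddw_group", "nova_class"} - set(df.columns)
        if missing:
            raise DataError(f"group map missing column(s): {sorted(missing)}")
        items = df["item_id"].astype(str)
        if items.duplicated().any():
            dups = items[items.duplicated()].tolist()
            raise DataError(f"duplicate item_id(s) in group map: {dups[:10]}")
        mddw = {
            i: (None if pd.isna(g) or g in ("", "none") else str(g))
            for i, g in zip(items, df["mddw_group"])
        }
        return cls(
            gdqs_group=dict(zip(items, df["gdqs_group"].astype(str))),
            mddw_group=mddw,
            nova_class=dict(zip(items, df["nova_class"].astype(int))),
        )

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.gdqs_group)
        return pd.DataFrame(
            {
                "item_id": items,
                "gdqs_group": [self.gdqs_group[i] for i in items],
                "mddw_group": [self.mddw_group.get(i) or "none" for i in items],
                "nova_class": [self.nova_class[i] for i in items],
            }
        )


def _check_mapped(item_ids, mapping: dict):
    unmapped = [i for i in item_ids if i not in mapping]
    if unmapped:
        # a silent drop would bias every score downward, so this is fatal
        raise UnmappedItemError(unmapped)


def aggregate_group_grams(
    day_records: pd.DataFrame,
    group_map: GroupMap,
    group_names,
    *,
    which: str = "gdqs",
) -> pd.Series:
    """Total grams/day per food group for one person-day.

    Grams are summed per group *before* any categorisation; groups absent
    from the day appear with 0 g.  ``which`` selects the GDQS or MDD-W
    grouping; for MDD-W, items mapped to no group are ignored.
    """
    mapping = group_map.gdqs_group if which == "gdqs" else group_map.mddw_group
    totals = pd.Series(0.0, index=pd.Index(group_names, name="group"))
    if len(day_records) == 0:
        return totals
    items = day_records["item_id"].astype(str)
    if which == "gdqs":
        _check_mapped(items, mapping)
    groups = items.map(mapping)
    grams = day_records["grams"].astype(float)
    summed = grams.groupby(groups.values).sum()
    for g, v in summed.items():
        if g is None:
            continue
        if g not in totals.index:
            raise DataError(f"group {g!r} from map not in configured group list")
        totals[g] += v
    return totals


def person_day_energy(day_records: pd.DataFrame) -> float:
    return float(day_records["energy_kcal"].sum())


def iter_person_days(df: pd.DataFrame):
    """Yield ((person_id, recall_day), sub-frame) in sorted order."""
    for key, sub in df.groupby(["person_id", "recall_day"], sort=True):
        yield key, sub


def daily_nutrient_totals(df: pd.DataFrame) -> pd.DataFrame:
    """Person-day totals of energy and every nutrient column."""
    cols = ["energy_kcal"] + nutrient_columns(df)
    out = df.groupby(["person_id", "recall_day"], sort=True)[cols].sum()
    return out.reset_index()
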