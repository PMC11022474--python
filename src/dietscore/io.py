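"""Readers and writers for the package's delimited-text interfaces.

Recall records: UTF-8 CSV with header ``person_id, recall_day, item_id,
grams, energy_kcal`` then one column per nutrient.  Group map: CSV with
``item_id, gdqs_group, mddw_group, nova_class``.  Malformed rows are
rejected with messages naming the offending line number (header = line 1);
missing required columns are a fatal configuration error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import REQUIRED_COLUMNS, GroupMap, nutrient_columns
from .exceptions import ConfigError, DataError

log = logging.getLogger("dietscore")


def read_recalls(path: str | Path) -> pd.DataFrame:
    """Read and validate a recall-record CSV.

    Returns the long-format frame, retrievably grouped by person and day via
    :func:`dietscore.core.iter_person_days`.  All rows are validated before
    any is accepted: a :class:`DataError` carries one message per bad row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"person_id": str, "item_id": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required column(s): {sorted(missing)}")

    numeric_cols = ["recall_day", "grams", "energy_kcal"] + nutrient_columns(df)
    errors: list[str] = []
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        for i in bad:
            # +2: 1-based line numbers plus the header line
            errors.append(f"line {i + 2}: column {col!r} is missing or not numeric "
                          f"(got {df.loc[i, col]!r})")
        df[col] = parsed

    for col in ("grams", "energy_kcal"):
        neg = df.index[df[col] < 0]
        for i in neg:
            errors.append(f"line {i + 2}: {col} must be non-negative (got {df.loc[i, col]})")
    bad_day = df.index[~df["recall_day"].isin([1, 2])]
    for i in bad_day:
        errors.append(f"line {i + 2}: recall_day must be 1 or 2 (got {df.loc[i, 'recall_day']})")
    nut_cols = nutrient_columns(df)
    if nut_cols:
        neg = df.index[(df[nut_cols] < 0).any(axis=1)]
        for i in neg:
            errors.append(f"line {i + 2}: negative nutrient amount")

    if errors:
        raise DataError(
            f"{path}: {len(errors)} invalid row(s); first: {errors[0]}", row_errors=errors
        )
    df["recall_day"] = df["recall_day"].astype(int)
    log.info("read %d records, %d persons from %s", len(df), df["person_id"].nunique(), path)
    return df


def write_recalls(df: pd.DataFrame, path: str | Path) -> None:
    """Write records in the dialect :func:`read_recalls` reads (round-trips)."""
    cols = list(REQUIRED_COLUMNS) + nutrient_columns(df)
    df[cols].to_csv(path, index=False)


def read_group_map(path: str | Path) -> GroupMap:
    df = pd.read_csv(path, dtype={"item_id": str})
    return GroupMap.from_frame(df)


def write_group_map(group_map: GroupMap, path: str | Path) -> None:
    group_map.to_frame().to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an output table (scores, usual intakes, adequacy) as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
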