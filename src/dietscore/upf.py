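"""Ultra-processed food (UPF) energy share.

Foods annotated NOVA class 4 in the group map are ultra-processed; their
summed energy divided by total energy gives the percentage of caloric
contribution from UPF for the person-day.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import GroupMap, _check_mapped
from .exceptions import DataError


@dataclass(frozen=True)
class UpfResult:
    upf_energy: float
    total_energy: float
    upf_share: float  # percent, 0-100


def upf_energy_share(day_records: pd.DataFrame, group_map: GroupMap) -> UpfResult:
    """Percent of the person-day's energy from NOVA class-4 items.

    A day with zero total energy has no defined share and raises rather
    than silently reporting 0.
    """
    total = float(day_records["energy_kcal"].sum())
    if total <= 0:
        raise DataError("UPF share undefined: person-day total energy is 0")
    items = day_records["item_id"].astype(str)
    _check_mapped(items, group_map.nova_class)
    is_upf = items.map(group_map.nova_class) == 4
    upf = float(day_records.loc[is_upf.values, "energy_kcal"].sum())
    return UpfResult(upf_energy=upf, total_energy=total, upf_share=100.0 * upf / total)
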