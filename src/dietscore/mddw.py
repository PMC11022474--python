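"""Minimum Dietary Diversity for Women (MDD-W).

One point per MDD-W food group consumed in *more than* a gram threshold
(default 15 g/day, strict inequality), over ten predefined groups; minimum
diversity is met at 5 or more groups.  Although designed for women, the
score is computed for everyone — it serves as a micronutrient-adequacy
proxy in other groups too.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AnalysisConfig
from .core import MDDW_GROUPS
from .exceptions import ConfigError


@dataclass(frozen=True)
class MddwResult:
    score: int
    meets_mdd: bool
    counted_groups: frozenset


def score_mddw(day_grams, config: AnalysisConfig | None = None) -> MddwResult:
    """Score one person-day from its ten MDD-W group gram totals."""
    config = config or AnalysisConfig()
    day_grams = dict(day_grams)
    unknown = set(day_grams) - set(MDDW_GROUPS)
    if unknown:
        raise ConfigError(f"unknown MDD-W group(s): {sorted(unknown)}")
    missing = set(MDDW_GROUPS) - set(day_grams)
    if missing:
        raise ConfigError(f"day_grams missing MDD-W group(s): {sorted(missing)}")
    counted = frozenset(
        g for g in MDDW_GROUPS if float(day_grams[g]) > config.mddw_gram_threshold
    )
    score = len(counted)
    return MddwResult(
        score=score,
        meets_mdd=score >= config.mddw_min_groups,
        counted_groups=counted,
    )
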