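"""Scoring-table, requirement-table and analysis configuration.

The GDQS scoring table is deliberately *external* configuration: the score is
defined by 25 food groups, each with gram/day cut-offs delimiting consumption
categories and a point value per category.  Categories are left-closed,
right-open in grams: with cut-offs ``[a, b]`` the categories are
``[0, a)``, ``[a, b)``, ``[b, inf)``.  The package ships an illustrative
default table that satisfies every structural invariant of the score
(25 groups: 16 healthy, 7 unhealthy, 2 unhealthy-in-excess; maxima
32 + 17 = 49); users replace it with their preferred published cut-offs.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .exceptions import ConfigError

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
UNHEALTHY_EXCESS = "unhealthy_excess"
ROLES = (HEALTHY, UNHEALTHY, UNHEALTHY_EXCESS)

#: The eight nutrients entering the overall-adequacy outcome by default.
DEFAULT_ADEQUACY_NUTRIENTS = (
    "protein",
    "fiber",
    "calcium",
    "iron",
    "zinc",
    "vitamin_a",
    "folate",
    "vitamin_b12",
)


@dataclass(frozen=True)
class GroupSpec:
    """One GDQS food group: role, gram cut-offs and per-category points."""

    name: str
    role: str
    cutoffs: tuple[float, ...]
    points: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))
        object.__setattr__(self, "points", tuple(float(p) for p in self.points))
        if self.role not in ROLES:
            raise ConfigError(f"group {self.name!r}: unknown role {self.role!r}")
        if len(self.points) != len(self.cutoffs) + 1:
            raise ConfigError(
                f"group {self.name!r}: {len(self.cutoffs)} cutoffs require "
                f"{len(self.cutoffs) + 1} point values, got {len(self.points)}"
            )
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])) or (
            self.cutoffs and self.cutoffs[0] <= 0
        ):
            raise ConfigError(
                f"group {self.name!r}: cutoffs must be positive and strictly increasing"
            )
        if any(p < 0 for p in self.points):
            raise ConfigError(f"group {self.name!r}: points must be non-negative")

    def category(self, grams: float) -> int:
        """Consumption-category index for a gram amount ([a, b) convention)."""
        if grams < 0:
            raise ValueError("grams must be non-negative")
        return bisect_right(self.cutoffs, grams)

    @property
    def max_points(self) -> float:
        return max(self.points)

    @property
    def min_points(self) -> float:
        return min(self.points)


@dataclass(frozen=True)
class ScoringTable:
    """The full GDQS configuration: an ordered mapping of 25 group specs."""

    groups: tuple[GroupSpec, ...]

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate group names in scoring table")

    def __getitem__(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(g.name == name for g in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def by_role(self, role: str) -> tuple[GroupSpec, ...]:
        return tuple(g for g in self.groups if g.role == role)

    def max_score(self, roles=ROLES) -> float:
        """Brute-force maximum achievable total over the given roles."""
        return sum(g.max_points for g in self.groups if g.role in roles)

    def min_score(self, roles=ROLES) -> float:
        return sum(g.min_points for g in self.groups if g.role in roles)

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "name": g.name,
                    "role": g.role,
                    "cutoffs": list(g.cutoffs),
                    "points": list(g.points),
                }
                for g in self.groups
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringTable":
        try:
            groups = tuple(
                GroupSpec(g["name"], g["role"], g["cutoffs"], g["points"])
                for g in d["groups"]
            )
        except KeyError as e:  # missing field
            raise ConfigError(f"scoring table entry missing field {e}") from e
        return cls(groups)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of structural validation of a scoring table."""

    failures: tuple[str, ...]
    max_total: float
    min_total: float
    max_healthy: float
    max_unhealthy: float

    @property
    def ok(self) -> bool:
        return not self.failures


def _is_unimodal_rise_fall(points) -> bool:
    """True if points rise to an interior-or-final peak then fall.

    The zero-intake category must not already be the unique maximum (a
    genuinely "unhealthy in excess" group rewards moderate, not zero,
    intake) and the top category must score below the peak.
    """
    peak = max(points)
    p = points.index(peak)
    if p == 0 or points[-1] >= peak:
        return False
    rising = all(a <= b for a, b in zip(points[: p + 1], points[1 : p + 1]))
    falling = all(a >= b for a, b in zip(points[p:], points[p + 1 :]))
    return rising and falling


def validate_scoring_table(
    table: ScoringTable,
    *,
    expected_counts: dict | None = None,
    expected_maxima: tuple[float, float, float] | None = (49.0, 32.0, 17.0),
) -> ValidationReport:
    """Check every structural invariant of a GDQS scoring table.

    Point-shape invariants (monotone healthy/unhealthy, unimodal excess) are
    always checked.  ``expected_counts``/``expected_maxima`` default to the
    published GDQS structure (25 = 16 + 7 + 2 groups; maxima 49 = 32 + 17);
    pass ``None`` to validate a custom table against shape invariants only.
    The achievable maxima/minima are computed by exhaustive per-group
    enumeration, never assumed.
    """
    failures: list[str] = []
    counts = {r: len(table.by_role(r)) for r in ROLES}
    if expected_counts is None and expected_maxima is not None:
        expected_counts = {HEALTHY: 16, UNHEALTHY: 7, UNHEALTHY_EXCESS: 2}
    if expected_counts is not None:
        for role, want in expected_counts.items():
            if counts.get(role, 0) != want:
                failures.append(
                    f"expected {want} {role} groups, found {counts.get(role, 0)}"
                )

    for g in table.groups:
        pts = list(g.points)
        if g.role == HEALTHY:
            if any(a > b for a, b in zip(pts, pts[1:])):
                failures.append(f"healthy group {g.name!r}: points not non-decreasing")
        elif g.role == UNHEALTHY:
            if any(a < b for a, b in zip(pts, pts[1:])):
                failures.append(f"unhealthy group {g.name!r}: points not non-increasing")
            if pts[0] != max(pts):
                failures.append(
                    f"unhealthy group {g.name!r}: maximum points not at zero-intake category"
                )
        else:
            if not _is_unimodal_rise_fall(pts):
                failures.append(
                    f"excess group {g.name!r}: points not unimodal (rise then fall)"
                )

    max_healthy = table.max_score((HEALTHY,))
    max_unhealthy = table.max_score((UNHEALTHY, UNHEALTHY_EXCESS))
    max_total = table.max_score()
    min_total = table.min_score()
    if expected_maxima is not None:
        want_total, want_plus, want_minus = expected_maxima
        if max_healthy != want_plus:
            failures.append(f"healthy maximum {max_healthy} != {want_plus}")
        if max_unhealthy != want_minus:
            failures.append(f"unhealthy(+excess) maximum {max_unhealthy} != {want_minus}")
        if max_total != want_total:
            failures.append(f"grand maximum {max_total} != {want_total}")

    return ValidationReport(
        failures=tuple(failures),
        max_total=max_total,
        min_total=min_total,
        max_healthy=max_healthy,
        max_unhealthy=max_unhealthy,
    )


@dataclass(frozen=True)
class RequirementEntry:
    """Requirement distribution for one nutrient.

    mode='probability': probability of adequacy is the requirement CDF at the
    usual intake — normal with mean ``ear`` and sd ``cv * ear``, or the
    tabulated ``curve`` (list of [intake, probability] knots) for skewed
    requirements.  mode='reference_ratio': for nutrients without an EAR, the
    capped ratio usual/reference, flagged non-probabilistic downstream.
    """

    nutrient: str
    mode: str
    ear: float | None = None
    cv: float | None = None
    curve: tuple[tuple[float, float], ...] | None = None
    reference: float | None = None

    def __post_init__(self):
        if self.mode not in ("probability", "reference_ratio"):
            raise ConfigError(f"{self.nutrient}: unknown mode {self.mode!r}")
        if self.mode == "probability":
            if self.curve is not None:
                pts = tuple((float(a), float(b)) for a, b in self.curve)
                object.__setattr__(self, "curve", pts)
                xs = [a for a, _ in pts]
                ys = [b for _, b in pts]
                if any(b <= a for a, b in zip(xs, xs[1:])):
                    raise ConfigError(f"{self.nutrient}: curve intakes must increase")
                if any(b < a for a, b in zip(ys, ys[1:])) or not (
                    0.0 <= ys[0] and ys[-1] <= 1.0
                ):
                    raise ConfigError(
                        f"{self.nutrient}: curve must be non-decreasing within [0, 1]"
                    )
            else:
                if self.ear is None or self.ear <= 0:
                    raise ConfigError(f"{self.nutrient}: ear must be > 0")
                if self.cv is None or not (0 < self.cv < 1):
                    raise ConfigError(f"{self.nutrient}: cv must be in (0, 1)")
        else:
            ref = self.reference if self.reference is not None else self.ear
            if ref is None or ref <= 0:
                raise ConfigError(f"{self.nutrient}: reference amount must be > 0")

    @property
    def ratio_reference(self) -> float:
        return self.reference if self.reference is not None else self.ear


@dataclass(frozen=True)
class RequirementTable:
    entries: dict  # nutrient name -> RequirementEntry

    def __getitem__(self, nutrient: str) -> RequirementEntry:
        try:
            return self.entries[nutrient]
        except KeyError:
            raise ConfigError(f"no requirement configured for nutrient {nutrient!r}")

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self.entries

    @classmethod
    def from_dict(cls, d: dict) -> "RequirementTable":
        entries = {}
        for nut, spec in d.items():
            curve = spec.get("curve")
            entries[nut] = RequirementEntry(
                nutrient=nut,
                mode=spec.get("mode", "probability"),
                ear=spec.get("ear"),
                cv=spec.get("cv"),
                curve=tuple(map(tuple, curve)) if curve else None,
                reference=spec.get("reference"),
            )
        return cls(entries)

    def to_dict(self) -> dict:
        out = {}
        for nut, e in self.entries.items():
            spec = {"mode": e.mode}
            if e.ear is not None:
                spec["ear"] = e.ear
            if e.cv is not None:
                spec["cv"] = e.cv
            if e.curve is not None:
                spec["curve"] = [list(p) for p in e.curve]
            if e.reference is not None:
                spec["reference"] = e.reference
            out[nut] = spec
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide analysis settings."""

    nutrients: tuple[str, ...] = DEFAULT_ADEQUACY_NUTRIENTS
    mpa_cutoff: float = 0.5
    gdqs_high_cut: float = 15.0  # high risk below this
    gdqs_low_cut: float = 23.0  # low risk at or above this
    mddw_gram_threshold: float = 15.0  # strictly-greater-than rule
    mddw_min_groups: int = 5
    covariates: tuple[str, ...] = (
        "age_range",
        "locality",
        "income",
        "supplement",
        "diet_change",
    )
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mpa_cutoff <= 1.0):
            raise ConfigError("mpa_cutoff must lie in [0, 1]")
        if not (0.0 <= self.gdqs_high_cut <= self.gdqs_low_cut <= 49.0):
            raise ConfigError("GDQS risk cut-offs must satisfy 0 <= high <= low <= 49")
        if self.mddw_gram_threshold < 0:
            raise ConfigError("MDD-W gram threshold must be non-negative")
        if not (0 <= self.mddw_min_groups <= 10):
            raise ConfigError("MDD-W minimum group count must lie in 0..10")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for key in ("nutrients", "covariates"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _load_structured(path: str | Path) -> dict:
    """Load a JSON or YAML config file by extension."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}: not valid JSON ({e})") from e


def load_scoring_table(path: str | Path) -> ScoringTable:
    return ScoringTable.from_dict(_load_structured(path))


def load_requirement_table(path: str | Path) -> RequirementTable:
    return RequirementTable.from_dict(_load_structured(path))


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    return AnalysisConfig.from_dict(_load_structured(path))


def _package_json(name: str) -> dict:
    with resources.files("dietscore.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def default_scoring_table() -> ScoringTable:
    """The packaged illustrative GDQS scoring table (see data/README note)."""
    return ScoringTable.from_dict(_package_json("gdqs_scoring_default.json"))


def example_requirement_table() -> RequirementTable:
    """Packaged illustrative requirement table for the default eight nutrients."""
    return RequirementTable.from_dict(_package_json("requirements_example.json"))
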