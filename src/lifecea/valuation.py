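"""EQ-5D profile valuation: value sets and the 5L -> 3L crosswalk.

A value set maps an EQ-5D-3L profile to a societal utility on a scale
anchored at 1 for full health (profile 11111) and 0 for dead; many tariffs
reach below 0 for severe states.  Valuation follows the usual additive
decrement structure:

    U = 1 - c * 1{any dimension > 1} - sum d(dim, level) - n3 * 1{any level 3}

5L responses are first mapped to a 3L profile through a per-dimension
crosswalk and then valued with the 3L tariff.

Official national tariffs are licensed publications and are deliberately not
bundled: the shipped defaults are clearly labelled synthetic toy tariffs with
the same algebraic structure, and any tariff can be supplied as a CSV
coefficient table (columns: term, dimension, level, value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .cohort import EQ5D_DIMENSIONS

_3L_LEVELS = (1, 2, 3)
_5L_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ValueSet:
    """An additive EQ-5D-3L tariff.

    ``decrements`` maps ``(dimension, level)`` to the utility decrement for
    levels above 1; ``constant_decrement`` applies once if any dimension is
    above 1, and ``n3_decrement`` once if any dimension is at level 3.
    """

    name: str
    decrements: Mapping[tuple[str, int], float]
    constant_decrement: float = 0.0
    n3_decrement: float = 0.0

    def __post_init__(self) -> None:
        for (dim, level), d in self.decrements.items():
            if dim not in EQ5D_DIMENSIONS:
                raise ValueError(f"unknown dimension {dim!r}")
            if level not in (2, 3):
                raise ValueError(f"decrements are defined for levels 2-3, got {level}")
            if d < 0:
                raise ValueError("decrements must be non-negative")

    def value(self, profile: tuple[int, ...]) -> float:
        _check_profile(profile, "EQ5D3L")
        if all(v == 1 for v in profile):
            return 1.0
        u = 1.0 - self.constant_decrement
        for dim, level in zip(EQ5D_DIMENSIONS, profile):
            if level > 1:
                u -= self.decrements.get((dim, level), 0.0)
        if any(v == 3 for v in profile):
            u -= self.n3_decrement
        return u

    @property
    def floor(self) -> float:
        """Minimum achievable value (profile 33333)."""
        return self.value((3,) * 5)


@dataclass(frozen=True)
class CrosswalkMap:
    """Deterministic per-dimension 5L -> 3L level mapping.

    The default collapses the two middle and two lower 5L levels
    (1,2,3,4,5 -> 1,2,2,3,3), preserving 11111 -> 11111.
    """

    level_map: Mapping[int, int] = field(
        default_factory=lambda: {1: 1, 2: 2, 3: 2, 4: 3, 5: 3}
    )

    def __post_init__(self) -> None:
        missing = [lv for lv in _5L_LEVELS if lv not in self.level_map]
        if missing:
            raise ValueError(f"crosswalk does not map 5L levels {missing}")
        if self.level_map[1] != 1:
            raise ValueError("crosswalk must map level 1 to level 1 (anchor 11111 -> 1.0)")
        if any(self.level_map[lv] not in _3L_LEVELS for lv in _5L_LEVELS):
            raise ValueError("crosswalk targets must be 3L levels")

    def to_3l(self, profile: tuple[int, ...]) -> tuple[int, ...]:
        _check_profile(profile, "EQ5D5L")
        return tuple(self.level_map[v] for v in profile)


def _check_profile(profile: tuple[int, ...], instrument: str) -> None:
    if len(profile) != 5:
        raise ValueError("an EQ-5D profile has five dimension levels")
    top = 3 if instrument == "EQ5D3L" else 5
    for v in profile:
        if not (isinstance(v, (int,)) or float(v).is_integer()) or not 1 <= int(v) <= top:
            raise ValueError(f"level {v!r} out of range for {instrument}")


def value_profile(
    profile: tuple[int, ...],
    instrument: str,
    value_set: ValueSet,
    crosswalk: CrosswalkMap | None = None,
) -> float:
    """Value a single EQ-5D profile; 5L profiles pass through the crosswalk."""
    if instrument == "EQ5D3L":
        return value_set.value(tuple(int(v) for v in profile))
    if instrument == "EQ5D5L":
        if crosswalk is None:
            raise ValueError("valuing a 5L profile requires a crosswalk")
        return value_set.value(crosswalk.to_3l(tuple(int(v) for v in profile)))
    raise ValueError(f"unknown instrument {instrument!r}")


def default_value_set(country: str) -> ValueSet:
    """Synthetic toy tariffs for demonstration and testing.

    These are NOT the published national value sets; they merely share the
    additive structure (the UK-style toy tariff has a negative floor, the
    US-style one a positive floor).
    """
    if country == "US":
        dec = {
            ("mobility", 2): 0.05, ("mobility", 3): 0.15,
            ("self_care", 2): 0.04, ("self_care", 3): 0.12,
            ("usual_activities", 2): 0.03, ("usual_activities", 3): 0.10,
            ("pain_discomfort", 2): 0.06, ("pain_discomfort", 3): 0.17,
            ("anxiety_depression", 2): 0.05, ("anxiety_depression", 3): 0.15,
        }
        return ValueSet("toy-US", dec, constant_decrement=0.0, n3_decrement=0.05)
    if country == "UK":
        dec = {
            ("mobility", 2): 0.07, ("mobility", 3): 0.26,
            ("self_care", 2): 0.09, ("self_care", 3): 0.26,
            ("usual_activities", 2): 0.04, ("usual_activities", 3): 0.09,
            ("pain_discomfort", 2): 0.12, ("pain_discomfort", 3): 0.39,
            ("anxiety_depression", 2): 0.07, ("anxiety_depression", 3): 0.24,
        }
        return ValueSet("toy-UK", dec, constant_decrement=0.08, n3_decrement=0.27)
    raise ValueError(f"no default value set for country {country!r}")


def value_set_to_frame(vs: ValueSet) -> pd.DataFrame:
    rows = [("constant", "", 0, vs.constant_decrement), ("n3", "", 0, vs.n3_decrement)]
    rows += [("decrement", dim, lv, d) for (dim, lv), d in sorted(vs.decrements.items())]
    return pd.DataFrame(rows, columns=["term", "dimension", "level", "value"])


def value_set_from_frame(frame: pd.DataFrame, name: str = "custom") -> ValueSet:
    """Read a tariff from its CSV coefficient-table form."""
    required = {"term", "dimension", "level", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"value-set table needs columns {sorted(required)}")
    const = n3 = 0.0
    dec: dict[tuple[str, int], float] = {}
    for _, row in frame.iterrows():
        if row["term"] == "constant":
            const = float(row["value"])
        elif row["term"] == "n3":
            n3 = float(row["value"])
        elif row["term"] == "decrement":
            dec[(str(row["dimension"]), int(row["level"]))] = float(row["value"])
        else:
            raise ValueError(f"unknown value-set term {row['term']!r}")
    return ValueSet(name, dec, constant_decrement=const, n3_decrement=n3)


def value_utility_table(
    utilities: pd.DataFrame,
    value_set: ValueSet,
    crosswalk: CrosswalkMap | None = None,
) -> pd.DataFrame:
    """Value every visit row of the EQ-5D table.

    Returns columns (patient_id, visit_time, utility); rows whose profile is
    missing get NaN utility and keep their place in the visit schedule.
    """
    import numpy as np

    crosswalk = crosswalk or CrosswalkMap()
    dims = list(EQ5D_DIMENSIONS)
    out = utilities[["patient_id", "visit_time"]].copy()

    levels = utilities[dims].to_numpy(dtype=float)
    missing = np.isnan(levels).any(axis=1)
    is_5l = (utilities["instrument"] == "EQ5D5L").to_numpy()
    lv = np.nan_to_num(levels, nan=1.0).astype(int)
    if ((lv < 1) | (lv > np.where(is_5l, 5, 3)[:, None])).any():
        raise ValueError("EQ-5D level out of range for instrument")
    xmap = np.array([0] + [crosswalk.level_map[i] for i in _5L_LEVELS])
    lv = np.where(is_5l[:, None], xmap[lv], lv)

    u = np.ones(len(lv))
    any_above = (lv > 1).any(axis=1)
    u -= value_set.constant_decrement * any_above
    u -= value_set.n3_decrement * (lv == 3).any(axis=1)
    for j, dim in enumerate(EQ5D_DIMENSIONS):
        for level in (2, 3):
            u -= value_set.decrements.get((dim, level), 0.0) * (lv[:, j] == level)
    u[missing] = np.nan
    out["utility"] = u
    return out
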