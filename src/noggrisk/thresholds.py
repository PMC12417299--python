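"""Age-dependent NOGG assessment, intervention and very-high-risk thresholds.

The UK guideline defines four probability thresholds for each fracture
outcome (major osteoporotic fracture, MOF; hip fracture), all expressed as
10-year FRAX probabilities on the 0-100 percent scale:

* **LAT** (lower assessment threshold) — below it risk is low and lifestyle
  advice suffices.
* **UAT** (upper assessment threshold) — the LAT-UAT band is "intermediate"
  risk in which BMD measurement is indicated.
* **IT** (intervention threshold) — above it drug treatment is offered.  Up
  to age 70 it is set at the risk of a same-age woman with a prior fracture
  and therefore rises with age; from 70 on it is fixed.
* **VHRT** (very-high-risk threshold) — the IT uplifted by 60%; above it
  specialist referral is considered.

The guideline publishes the threshold values at 5-year age anchors from 50
to 70.  This module stores those anchors (shipped as a plain CSV so that
alternative national sets can be swapped in), interpolates between them
piecewise-linearly, clamps ages 45-50 to the age-50 values and ages >= 70 to
the age-70 values, and validates the transcription against the 60% rule.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "Thresholds",
    "ThresholdSet",
    "OutOfScopePopulationError",
    "AGE_FLOOR",
    "AGE_PLATEAU",
    "VHRT_UPLIFT",
    "anchor_table",
    "load_threshold_sets",
    "thresholds_at",
    "derive_vhrt",
    "validate_anchors",
]

#: Youngest supported age, in years.  The guideline covers postmenopausal
#: women and men aged >= 50; ages in [45, 50) are clamped to the age-50
#: thresholds, below 45 the population is out of scope.
AGE_FLOOR = 45.0

#: Age at and above which the fixed (age-70) thresholds apply.
AGE_PLATEAU = 70.0

#: Very-high-risk threshold = intervention threshold uplifted by 60%.
VHRT_UPLIFT = 1.6


class Outcome(str, enum.Enum):
    """Fracture outcome a FRAX probability refers to."""

    MOF = "mof"
    HIP = "hip"


class OutOfScopePopulationError(ValueError):
    """Raised when a threshold query falls outside the guideline population."""


class Thresholds(NamedTuple):
    """The four thresholds at one age, percent scale."""

    lat: float
    it: float
    uat: float
    vhrt: float


@dataclass(frozen=True)
class ThresholdSet:
    """Anchored thresholds for one outcome with interpolation between anchors.

    ``anchors`` is an ordered list of ``(age, lat, it, uat, vhrt)`` tuples.
    Anchor values are stored exactly as published (hip age-50 values carry
    two decimals, all others one); interpolated values are never re-rounded.
    """

    outcome: Outcome
    anchors: tuple[tuple[float, float, float, float, float], ...]
    _ages: np.ndarray = field(init=False, repr=False, compare=False)
    _cols: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.anchors, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5 or arr.shape[0] < 2:
            raise ValueError("anchors must be >= 2 rows of (age, lat, it, uat, vhrt)")
        ages = arr[:, 0]
        if not np.all(np.diff(ages) > 0):
            raise ValueError("anchor ages must be strictly increasing")
        object.__setattr__(self, "_ages", ages)
        object.__setattr__(self, "_cols", arr[:, 1:])

    @property
    def anchor_ages(self) -> tuple[float, ...]:
        return tuple(self._ages)

    def at(self, age: float) -> Thresholds:
        """Thresholds at ``age``, clamped to [anchor_min, anchor_max].

        Exact at anchor ages, piecewise-linear in between, constant outside
        the anchored range (ages in [AGE_FLOOR, 50) use the age-50 values,
        ages >= 70 the age-70 values).
        """
        if not (isinstance(age, (int, float)) and math.isfinite(age)):
            raise ValueError(f"age must be a finite number, got {age!r}")
        if age < AGE_FLOOR:
            raise OutOfScopePopulationError(
                f"age {age} is below the supported floor of {AGE_FLOOR}; the "
                "guideline covers postmenopausal women and men aged >= 50"
            )
        a = float(np.clip(age, self._ages[0], self._ages[-1]))
        # exact anchor lookup keeps published values bit-identical
        idx = np.searchsorted(self._ages, a)
        if idx < len(self._ages) and self._ages[idx] == a:
            return Thresholds(*(float(v) for v in self._cols[idx]))
        vals = [float(np.interp(a, self._ages, self._cols[:, j])) for j in range(4)]
        return Thresholds(*vals)


def derive_vhrt(it: float) -> float:
    """Very-high-risk threshold from an intervention threshold: IT x 1.6.

    Capped at 100 (probabilities live on the percent scale).
    """
    if it < 0:
        raise ValueError(f"intervention threshold must be >= 0, got {it}")
    return min(it * VHRT_UPLIFT, 100.0)


def _data_path() -> Path:
    return Path(str(resources.files("noggrisk").joinpath("data/uk_thresholds_2024.csv")))


def load_threshold_sets(path: str | Path | None = None) -> dict[Outcome, ThresholdSet]:
    """Load per-outcome threshold sets from a CSV of anchors.

    The CSV columns are ``outcome, age, lat, it, uat, vhrt``; the packaged
    default carries the published UK values.  Supplying ``path`` swaps in an
    alternative national threshold set.
    """
    df = pd.read_csv(path if path is not None else _data_path())
    required = {"outcome", "age", "lat", "it", "uat", "vhrt"}
    if not required.issubset(df.columns):
        raise ValueError(f"threshold file must have columns {sorted(required)}")
    sets: dict[Outcome, ThresholdSet] = {}
    for outcome, grp in df.groupby("outcome", sort=False):
        grp = grp.sort_values("age")
        anchors = tuple(
            (float(r.age), float(r.lat), float(r.it), float(r.uat), float(r.vhrt))
            for r in grp.itertuples()
        )
        sets[Outcome(outcome)] = ThresholdSet(Outcome(outcome), anchors)
    return sets


_DEFAULT_SETS: dict[Outcome, ThresholdSet] | None = None


def anchor_table() -> dict[Outcome, ThresholdSet]:
    """The published UK threshold sets (cached)."""
    global _DEFAULT_SETS
    if _DEFAULT_SETS is None:
        _DEFAULT_SETS = load_threshold_sets()
    return _DEFAULT_SETS


def thresholds_at(
    age: float,
    outcome: Outcome | str,
    sets: dict[Outcome, ThresholdSet] | None = None,
) -> Thresholds:
    """The (lat, it, uat, vhrt) tuple for one outcome at a given age."""
    sets = sets if sets is not None else anchor_table()
    return sets[Outcome(outcome)].at(age)


@dataclass
class AnchorCheck:
    """Validation result for one anchor row."""

    age: float
    it: float
    vhrt: float
    derived_vhrt: float
    discrepancy: float  # |rounded(IT x 1.6) - printed VHRT|, printed precision
    ordering_ok: bool


@dataclass
class ValidationReport:
    outcome: Outcome
    checks: list[AnchorCheck]
    monotone: bool

    @property
    def ordering_ok(self) -> bool:
        return all(c.ordering_ok for c in self.checks)

    @property
    def max_discrepancy(self) -> float:
        return max(c.discrepancy for c in self.checks)


def _printed_decimals(value: float) -> int:
    """Decimals the guideline prints for a threshold of this magnitude."""
    return 2 if value < 1 else 1


def validate_anchors(ts: ThresholdSet) -> ValidationReport:
    """Self-check of a threshold set against the 60% VHRT rule and ordering.

    For each anchor, reports the absolute discrepancy between the stored
    VHRT and ``derive_vhrt(IT)`` rounded to the printed precision, and flags
    any ordering (lat < it < uat < vhrt) or age-monotonicity violation.
    """
    checks = []
    for age, lat, it, uat, vhrt in ts.anchors:
        nd = _printed_decimals(vhrt)
        derived = derive_vhrt(it)
        disc = abs(round(derived, nd) - vhrt)
        ordering = 0 < lat < it < uat < vhrt <= 100
        checks.append(AnchorCheck(age, it, vhrt, derived, disc, ordering))
    cols = np.asarray(ts.anchors, dtype=float)[:, 1:]
    monotone = bool(np.all(np.diff(cols, axis=0) >= 0))
    return ValidationReport(ts.outcome, checks, monotone)
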