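"""Reference breast-cancer incidence-rate tables.

Familial relative risks are estimated by indirect standardization: observed
breast cancers in relatives are compared with the number expected from
general-population incidence rates that vary by attained age and calendar
period. This module reads, validates and queries such a rate table, and
derives the case-age weight distribution used to average age-specific
familial relative risks.

Conventions
-----------
* All rates are stored per woman-year (events per person-year), never per
  100,000.
* Cells are half-open rectangles ``[age_lo, age_hi) x [period_lo,
  period_hi)`` on real-valued (fractional-year) age and calendar axes, so a
  point on a shared boundary belongs to exactly one cell.
* A valid table tiles a rectangular age x period grid with no gaps or
  overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RATE_COLUMNS = ("age_lo", "age_hi", "period_lo", "period_hi", "rate")


class RateTableError(ValueError):
    """Invalid rate-table structure or contents."""


class OutOfCoverageError(RateTableError):
    """An (age, date) point or interval falls outside the rate grid."""


@dataclass(frozen=True)
class RateCell:
    """One half-open age x period rectangle with a constant incidence rate.

    ``rate`` is events per woman-year.
    """

    age_lo: float
    age_hi: float
    period_lo: float
    period_hi: float
    rate: float

    def __post_init__(self) -> None:
        if not self.age_lo < self.age_hi:
            raise RateTableError(f"cell {self}: age_lo must be < age_hi")
        if not self.period_lo < self.period_hi:
            raise RateTableError(f"cell {self}: period_lo must be < period_hi")
        if self.rate < 0:
            raise RateTableError(f"cell {self}: negative rate {self.rate}")

    def contains(self, age: float, date: float) -> bool:
        return (self.age_lo <= age < self.age_hi
                and self.period_lo <= date < self.period_hi)


def _axis_breaks(intervals: set[tuple[float, float]], axis: str) -> np.ndarray:
    """Check that a set of half-open intervals chains contiguously and
    return the break points."""
    ordered = sorted(intervals)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 > lo2:
            raise RateTableError(
                f"overlapping {axis} bands [{lo1},{hi1}) and [{lo2},{hi2})")
        if hi1 < lo2:
            raise RateTableError(
                f"gap in {axis} bands between [{lo1},{hi1}) and [{lo2},{hi2})")
    return np.array([lo for lo, _ in ordered] + [ordered[-1][1]])


class RateTable:
    """A rectangular age x calendar-period grid of incidence rates."""

    def __init__(self, cells: Iterable[RateCell]):
        cells = list(cells)
        if not cells:
            raise RateTableError("rate table has no cells")
        age_iv = {(c.age_lo, c.age_hi) for c in cells}
        per_iv = {(c.period_lo, c.period_hi) for c in cells}
        self._age_breaks = _axis_breaks(age_iv, "age")
        self._period_breaks = _axis_breaks(per_iv, "period")
        na, np_ = len(age_iv), len(per_iv)
        rates = np.full((na, np_), np.nan)
        a_index = {iv: i for i, iv in enumerate(sorted(age_iv))}
        p_index = {iv: j for j, iv in enumerate(sorted(per_iv))}
        for c in cells:
            i = a_index[(c.age_lo, c.age_hi)]
            j = p_index[(c.period_lo, c.period_hi)]
            if not np.isnan(rates[i, j]):
                raise RateTableError(
                    f"duplicate cell for ages [{c.age_lo},{c.age_hi}) "
                    f"period [{c.period_lo},{c.period_hi})")
            rates[i, j] = c.rate
        if np.isnan(rates).any():
            i, j = map(int, np.argwhere(np.isnan(rates))[0])
            raise RateTableError(
                f"grid gap: no cell for ages "
                f"[{self._age_breaks[i]},{self._age_breaks[i + 1]}) "
                f"period [{self._period_breaks[j]},{self._period_breaks[j + 1]})")
        self._rates = rates

    @classmethod
    def from_grid(cls, age_breaks: Sequence[float],
                  period_breaks: Sequence[float],
                  rates: np.ndarray) -> "RateTable":
        """Build a table from break points and an (n_age, n_period) array."""
        rates = np.asarray(rates, dtype=float)
        cells = [
            RateCell(age_breaks[i], age_breaks[i + 1],
                     period_breaks[j], period_breaks[j + 1],
                     float(rates[i, j]))
            for i in range(len(age_breaks) - 1)
            for j in range(len(period_breaks) - 1)
        ]
        return cls(cells)

    # -- structure ---------------------------------------------------------

    @property
    def age_grid(self) -> np.ndarray:
        return self._age_breaks.copy()

    @property
    def period_grid(self) -> np.ndarray:
        return self._period_breaks.copy()

    @property
    def rates(self) -> np.ndarray:
        """Rates as an (n_age_bands, n_period_bands) array."""
        return self._rates.copy()

    @property
    def cells(self) -> list[RateCell]:
        a, p = self._age_breaks, self._period_breaks
        return [
            RateCell(a[i], a[i + 1], p[j], p[j + 1], float(self._rates[i, j]))
            for i in range(len(a) - 1) for j in range(len(p) - 1)
        ]

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self._age_breaks[0]), float(self._age_breaks[-1])

    @property
    def period_range(self) -> tuple[float, float]:
        return float(self._period_breaks[0]), float(self._period_breaks[-1])

    # -- queries -----------------------------------------------------------

    def locate(self, age, date):
        """Vectorized (age band, period band) indices for point lookups.

        Raises :class:`OutOfCoverageError` if any point lies outside the
        covered rectangle (half-open: the upper edges are excluded).
        """
        age = np.asarray(age, dtype=float)
        date = np.asarray(date, dtype=float)
        i = np.searchsorted(self._age_breaks, age, side="right") - 1
        j = np.searchsorted(self._period_breaks, date, side="right") - 1
        bad_age = (i < 0) | (i >= len(self._age_breaks) - 1)
        bad_per = (j < 0) | (j >= len(self._period_breaks) - 1)
        if np.any(bad_age) or np.any(bad_per):
            a = float(np.atleast_1d(age)[np.argmax(np.atleast_1d(bad_age | bad_per))])
            d = float(np.atleast_1d(date)[np.argmax(np.atleast_1d(bad_age | bad_per))])
            raise OutOfCoverageError(
                f"(age={a}, date={d}) outside rate grid "
                f"ages {self.age_range}, periods {self.period_range}")
        return i, j

    def lookup(self, age: float, date: float) -> float:
        """Rate per woman-year of the unique cell containing (age, date)."""
        i, j = self.locate(age, date)
        return float(self._rates[i, j])


def lookup_rate(table: RateTable, age: float, date: float) -> float:
    """Functional alias for :meth:`RateTable.lookup`."""
    return table.lookup(age, date)


# -- I/O -------------------------------------------------------------------


def read_rate_table(path, rate_scale: float = 1.0) -> RateTable:
    """Read a rate CSV (columns ``age_lo,age_hi,period_lo,period_hi,rate``).

    ``rate`` in the file is per ``rate_scale`` woman-years (pass 100000 for
    registry-style rates); stored rates are per woman-year.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise RateTableError(f"rate CSV {path} missing columns {missing}")
    if rate_scale <= 0:
        raise RateTableError(f"rate_scale must be positive, got {rate_scale}")
    cells = [
        RateCell(row.age_lo, row.age_hi, row.period_lo, row.period_hi,
                 row.rate / rate_scale)
        for row in df.itertuples()
    ]
    return RateTable(cells)


def write_rate_table(table: RateTable, path, rate_scale: float = 1.0) -> None:
    """Write the canonical CSV dialect; inverse of :func:`read_rate_table`."""
    rows = [
        (c.age_lo, c.age_hi, c.period_lo, c.period_hi, c.rate * rate_scale)
        for c in table.cells
    ]
    pd.DataFrame(rows, columns=RATE_COLUMNS).to_csv(path, index=False)


# -- age weights -----------------------------------------------------------


@dataclass(frozen=True)
class AgeWeights:
    """Normalized weights over strictly increasing ages.

    Used to average age-specific familial relative risks over the age
    distribution of breast-cancer cases.
    """

    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "weights",
                           np.asarray(self.weights, dtype=float))
        if self.ages.shape != self.weights.shape or self.ages.ndim != 1:
            raise ValueError("ages and weights must be equal-length 1-d")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1; use normalize_weights")


def normalize_weights(raw) -> AgeWeights:
    """Rescale non-negative (age, weight) pairs to sum to one.

    ``raw`` is an iterable of pairs, or an :class:`AgeWeights`.
    """
    if isinstance(raw, AgeWeights):
        pairs = list(zip(raw.ages, raw.weights))
    else:
        pairs = [(float(a), float(w)) for a, w in raw]
    if not pairs:
        raise ValueError("no (age, weight) pairs supplied")
    ages = np.array([a for a, _ in pairs])
    w = np.array([x for _, x in pairs])
    if np.any(w < 0):
        raise ValueError("negative weight supplied")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero; at least one must be positive")
    return AgeWeights(ages, w / total)


def incidence_age_weights(table: RateTable, age_lo: float = 20,
                          age_hi: float = 70, date: float | None = None,
                          step: float = 1.0) -> AgeWeights:
    """Case-age weights proportional to incidence at each age.

    Evaluates the rate at ages ``age_lo, age_lo+step, ... , age_hi``
    (inclusive, clipped to grid coverage) at calendar time ``date``
    (default: midpoint of the table's period coverage).
    """
    if date is None:
        p0, p1 = table.period_range
        date = 0.5 * (p0 + p1)
    a0, a1 = table.age_range
    ages = np.arange(age_lo, age_hi + 0.5 * step, step)
    ages = ages[(ages >= a0) & (ages < a1)]
    rates = np.array([table.lookup(a, date) for a in ages])
    return normalize_weights(zip(ages, rates))
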