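"""Familial relative risk estimation by indirect standardization.

The familial relative risk (FRR) of a stratum of relatives is the ratio
O/E of observed breast cancers to the number expected under
general-population incidence. Expected counts come from a Lexis expansion:
each relative's follow-up is split at every age-band and calendar-period
crossing so that a piecewise-constant reference rate applies on each
segment, and E = sum of person-years x rate.

Because relatives of one proband share genes and environment, the variance
of the estimate treats families as independent clusters. For a one-parameter
Poisson model of the standardized incidence ratio, the cluster-score
(sandwich) variance of log(O/E) is

    Var(log FRR) = sum_f (o_f - FRR * e_f)^2 / O^2

over families f; confidence intervals are computed on the log scale and
exponentiated. Strata with no observed events report FRR 0 with the exact
one-sided Poisson upper bound 3.69 / E.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import (Exclusion, Family, FollowUpInterval, MarkerStatus,
                           SubtypeLabel, derive_follow_up, impute_birth_date,
                           restrict_age_window)
from .reference_rates import OutOfCoverageError, RateCell, RateTable

logger = logging.getLogger("famsubtype")

#: exact one-sided 95% Poisson upper bound on the mean given zero events
ZERO_EVENT_UPPER = 3.69


class EstimationError(ValueError):
    """FRR estimate is undefined for the given inputs."""


# -- Lexis expansion -------------------------------------------------------


@dataclass(frozen=True)
class LexisSegment:
    """Person-time of one relative falling inside one rate cell."""

    family_id: str
    person_id: str
    cell: RateCell
    person_years: float


def _clip_to_coverage(interval: FollowUpInterval, table: RateTable,
                      coverage: str) -> Optional[tuple[float, float, bool]]:
    """Effective (entry_age, exit_age, event kept) under the coverage policy.

    ``coverage='error'`` raises if any follow-up lies outside the grid;
    ``'truncate'`` clips to the grid edges (dropping an event whose exit is
    truncated away). Returns ``None`` if nothing remains.
    """
    birth = interval.birth_date
    a0, a1 = table.age_range
    p0, p1 = table.period_range
    lo = max(interval.entry_age, a0, p0 - birth)
    hi = min(interval.exit_age, a1, p1 - birth)
    if coverage == "error":
        if (lo > interval.entry_age + 1e-12) or (hi < interval.exit_age - 1e-12):
            raise OutOfCoverageError(
                f"{interval.person_id}: follow-up ages "
                f"[{interval.entry_age:.2f},{interval.exit_age:.2f}] dates "
                f"[{interval.entry_date:.2f},{interval.exit_date:.2f}] extend "
                f"outside rate grid (ages {table.age_range}, "
                f"periods {table.period_range})")
    elif coverage != "truncate":
        raise ValueError(f"unknown coverage policy {coverage!r}")
    if hi <= lo:
        return None
    event = interval.event and hi >= interval.exit_age - 1e-12
    return lo, hi, event


def expand_lexis(interval: FollowUpInterval, table: RateTable,
                 coverage: str = "error") -> list[LexisSegment]:
    """Split follow-up at every age-band and period crossing.

    Each returned segment lies wholly within one rate cell; segment
    person-years sum exactly to the (possibly truncated) interval length.
    """
    clipped = _clip_to_coverage(interval, table, coverage)
    if clipped is None:
        return []
    lo, hi, _ = clipped
    birth = interval.birth_date
    cuts = {lo, hi}
    cuts.update(a for a in table.age_grid if lo < a < hi)
    cuts.update(p - birth for p in table.period_grid if lo < p - birth < hi)
    edges = sorted(cuts)
    segments = []
    cells = {}
    for s, e in zip(edges, edges[1:]):
        mid_age = 0.5 * (s + e)
        i, j = table.locate(mid_age, birth + mid_age)
        key = (int(i), int(j))
        if key not in cells:
            a = table.age_grid
            p = table.period_grid
            cells[key] = RateCell(a[key[0]], a[key[0] + 1],
                                  p[key[1]], p[key[1] + 1],
                                  float(table.rates[key]))
        segments.append(LexisSegment(interval.family_id, interval.person_id,
                                     cells[key], e - s))
    return segments


def expected_count(segments: Iterable[LexisSegment]) -> float:
    """E = sum of person-years x cell rate over Lexis segments."""
    return float(sum(s.person_years * s.cell.rate for s in segments))


def _expected_by_person(birth: np.ndarray, entry_age: np.ndarray,
                        exit_age: np.ndarray, table: RateTable) -> np.ndarray:
    """Vectorized per-person expected counts.

    Equivalent to expand_lexis + expected_count per interval (asserted in
    tests), but loops over the grid's cells instead of over people: along a
    life-line age and date advance together, so the overlap of a follow-up
    interval with cell [a0,a1)x[p0,p1) is
    [max(entry, a0, p0-birth), min(exit, a1, p1-birth)).
    """
    e = np.zeros_like(entry_age, dtype=float)
    ages = table.age_grid
    periods = table.period_grid
    rates = table.rates
    for i in range(len(ages) - 1):
        for j in range(len(periods) - 1):
            r = rates[i, j]
            if r == 0.0:
                continue
            lo = np.maximum(np.maximum(entry_age, ages[i]),
                            periods[j] - birth)
            hi = np.minimum(np.minimum(exit_age, ages[i + 1]),
                            periods[j + 1] - birth)
            e += r * np.clip(hi - lo, 0.0, None)
    return e


# -- FRR estimate ----------------------------------------------------------


@dataclass(frozen=True)
class FRREstimate:
    """Observed/expected FRR with a family-clustered robust 95% CI."""

    label: str
    observed: int
    expected: float
    frr: float
    ci_lo: float
    ci_hi: float
    robust_se: float  # SE of log(FRR); nan when O = 0
    n_families: int

    def __str__(self) -> str:
        return (f"{self.label}: O={self.observed} E={self.expected:.2f} "
                f"FRR={self.frr:.2f} (95% CI {self.ci_lo:.2f}-{self.ci_hi:.2f})")


def _estimate_from_contributions(o_f: np.ndarray, e_f: np.ndarray,
                                 label: str, alpha: float = 0.05
                                 ) -> FRREstimate:
    observed = int(o_f.sum())
    expected = float(e_f.sum())
    if expected <= 0:
        raise EstimationError(f"stratum {label!r}: expected count is zero")
    frr = observed / expected
    z = stats.norm.ppf(1 - alpha / 2)
    if observed == 0:
        return FRREstimate(label, 0, expected, 0.0, 0.0,
                           ZERO_EVENT_UPPER / expected, float("nan"),
                           len(o_f))
    se = float(np.sqrt(np.sum((o_f - frr * e_f) ** 2)) / observed)
    return FRREstimate(label, observed, expected, frr,
                       float(frr * np.exp(-z * se)),
                       float(frr * np.exp(z * se)), se, len(o_f))


def estimate_frr(intervals: Sequence[FollowUpInterval], table: RateTable,
                 label: str = "all", coverage: str = "error",
                 alpha: float = 0.05) -> FRREstimate:
    """FRR = O/E for a set of follow-up intervals against reference rates.

    Families are the robust-variance clusters; intervals sharing a
    ``family_id`` contribute jointly.
    """
    if not intervals:
        raise EstimationError(f"stratum {label!r}: no follow-up intervals")
    birth = np.array([iv.birth_date for iv in intervals])
    entry = np.array([iv.entry_age for iv in intervals])
    exit_ = np.array([iv.exit_age for iv in intervals])
    if coverage == "error":
        for iv in intervals:
            _clip_to_coverage(iv, table, "error")
        event = np.array([iv.event for iv in intervals], dtype=float)
    else:
        kept = [_clip_to_coverage(iv, table, "truncate") for iv in intervals]
        entry = np.array([k[0] if k else 0.0 for k in kept])
        exit_ = np.array([k[1] if k else 0.0 for k in kept])
        event = np.array([bool(k and k[2]) for k in kept], dtype=float)
    e_person = _expected_by_person(birth, entry, exit_, table)
    fam = pd.Series([iv.family_id for iv in intervals])
    codes, _ = pd.factorize(fam)
    n_fam = codes.max() + 1
    o_f = np.zeros(n_fam)
    e_f = np.zeros(n_fam)
    np.add.at(o_f, codes, event)
    np.add.at(e_f, codes, e_person)
    return _estimate_from_contributions(o_f, e_f, label, alpha)


def frr_from_counts(observed: int, expected: float, label: str = "",
                    alpha: float = 0.05) -> FRREstimate:
    """FRR from aggregate O and E only (e.g., a published table row).

    Without family-level contributions the robust clustering is
    unavailable; the SE falls back to the independent-Poisson form
    sqrt(O)/O = 1/sqrt(O) on the log scale.
    """
    if expected <= 0:
        raise EstimationError("expected count must be positive")
    if observed == 0:
        return FRREstimate(label, 0, expected, 0.0, 0.0,
                           ZERO_EVENT_UPPER / expected, float("nan"), 0)
    frr = observed / expected
    se = 1.0 / np.sqrt(observed)
    z = stats.norm.ppf(1 - alpha / 2)
    return FRREstimate(label, int(observed), float(expected), frr,
                       float(frr * np.exp(-z * se)),
                       float(frr * np.exp(z * se)), float(se), 0)


# -- heterogeneity ---------------------------------------------------------


@dataclass(frozen=True)
class HeterogeneityResult:
    labels: tuple[str, str]
    statistic: float  # Wald z for equality of log-FRRs
    p_value: float


def test_frr_heterogeneity(a: FRREstimate, b: FRREstimate
                           ) -> HeterogeneityResult:
    """Two-sided Wald test of equal FRRs on the log scale.

    Strata are assumed to come from disjoint families, so the variance of
    the difference is the sum of the robust variances.
    """
    for est in (a, b):
        if not np.isfinite(est.robust_se) or est.robust_se <= 0:
            raise EstimationError(
                f"stratum {est.label!r}: robust SE unavailable or zero")
        if est.frr <= 0:
            raise EstimationError(
                f"stratum {est.label!r}: FRR must be positive to compare")
    z = (np.log(a.frr) - np.log(b.frr)) / np.hypot(a.robust_se, b.robust_se)
    p = 2 * stats.norm.sf(abs(z))
    return HeterogeneityResult((a.label, b.label), float(z), float(p))


# -- Nelson-Aalen ----------------------------------------------------------


@dataclass(frozen=True)
class CumulativeHazardCurve:
    """Ordered (age, cumulative hazard, variance) triples."""

    ages: np.ndarray
    cumhaz: np.ndarray
    variance: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "cumhaz": self.cumhaz,
                             "variance": self.variance})


def nelson_aalen(intervals: Sequence[FollowUpInterval]
                 ) -> CumulativeHazardCurve:
    """Nelson-Aalen cumulative hazard over age with left truncation.

    A subject is at risk at age t if entry_age < t <= exit_age; ties at one
    age form a single increment d/n with variance increment d/n^2. With no
    events the curve is identically zero.
    """
    entry = np.array([iv.entry_age for iv in intervals])
    exit_ = np.array([iv.exit_age for iv in intervals])
    ev_ages = np.array(sorted({iv.exit_age for iv in intervals if iv.event}),
                       dtype=float)
    if ev_ages.size == 0:
        return CumulativeHazardCurve(np.array([]), np.array([]), np.array([]))
    inc = np.empty_like(ev_ages)
    var = np.empty_like(ev_ages)
    event_exit = np.array([iv.exit_age if iv.event else np.nan
                           for iv in intervals])
    for k, t in enumerate(ev_ages):
        at_risk = np.sum((entry < t) & (exit_ >= t))
        d = np.sum(event_exit == t)
        inc[k] = d / at_risk
        var[k] = d / at_risk ** 2
    return CumulativeHazardCurve(ev_ages, np.cumsum(inc), np.cumsum(var))


# -- subtype analysis grids ------------------------------------------------


def _marker_stratum(grouping: str, p) -> Optional[str]:
    """Stratum label of a proband under a grouping; None = marker missing."""
    U = MarkerStatus.UNKNOWN
    if grouping in ("ER", "PR", "HER2"):
        status = getattr(p, grouping.lower())
        if status is U:
            return None
        return f"{grouping}-{'positive' if status is MarkerStatus.POSITIVE else 'negative'}"
    if grouping == "ERxPR":
        if p.er is U or p.pr is U:
            return None
        e = "+" if p.er is MarkerStatus.POSITIVE else "-"
        r = "+" if p.pr is MarkerStatus.POSITIVE else "-"
        return f"ER{e}PR{r}"
    if grouping == "luminal":
        sub = p.subtype
        if sub is SubtypeLabel.UNCLASSIFIABLE:
            return None
        return sub.value
    raise ValueError(f"unknown grouping {grouping!r}")


GROUPINGS = ("ER", "PR", "HER2", "ERxPR", "luminal")
WINDOWS = ("full", "under50", "from50")
INDEX_AGE_STRATA = ("any", "<50", ">=50")


def run_subtype_analysis(families: Sequence[Family], table: RateTable,
                         grouping: str = "ER",
                         windows: Sequence[str] = ("full",),
                         index_age_strata: Sequence[str] = ("any",),
                         by_role: bool = True,
                         coverage: str = "error",
                         max_age: float = 85.0,
                         cohort_start: float = 1960.0,
                         min_birth_year: float = 1890.0) -> pd.DataFrame:
    """FRR estimates for a grid of subtype strata, windows and index ages.

    Produces one row per (relative role x stratum x window x index-age
    stratum); the ``all`` stratum always includes every eligible relative,
    so relatives of probands with a missing grouping marker appear there and
    only there. Strata with no events are reported with O = 0, not an
    error; empty strata (no person-time) are omitted. Exclusion counts by
    reason are logged.
    """
    exclusions: Counter[str] = Counter()
    rows = []  # (role, stratum or None, index_age_flag<50, interval)
    for fam in families:
        p = fam.proband
        stratum = _marker_stratum(grouping, p)
        young = p.age_at_diagnosis < 50
        for rel in fam.relatives:
            rel = impute_birth_date(rel, p)
            res = derive_follow_up(rel, max_age=max_age,
                                   cohort_start=cohort_start,
                                   min_birth_year=min_birth_year)
            if isinstance(res, Exclusion):
                exclusions[res.reason] += 1
                continue
            rows.append((rel.role.value, stratum, young, res))
    for reason, n in sorted(exclusions.items()):
        logger.info("excluded %d relatives: %s", n, reason)

    roles = ("all", "mother", "sister") if by_role else ("all",)
    strata = ["all"] + sorted({s for _, s, _, _ in rows if s is not None})
    out = []
    for window in windows:
        clipped = [(role, s, young, restrict_age_window(iv, window))
                   for role, s, young, iv in rows]
        clipped = [c for c in clipped if c[3] is not None]
        for ia in index_age_strata:
            for role in roles:
                for stratum in strata:
                    sel = [iv for r, s, young, iv in clipped
                           if (role == "all" or r == role)
                           and (stratum == "all" or s == stratum)
                           and (ia == "any" or young == (ia == "<50"))]
                    if not sel:
                        continue
                    est = estimate_frr(sel, table, label=stratum,
                                       coverage=coverage)
                    out.append({
                        "label": stratum, "window": window,
                        "index_age": ia, "role": role,
                        "observed": est.observed, "expected": est.expected,
                        "frr": est.frr, "ci_lo": est.ci_lo,
                        "ci_hi": est.ci_hi, "robust_se": est.robust_se,
                        "n_families": est.n_families,
                    })
    return pd.DataFrame(out)


def round_report(report: pd.DataFrame) -> pd.DataFrame:
    """Round FRR and CI columns to 2 decimals and E to 2, for table output."""
    out = report.copy()
    for col in ("frr", "ci_lo", "ci_hi", "expected"):
        out[col] = out[col].round(2)
    return out.drop(columns=["robust_se"], errors="ignore")
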