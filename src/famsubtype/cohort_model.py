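"""Cohort data model and eligibility / censoring rules.

Families consist of a proband (the breast-cancer index case, whose tumour
carries ER/PR/HER2 marker status) and her first-degree female relatives
(mothers and sisters only). Relatives form a retrospective cohort: each
woman enters follow-up on 1 January 1960 (or at birth if later) and is
censored at the first of any cancer diagnosis, death, completion of the
family-history questionnaire, or age 85. Relatives born before 1890 are
excluded. Relatives with unknown birth dates receive an imputed one: a
mother is assumed born 30 years before the proband, a sister in the same
year as the proband.

Dates are handled internally as decimal years. ISO ``YYYY-MM-DD`` dates
convert exactly via day-count / 365.25; a bare year ``YYYY`` in the TSV is
read as mid-year (``YYYY + 0.5``) so that reading and writing round-trip
without loss.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd


class CohortDataError(ValueError):
    """Malformed family-history records."""


# -- dates as decimal years ------------------------------------------------

_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_YEAR_RE = re.compile(r"^\d{4}$")


def to_decimal_year(d: _dt.date) -> float:
    """Exact ISO-date -> decimal-year conversion (day count / 365.25)."""
    doy = (d - _dt.date(d.year, 1, 1)).days
    return d.year + doy / 365.25


def from_decimal_year(x: float) -> _dt.date:
    """Inverse of :func:`to_decimal_year` for values produced by it."""
    year = int(math.floor(x))
    doy = int(round((x - year) * 365.25))
    return _dt.date(year, 1, 1) + _dt.timedelta(days=doy)


def parse_date(text: str) -> Optional[float]:
    """Parse a TSV date field: ISO date, bare year (mid-year), or empty."""
    text = (text or "").strip()
    if not text:
        return None
    if _YEAR_RE.match(text):
        return int(text) + 0.5
    if _ISO_RE.match(text):
        return to_decimal_year(_dt.date.fromisoformat(text))
    raise CohortDataError(f"unparseable date {text!r} (want YYYY-MM-DD or YYYY)")


def format_date(x: Optional[float]) -> str:
    """Inverse of :func:`parse_date` (empty string for missing)."""
    if x is None:
        return ""
    if x == math.floor(x) + 0.5:
        return str(int(math.floor(x)))
    return from_decimal_year(x).isoformat()


# -- marker status and subtype ---------------------------------------------


class MarkerStatus(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "MarkerStatus":
        t = (text or "").strip().lower()
        if t in ("positive", "pos", "+", "1"):
            return cls.POSITIVE
        if t in ("negative", "neg", "-", "0"):
            return cls.NEGATIVE
        if t in ("", "unknown", "na", "nan", "."):
            return cls.UNKNOWN
        raise CohortDataError(f"unparseable marker status {text!r}")

    def __str__(self) -> str:  # TSV serialization
        return "" if self is MarkerStatus.UNKNOWN else self.value


class SubtypeLabel(enum.Enum):
    LUMINAL = "luminal"
    LUMINAL_HER2POS = "luminal_her2pos"
    LUMINAL_HER2NEG = "luminal_her2neg"
    NONLUMINAL_HER2POS = "nonluminal_her2pos"
    TRIPLE_NEGATIVE = "triple_negative"
    UNCLASSIFIABLE = "unclassifiable"


_POS = MarkerStatus.POSITIVE
_NEG = MarkerStatus.NEGATIVE


def classify_subtype(er: MarkerStatus, pr: MarkerStatus,
                     her2: MarkerStatus) -> SubtypeLabel:
    """Immunohistochemical subtype from ER/PR/HER2 status.

    Luminal means ER and/or PR positive; within luminal the HER2 split is
    made only when HER2 is known (otherwise the coarse ``luminal`` label is
    kept). Non-luminal HER2-positive requires ER and PR both negative with
    HER2 positive; triple negative requires all three negative. Any
    combination whose deciding markers are unknown is unclassifiable.
    Total: every status triple maps to exactly one label.
    """
    if er is _POS or pr is _POS:
        if her2 is _POS:
            return SubtypeLabel.LUMINAL_HER2POS
        if her2 is _NEG:
            return SubtypeLabel.LUMINAL_HER2NEG
        return SubtypeLabel.LUMINAL
    if er is _NEG and pr is _NEG:
        if her2 is _POS:
            return SubtypeLabel.NONLUMINAL_HER2POS
        if her2 is _NEG:
            return SubtypeLabel.TRIPLE_NEGATIVE
    return SubtypeLabel.UNCLASSIFIABLE


# -- records ---------------------------------------------------------------


class Role(enum.Enum):
    MOTHER = "mother"
    SISTER = "sister"

    @classmethod
    def parse(cls, text: str) -> "Role":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise CohortDataError(f"unknown relative role {text!r}") from None


@dataclass(frozen=True)
class Proband:
    """Index case: contributes subtype labels but no person-time."""

    family_id: str
    person_id: str
    birth_date: float
    diagnosis_date: float
    er: MarkerStatus = MarkerStatus.UNKNOWN
    pr: MarkerStatus = MarkerStatus.UNKNOWN
    her2: MarkerStatus = MarkerStatus.UNKNOWN
    age_at_diagnosis: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.diagnosis_date > self.birth_date:
            raise CohortDataError(
                f"proband {self.person_id}: diagnosis before birth")
        derived = self.diagnosis_date - self.birth_date
        if self.age_at_diagnosis is None:
            object.__setattr__(self, "age_at_diagnosis", derived)
        elif abs(self.age_at_diagnosis - derived) > 1.0:
            raise CohortDataError(
                f"proband {self.person_id}: age_at_diagnosis "
                f"{self.age_at_diagnosis} inconsistent with dates ({derived:.2f})")

    @property
    def subtype(self) -> SubtypeLabel:
        return classify_subtype(self.er, self.pr, self.her2)


@dataclass(frozen=True)
class Relative:
    """Mother or sister of the proband; the at-risk cohort member."""

    family_id: str
    person_id: str
    role: Role
    questionnaire_date: float
    birth_date: Optional[float] = None
    birth_date_imputed: bool = False
    breast_cancer_date: Optional[float] = None
    other_cancer_date: Optional[float] = None
    death_date: Optional[float] = None

    def __post_init__(self) -> None:
        if self.questionnaire_date is None:
            raise CohortDataError(
                f"relative {self.person_id}: questionnaire date required")
        if self.birth_date is not None:
            for name in ("breast_cancer_date", "other_cancer_date",
                         "death_date", "questionnaire_date"):
                val = getattr(self, name)
                if val is not None and val <= self.birth_date:
                    raise CohortDataError(
                        f"relative {self.person_id}: {name} not after birth")


@dataclass(frozen=True)
class Family:
    family_id: str
    proband: Proband
    relatives: tuple[Relative, ...] = ()


@dataclass(frozen=True)
class FollowUpInterval:
    """At-risk segment of one relative, in both age and calendar time."""

    family_id: str
    person_id: str
    entry_age: float
    exit_age: float
    entry_date: float
    exit_date: float
    event: bool  # breast cancer at exit

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise CohortDataError(
                f"{self.person_id}: entry_age {self.entry_age} !< "
                f"exit_age {self.exit_age}")
        if abs((self.exit_date - self.entry_date)
               - (self.exit_age - self.entry_age)) > 1e-9:
            raise CohortDataError(
                f"{self.person_id}: age span and date span disagree")

    @property
    def length(self) -> float:
        return self.exit_age - self.entry_age

    @property
    def birth_date(self) -> float:
        return self.entry_date - self.entry_age


@dataclass(frozen=True)
class Exclusion:
    """A relative removed before follow-up, with a machine-readable reason."""

    family_id: str
    person_id: str
    reason: str


# -- eligibility and censoring ---------------------------------------------

MOTHER_IMPUTATION_OFFSET = 30.0  # years before the proband's birth

#: censoring causes in tie-break priority order (first wins on a shared date)
CENSOR_PRIORITY = ("breast_cancer", "other_cancer", "death",
                   "questionnaire", "age_cap")


def impute_birth_date(relative: Relative, proband: Proband) -> Relative:
    """Fill a missing birth date from the proband's.

    Mothers are assumed born 30 years before the proband; sisters in the
    same year as the proband. Known birth dates pass through unchanged.
    """
    if relative.birth_date is not None:
        return relative
    if relative.role is Role.MOTHER:
        birth = proband.birth_date - MOTHER_IMPUTATION_OFFSET
    elif relative.role is Role.SISTER:
        birth = proband.birth_date
    else:  # pragma: no cover - Role enum is closed
        raise CohortDataError(f"cannot impute birth for role {relative.role}")
    return dataclasses.replace(relative, birth_date=birth,
                               birth_date_imputed=True)


def derive_follow_up(relative: Relative, max_age: float = 85.0,
                     cohort_start: float = 1960.0,
                     min_birth_year: float = 1890.0,
                     tie_priority: tuple[str, ...] = CENSOR_PRIORITY
                     ) -> FollowUpInterval | Exclusion:
    """Apply entry, censoring and exclusion rules to one relative.

    Entry is the later of ``cohort_start`` and birth; exit is the earliest
    of breast-cancer diagnosis, any other cancer diagnosis, death,
    questionnaire completion, and reaching ``max_age``. The relative is an
    event only when the breast-cancer date wins (ties broken by
    ``tie_priority``). Returns an :class:`Exclusion` for births before
    ``min_birth_year`` and for relatives with no at-risk time.
    """
    if relative.birth_date is None:
        raise CohortDataError(
            f"relative {relative.person_id}: birth date missing; impute first")
    birth = relative.birth_date
    if birth < min_birth_year:
        return Exclusion(relative.family_id, relative.person_id,
                         f"pre-{int(min_birth_year)} birth")
    candidates = {
        "breast_cancer": relative.breast_cancer_date,
        "other_cancer": relative.other_cancer_date,
        "death": relative.death_date,
        "questionnaire": relative.questionnaire_date,
        "age_cap": birth + max_age,
    }
    entry = max(cohort_start, birth)
    exit_date = min(v for v in candidates.values() if v is not None)
    cause = next(c for c in tie_priority
                 if candidates[c] is not None and candidates[c] == exit_date)
    if exit_date <= entry:
        return Exclusion(relative.family_id, relative.person_id,
                         "no at-risk time")
    return FollowUpInterval(
        family_id=relative.family_id, person_id=relative.person_id,
        entry_age=entry - birth, exit_age=exit_date - birth,
        entry_date=entry, exit_date=exit_date,
        event=(cause == "breast_cancer"))


def restrict_age_window(interval: FollowUpInterval, window: str,
                        cut: float = 50.0) -> Optional[FollowUpInterval]:
    """Clip follow-up to an age window: ``under50``, ``from50`` or ``full``.

    ``under50`` keeps person-time below the cut (the event is kept only if
    it occurs strictly before it); ``from50`` keeps person-time from the cut
    on. The two windows partition the full interval's person-time exactly.
    An event at exactly the cut age is a measure-zero boundary case under
    continuous time and is counted by neither window. Returns ``None`` when
    the clipped interval is empty.
    """
    if window == "full":
        return interval
    if window == "under50":
        if interval.entry_age >= cut:
            return None
        new_exit_age = min(interval.exit_age, cut)
        if new_exit_age <= interval.entry_age:
            return None
        return FollowUpInterval(
            interval.family_id, interval.person_id,
            interval.entry_age, new_exit_age,
            interval.entry_date,
            interval.entry_date + (new_exit_age - interval.entry_age),
            interval.event and interval.exit_age < cut)
    if window == "from50":
        if interval.exit_age <= cut:
            return None
        new_entry_age = max(interval.entry_age, cut)
        return FollowUpInterval(
            interval.family_id, interval.person_id,
            new_entry_age, interval.exit_age,
            interval.exit_date - (interval.exit_age - new_entry_age),
            interval.exit_date, interval.event)
    raise ValueError(f"unknown window {window!r}")


# -- TSV I/O ---------------------------------------------------------------

FAMILY_COLUMNS = (
    "family_id", "person_id", "role", "birth_date", "diagnosis_date",
    "er", "pr", "her2", "breast_cancer_date", "other_cancer_date",
    "death_date", "questionnaire_date",
)


def read_family_table(path) -> list[Family]:
    """Read the family TSV dialect into :class:`Family` records.

    One ``role=proband`` row per family is mandatory; relatives must cite a
    family that has a proband; person ids are globally unique. Empty string
    means missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FAMILY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortDataError(f"family TSV {path} missing columns {missing}")
    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise CohortDataError(f"duplicate person_id {dup!r}")

    probands: dict[str, Proband] = {}
    relatives: dict[str, list[Relative]] = {}
    order: list[str] = []
    for row in df.itertuples():
        fid = row.family_id
        if fid not in relatives:
            relatives[fid] = []
            order.append(fid)
        if row.role.strip().lower() == "proband":
            if fid in probands:
                raise CohortDataError(f"family {fid!r}: more than one proband")
            birth = parse_date(row.birth_date)
            diag = parse_date(row.diagnosis_date)
            if birth is None or diag is None:
                raise CohortDataError(
                    f"proband {row.person_id!r}: birth and diagnosis "
                    "dates are mandatory")
            probands[fid] = Proband(
                family_id=fid, person_id=row.person_id,
                birth_date=birth, diagnosis_date=diag,
                er=MarkerStatus.parse(row.er),
                pr=MarkerStatus.parse(row.pr),
                her2=MarkerStatus.parse(row.her2))
        else:
            q = parse_date(row.questionnaire_date)
            if q is None:
                raise CohortDataError(
                    f"relative {row.person_id!r}: questionnaire date mandatory")
            relatives[fid].append(Relative(
                family_id=fid, person_id=row.person_id,
                role=Role.parse(row.role), questionnaire_date=q,
                birth_date=parse_date(row.birth_date),
                breast_cancer_date=parse_date(row.breast_cancer_date),
                other_cancer_date=parse_date(row.other_cancer_date),
                death_date=parse_date(row.death_date)))
    families = []
    for fid in order:
        if fid not in probands:
            raise CohortDataError(f"family {fid!r} has relatives but no proband")
        families.append(Family(fid, probands[fid], tuple(relatives[fid])))
    return families


def write_family_table(families: Iterable[Family], path) -> None:
    """Write families back to the TSV dialect (inverse of the reader)."""
    rows = []
    for fam in families:
        p = fam.proband
        rows.append({
            "family_id": fam.family_id, "person_id": p.person_id,
            "role": "proband", "birth_date": format_date(p.birth_date),
            "diagnosis_date": format_date(p.diagnosis_date),
            "er": str(p.er), "pr": str(p.pr), "her2": str(p.her2),
            "breast_cancer_date": "", "other_cancer_date": "",
            "death_date": "", "questionnaire_date": "",
        })
        for r in fam.relatives:
            rows.append({
                "family_id": fam.family_id, "person_id": r.person_id,
                "role": r.role.value,
                "birth_date": ("" if r.birth_date_imputed
                               else format_date(r.birth_date)),
                "diagnosis_date": "", "er": "", "pr": "", "her2": "",
                "breast_cancer_date": format_date(r.breast_cancer_date),
                "other_cancer_date": format_date(r.other_cancer_date),
                "death_date": format_date(r.death_date),
                "questionnaire_date": format_date(r.questionnaire_date),
            })
    pd.DataFrame(rows, columns=list(FAMILY_COLUMNS)).to_csv(
        path, sep="\t", index=False)
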