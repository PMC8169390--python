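"""Domain types and date semantics for registry records.

ClinicalTrials.gov reports some dates (notably primary completion dates
registered before 2017) at month or year precision.  All due-date
arithmetic in this package is exact calendar-day counting on *resolved*
dates; partial dates are resolved deterministically by a configurable
convention, defaulting to the last consistent day (which postpones
due-ness and therefore gives sponsors the benefit of the doubt).
"""

from __future__ import annotations

import calendar
import enum
import logging
import re
from dataclasses import dataclass, field
from datetime import date

logger = logging.getLogger(__name__)

__all__ = [
    "PartialDate",
    "DateConvention",
    "OverallStatus",
    "StudyType",
    "TrialRecord",
    "ClassificationConfig",
    "MalformedDateError",
    "resolve_partial_date",
    "days_between",
]


class MalformedDateError(ValueError):
    """A date string or (year, month, day) combination is not a valid date."""


class DateConvention(enum.Enum):
    """How a partial-precision date is resolved to a full calendar date."""

    LAST_DAY = "last"
    FIRST_DAY = "first"
    MID_MONTH = "mid"


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date that may lack day, or both day and month.

    Invariants: ``day`` present implies ``month`` present; when fully
    specified, (year, month, day) must be a valid Gregorian date.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise MalformedDateError(
                f"day without month in partial date ({self.year}, None, {self.day})"
            )
        if self.month is not None and not 1 <= self.month <= 12:
            raise MalformedDateError(f"month {self.month} out of range in {self.year}")
        if self.day is not None:
            last = calendar.monthrange(self.year, self.month)[1]
            if not 1 <= self.day <= last:
                raise MalformedDateError(
                    f"day {self.day} invalid for {self.year}-{self.month:02d}"
                )

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def isoformat(self) -> str:
        """ISO-8601 with truncation: '2014', '2014-06' or '2014-06-30'."""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    @classmethod
    def from_date(cls, d: date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    _ISO_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")
    _TEXT_RE = re.compile(
        r"^([A-Za-z]+)\s+(?:(\d{1,2}),\s+)?(\d{4})$"
    )  # "June 2014" / "June 30, 2014"

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse registry date text, preserving partial precision.

        Accepts ISO-8601 truncated forms ('2014', '2014-06', '2014-06-30')
        and the registry's legacy long forms ('June 2014', 'June 30, 2014').
        """
        s = text.strip()
        m = cls._ISO_RE.match(s)
        if m:
            y, mo, dy = m.groups()
            return cls(int(y), int(mo) if mo else None, int(dy) if dy else None)
        m = cls._TEXT_RE.match(s)
        if m:
            month_name, dy, y = m.groups()
            try:
                month = list(calendar.month_name).index(month_name.capitalize())
            except ValueError:
                month = 0
            if month == 0:
                try:
                    month = list(calendar.month_abbr).index(month_name[:3].capitalize())
                except ValueError:
                    raise MalformedDateError(f"unrecognised month in date {text!r}")
            return cls(int(y), month, int(dy) if dy else None)
        raise MalformedDateError(f"unparseable date text {text!r}")


def resolve_partial_date(
    d: PartialDate, convention: DateConvention = DateConvention.LAST_DAY
) -> date:
    """Resolve a partial date to a full calendar date, deterministically.

    LAST_DAY: latest consistent day (2014 -> 2014-12-31, 2014-06 -> 2014-06-30).
    FIRST_DAY: earliest consistent day.
    MID_MONTH: day 15 of the month, or July 1 for year-only precision.

    Idempotent on fully specified dates for every convention.
    """
    if d.month is None:
        if convention is DateConvention.LAST_DAY:
            return date(d.year, 12, 31)
        if convention is DateConvention.FIRST_DAY:
            return date(d.year, 1, 1)
        return date(d.year, 7, 1)
    if d.day is None:
        if convention is DateConvention.LAST_DAY:
            return date(d.year, d.month, calendar.monthrange(d.year, d.month)[1])
        if convention is DateConvention.FIRST_DAY:
            return date(d.year, d.month, 1)
        return date(d.year, d.month, 15)
    return date(d.year, d.month, d.day)


def days_between(earlier: date, later: date) -> int:
    """Signed exact calendar-day count ``later - earlier``.

    No rounding and no month approximations; negative when ``later``
    precedes ``earlier``.
    """
    return (later - earlier).days


class OverallStatus(enum.Enum):
    NOT_YET_RECRUITING = "NOT_YET_RECRUITING"
    RECRUITING = "RECRUITING"
    ENROLLING_BY_INVITATION = "ENROLLING_BY_INVITATION"
    ACTIVE_NOT_RECRUITING = "ACTIVE_NOT_RECRUITING"
    COMPLETED = "COMPLETED"
    TERMINATED = "TERMINATED"
    SUSPENDED = "SUSPENDED"
    WITHDRAWN = "WITHDRAWN"
    UNKNOWN = "UNKNOWN"

    @property
    def is_finished(self) -> bool:
        """Completed and Terminated are the only finished statuses."""
        return self in (OverallStatus.COMPLETED, OverallStatus.TERMINATED)

    @property
    def is_exempt(self) -> bool:
        """Suspended and Withdrawn trials carry no reporting requirement."""
        return self in (OverallStatus.SUSPENDED, OverallStatus.WITHDRAWN)

    @property
    def is_ongoing(self) -> bool:
        return self in (
            OverallStatus.NOT_YET_RECRUITING,
            OverallStatus.RECRUITING,
            OverallStatus.ENROLLING_BY_INVITATION,
            OverallStatus.ACTIVE_NOT_RECRUITING,
        )

    @classmethod
    def parse(cls, text: str) -> "OverallStatus":
        """Normalise registry status vocabulary, case-insensitively.

        Spaces and commas are tolerated ('Active, not recruiting' ->
        ACTIVE_NOT_RECRUITING).  'Unknown status' and any unrecognised
        string map to UNKNOWN (with a warning for the latter), so novel
        registry vocabulary degrades to the inconsistent bucket rather
        than crashing an audit.
        """
        key = re.sub(r"[\s,]+", "_", text.strip()).upper().strip("_")
        if key in ("UNKNOWN_STATUS", ""):
            return cls.UNKNOWN
        try:
            return cls[key]
        except KeyError:
            logger.warning("unrecognised overall status %r mapped to UNKNOWN", text)
            return cls.UNKNOWN


class StudyType(enum.Enum):
    INTERVENTIONAL = "INTERVENTIONAL"
    OBSERVATIONAL = "OBSERVATIONAL"
    EXPANDED_ACCESS = "EXPANDED_ACCESS"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, text: str) -> "StudyType":
        key = re.sub(r"[\s,]+", "_", text.strip()).upper().strip("_")
        if key.startswith("OBSERVATIONAL"):  # "Observational [Patient Registry]"
            return cls.OBSERVATIONAL
        try:
            return cls[key]
        except KeyError:
            return cls.OTHER


_NCT_RE = re.compile(r"^NCT\d8$".replace("8", "{8}"))


@dataclass(frozen=True)
class TrialRecord:
    """One registry entry, as consumed by the classifier."""

    nct_id: str
    lead_sponsor: str
    study_type: StudyType
    overall_status: OverallStatus
    primary_completion_date: PartialDate | None = None
    results_first_posted: date | None = None

    def __post_init__(self) -> None:
        if not _NCT_RE.match(self.nct_id):
            raise ValueError(f"invalid NCT identifier {self.nct_id!r}")


@dataclass(frozen=True)
class ClassificationConfig:
    """Reference date and thresholds of an audit run.

    ``reporting_window_days`` operationalises the WHO 12-month disclosure
    window as 365 days; ``grace_days`` adds the registry's 30-day
    quality-control interval between results submission and public
    posting.  A trial is *due* when its resolved primary completion date
    lies strictly more than ``due_threshold_days`` (= window + grace,
    default 395) before ``as_of``.
    """

    as_of: date
    reporting_window_days: int = 365
    grace_days: int = 30
    date_convention: DateConvention = DateConvention.LAST_DAY

    def __post_init__(self) -> None:
        if self.reporting_window_days <= 0:
            raise ValueError("reporting_window_days must be strictly positive")
        if self.grace_days < 0:
            raise ValueError("grace_days must be non-negative")

    @property
    def due_threshold_days(self) -> int:
        return self.reporting_window_days + self.grace_days

    def resolve(self, d: PartialDate) -> date:
        return resolve_partial_date(d, self.date_convention)
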