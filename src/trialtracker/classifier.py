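"""Reporting-status classification of registry trial records.

Every interventional trial record is assigned to exactly one category of
a mutually exclusive, collectively exhaustive taxonomy, as a function of
the record and the audit reference date (``as_of``):

* ``NO_REQUIREMENT`` — Suspended or Withdrawn trials; never required to
  report, even if dates are missing or results were in fact posted
  (posted results are ignored).
* ``DUE_UNREPORTED`` — finished (Completed/Terminated) trials whose
  resolved primary completion date (PCD) lies strictly more than the due
  threshold (default 395 days = 365-day WHO window + 30-day posting
  grace) in the past, without posted results; finished trials with no
  PCD at all and no results are also due-unreported.
* ``DUE_REPORTED_TIMELY`` / ``DUE_REPORTED_LATE`` — due trials that did
  post results, split on whether posting occurred within the threshold
  (inclusive) of the PCD or after it.
* ``NOT_DUE_UNREPORTED`` / ``NOT_DUE_REPORTED`` — finished trials whose
  PCD is at most the threshold in the past.
* ``ONGOING`` — recruiting-family statuses with a PCD not in the past.
* ``INCONSISTENT`` — unknown status, or an ongoing status contradicted
  by its dates (PCD in the past, or no PCD at all).

Boundary semantics: "more than 395 days in the past" is strict (>);
"reported within 395 days" is inclusive (<=).  The two phrasings
partition the integers only under this reading.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .registry_model import (
    ClassificationConfig,
    OverallStatus,
    TrialRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReportingCategory",
    "InconsistencyReason",
    "ClassifiedTrial",
    "classify",
    "classify_all",
    "is_due",
    "DUE_CATEGORIES",
]


class ReportingCategory(enum.Enum):
    NO_REQUIREMENT = "NO_REQUIREMENT"
    DUE_UNREPORTED = "DUE_UNREPORTED"
    DUE_REPORTED_LATE = "DUE_REPORTED_LATE"
    DUE_REPORTED_TIMELY = "DUE_REPORTED_TIMELY"
    NOT_DUE_UNREPORTED = "NOT_DUE_UNREPORTED"
    NOT_DUE_REPORTED = "NOT_DUE_REPORTED"
    ONGOING = "ONGOING"
    INCONSISTENT = "INCONSISTENT"


#: Categories that count toward the due-trial denominator.
DUE_CATEGORIES = frozenset(
    {
        ReportingCategory.DUE_UNREPORTED,
        ReportingCategory.DUE_REPORTED_LATE,
        ReportingCategory.DUE_REPORTED_TIMELY,
    }
)


class InconsistencyReason(enum.Enum):
    UNKNOWN_STATUS = "UNKNOWN_STATUS"
    ONGOING_PAST_COMPLETION = "ONGOING_PAST_COMPLETION"
    ONGOING_NO_COMPLETION_DATE = "ONGOING_NO_COMPLETION_DATE"
    NONE = "NONE"


@dataclass(frozen=True)
class ClassifiedTrial:
    """A trial record joined with its category and timing quantities.

    ``days_since_pcd``: as_of minus the resolved PCD (present whenever a
    PCD is present).  ``days_to_report``: results-first-posted minus the
    resolved PCD; present only when both dates exist and the trial is
    not exempt.  ``days_overdue``: how far past the due threshold an
    unreported due trial is.
    """

    record: TrialRecord
    category: ReportingCategory
    inconsistency: InconsistencyReason = InconsistencyReason.NONE
    days_since_pcd: int | None = None
    days_to_report: int | None = None
    days_overdue: int | None = None


def classify(record: TrialRecord, config: ClassificationConfig) -> ClassifiedTrial:
    """Assign a record to exactly one reporting category.

    The rules are evaluated in a fixed order so that the Suspended/
    Withdrawn exemption always short-circuits, then finished statuses,
    then unknown status, then the ongoing family.  Every well-formed
    record classifies; there is no error path.
    """
    status = record.overall_status
    threshold = config.due_threshold_days

    pcd = (
        config.resolve(record.primary_completion_date)
        if record.primary_completion_date is not None
        else None
    )
    days_since = (config.as_of - pcd).days if pcd is not None else None

    results = record.results_first_posted
    if results is not None and results > config.as_of:
        # A posting date after the audit date is malformed at this as_of;
        # the results are ignored for classification.
        logger.warning(
            "%s: results_first_posted %s is after as_of %s; ignoring results",
            record.nct_id,
            results.isoformat(),
            config.as_of.isoformat(),
        )
        results = None

    days_to_report = (results - pcd).days if results is not None and pcd is not None else None

    # (1) exemption short-circuits everything, posted results included
    if status.is_exempt:
        return ClassifiedTrial(record, ReportingCategory.NO_REQUIREMENT)

    # (2) finished trials
    if status.is_finished:
        if pcd is None:
            if results is None:
                # finished, no PCD, no results: treated as due-unreported
                return ClassifiedTrial(record, ReportingCategory.DUE_UNREPORTED)
            # Finished with results but no PCD: results exist but their
            # timeliness is unverifiable; conservatively late, with the
            # timing fields absent.
            logger.warning(
                "%s: finished with results but no primary completion date; "
                "classed as due-reported-late with unverifiable timing",
                record.nct_id,
            )
            return ClassifiedTrial(record, ReportingCategory.DUE_REPORTED_LATE)
        if days_since > threshold:  # strictly more than threshold -> due
            if results is None:
                return ClassifiedTrial(
                    record,
                    ReportingCategory.DUE_UNREPORTED,
                    days_since_pcd=days_since,
                    days_overdue=days_since - threshold,
                )
            cat = (
                ReportingCategory.DUE_REPORTED_TIMELY
                if days_to_report <= threshold
                else ReportingCategory.DUE_REPORTED_LATE
            )
            return ClassifiedTrial(
                record, cat, days_since_pcd=days_since, days_to_report=days_to_report
            )
        # not yet due (<= threshold, including PCD in the future)
        if results is None:
            return ClassifiedTrial(
                record, ReportingCategory.NOT_DUE_UNREPORTED, days_since_pcd=days_since
            )
        return ClassifiedTrial(
            record,
            ReportingCategory.NOT_DUE_REPORTED,
            days_since_pcd=days_since,
            days_to_report=days_to_report,
        )

    # (3) unknown status is inconsistent by definition
    if status is OverallStatus.UNKNOWN:
        return ClassifiedTrial(
            record,
            ReportingCategory.INCONSISTENT,
            InconsistencyReason.UNKNOWN_STATUS,
            days_since_pcd=days_since,
            days_to_report=days_to_report,
        )

    # (4) ongoing family
    if pcd is None:
        return ClassifiedTrial(
            record,
            ReportingCategory.INCONSISTENT,
            InconsistencyReason.ONGOING_NO_COMPLETION_DATE,
        )
    if pcd < config.as_of:
        return ClassifiedTrial(
            record,
            ReportingCategory.INCONSISTENT,
            InconsistencyReason.ONGOING_PAST_COMPLETION,
            days_since_pcd=days_since,
            days_to_report=days_to_report,
        )
    return ClassifiedTrial(
        record,
        ReportingCategory.ONGOING,
        days_since_pcd=days_since,
        days_to_report=days_to_report,
    )


def classify_all(
    records: Iterable[TrialRecord], config: ClassificationConfig
) -> list[ClassifiedTrial]:
    """Classify a sequence of records, preserving order."""
    return [classify(r, config) for r in records]


def is_due(record: TrialRecord, config: ClassificationConfig) -> bool:
    """True iff the record's PCD makes it count toward the due denominator."""
    return classify(record, config).category in DUE_CATEGORIES
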