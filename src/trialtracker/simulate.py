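"""Seeded synthetic registry generator.

Emulates a cohort of ClinicalTrials.gov records for testing the audit
pipeline without network access: configurable overall-status mixture,
partial-precision completion dates, a reporting probability for due
trials, and a right-skewed (log-normal) reporting-delay distribution
(real registry delays are positive and heavily right-skewed, with mean
well above median).  Each generated record carries the reporting
category the generator *intends*, derived from its own construction —
never by running the classifier — so classifier-recovery tests are a
genuine round trip.

The generator only emits unambiguous configurations: no future-dated
results and no finished-with-results-but-no-completion-date records.
Those documented edge cases are pinned by dedicated hand-built fixtures
in the test suite instead.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .classifier import InconsistencyReason, ReportingCategory
from .registry_model import (
    OverallStatus,
    PartialDate,
    StudyType,
    TrialRecord,
)

__all__ = [
    "SimulationParams",
    "GeneratedTrial",
    "generate_registry",
    "DEFAULT_STATUS_MIX",
]

#: Default status mixture, shaped like a mature academic-sponsor cohort:
#: a majority of finished trials, a sizeable ongoing tail, and small
#: unknown/suspended/withdrawn fractions.
DEFAULT_STATUS_MIX: dict[OverallStatus, float] = {
    OverallStatus.COMPLETED: 0.50,
    OverallStatus.TERMINATED: 0.06,
    OverallStatus.RECRUITING: 0.14,
    OverallStatus.ACTIVE_NOT_RECRUITING: 0.08,
    OverallStatus.NOT_YET_RECRUITING: 0.04,
    OverallStatus.ENROLLING_BY_INVITATION: 0.02,
    OverallStatus.UNKNOWN: 0.10,
    OverallStatus.SUSPENDED: 0.02,
    OverallStatus.WITHDRAWN: 0.04,
}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic registry.

    ``delay_log_mu``/``delay_log_sigma`` are the location and scale of
    the log-normal reporting delay, in log-days.  The defaults place the
    median delay at exp(6.59) ~ 728 days and the mean at
    exp(mu + sigma^2/2) ~ 981 days — a delay profile typical of academic
    sponsors, far beyond the 395-day window.  ``p_report_given_due`` is
    the probability that a due finished trial has posted results at all
    (default 0.10: roughly one due academic trial in ten has tabular
    registry results).  ``p_month_precision`` is the probability a
    completion date lacks its day, as pre-2017 registrations commonly
    do.
    """

    n_trials: int = 1000
    sponsor_names: tuple[str, ...] = ("University of Synthetica",)
    status_mix: dict[OverallStatus, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_MIX)
    )
    p_report_given_due: float = 0.10
    p_report_given_not_due: float = 0.05
    delay_log_mu: float = 6.59
    delay_log_sigma: float = 0.772
    p_month_precision: float = 0.50
    p_ongoing_past_pcd: float = 0.25
    p_ongoing_missing_pcd: float = 0.10
    pcd_window: tuple[date, date] = (date(2005, 1, 1), date(2020, 10, 19))
    as_of: date = date(2020, 10, 19)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not self.sponsor_names:
            raise ValueError("at least one sponsor name is required")
        for p in (
            self.p_report_given_due,
            self.p_report_given_not_due,
            self.p_month_precision,
            self.p_ongoing_past_pcd,
            self.p_ongoing_missing_pcd,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_ongoing_past_pcd + self.p_ongoing_missing_pcd > 1.0:
            raise ValueError("ongoing inconsistency probabilities exceed 1")
        total = math.fsum(self.status_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"status_mix sums to {total}, not 1")
        if any(p < 0 for p in self.status_mix.values()):
            raise ValueError("status_mix probabilities must be non-negative")
        if self.pcd_window[0] > self.pcd_window[1]:
            raise ValueError("pcd_window start after end")
        if self.delay_log_sigma < 0:
            raise ValueError("delay_log_sigma must be non-negative")

    @property
    def delay_mean_days(self) -> float:
        """Analytic mean of the log-normal delay distribution."""
        return math.exp(self.delay_log_mu + self.delay_log_sigma**2 / 2)

    @property
    def delay_sd_days(self) -> float:
        """Analytic standard deviation of the log-normal delay."""
        s2 = self.delay_log_sigma**2
        return math.sqrt((math.exp(s2) - 1) * math.exp(2 * self.delay_log_mu + s2))


@dataclass(frozen=True)
class GeneratedTrial:
    """A synthetic record plus the category its construction implies."""

    record: TrialRecord
    true_category: ReportingCategory
    true_inconsistency: InconsistencyReason = InconsistencyReason.NONE


def _sample_pcd(
    rng: np.random.Generator,
    window_lo: date,
    window_hi: date,
    p_month: float,
) -> tuple[PartialDate, date]:
    """Sample a completion date, possibly at month precision.

    Returns the stored partial date together with its resolution under
    the default LAST_DAY convention.  Month-precision dates are placed
    at their month's end, so truncation is lossless and the resolved
    date (hence the intended category) is unambiguous; the month-end
    snap may push the resolved date up to 30 days past ``window_hi``.
    """
    span = (window_hi - window_lo).days
    full = window_lo + timedelta(days=int(rng.integers(span + 1)))
    if rng.random() < p_month:
        last = calendar.monthrange(full.year, full.month)[1]
        resolved = date(full.year, full.month, last)
        return PartialDate(full.year, full.month), resolved
    return PartialDate.from_date(full), full


def generate_registry(params: SimulationParams) -> list[GeneratedTrial]:
    """Generate a reproducible synthetic registry cohort.

    Records come with their intended category as ground truth; NCT
    identifiers are synthetic ("NCT9...") and unique.  Intended-category
    bookkeeping uses the 395-day due threshold and the LAST_DAY
    resolution convention, i.e. the default audit configuration.
    """
    rng = np.random.default_rng(params.seed)
    statuses = list(params.status_mix.keys())
    weights = np.array([params.status_mix[s] for s in statuses], dtype=float)
    weights = weights / weights.sum()
    threshold = 395
    as_of = params.as_of
    lo, hi = params.pcd_window
    finished_hi = min(hi, as_of)
    out: list[GeneratedTrial] = []

    for i in range(params.n_trials):
        nct_id = f"NCT{90000000 + i:08d}"
        sponsor = params.sponsor_names[int(rng.integers(len(params.sponsor_names)))]
        status: OverallStatus = statuses[int(rng.choice(len(statuses), p=weights))]

        pcd: PartialDate | None = None
        posted: date | None = None
        reason = InconsistencyReason.NONE

        if status.is_exempt:
            # exempt regardless of dates; give half of them a date anyway
            category = ReportingCategory.NO_REQUIREMENT
            if rng.random() < 0.5:
                pcd, _ = _sample_pcd(rng, lo, finished_hi, params.p_month_precision)
        elif status.is_finished:
            pcd, resolved = _sample_pcd(rng, lo, finished_hi, params.p_month_precision)
            days_since = (as_of - resolved).days
            if days_since > threshold:
                if rng.random() < params.p_report_given_due:
                    delay = int(
                        rng.lognormal(params.delay_log_mu, params.delay_log_sigma)
                    )
                    # keep the posting on or before the audit date
                    delay = max(1, min(delay, days_since))
                    posted = resolved + timedelta(days=delay)
                    category = (
                        ReportingCategory.DUE_REPORTED_TIMELY
                        if delay <= threshold
                        else ReportingCategory.DUE_REPORTED_LATE
                    )
                else:
                    category = ReportingCategory.DUE_UNREPORTED
            else:
                if days_since >= 1 and rng.random() < params.p_report_given_not_due:
                    delay = int(rng.integers(1, days_since + 1))
                    posted = resolved + timedelta(days=delay)
                    category = ReportingCategory.NOT_DUE_REPORTED
                else:
                    category = ReportingCategory.NOT_DUE_UNREPORTED
        elif status is OverallStatus.UNKNOWN:
            category = ReportingCategory.INCONSISTENT
            reason = InconsistencyReason.UNKNOWN_STATUS
            if rng.random() < 0.5:
                pcd, _ = _sample_pcd(rng, lo, hi, params.p_month_precision)
        else:  # ongoing family
            u = rng.random()
            if u < params.p_ongoing_missing_pcd:
                category = ReportingCategory.INCONSISTENT
                reason = InconsistencyReason.ONGOING_NO_COMPLETION_DATE
            elif u < params.p_ongoing_missing_pcd + params.p_ongoing_past_pcd:
                # resolved PCD strictly before as_of, even after month-end
                # snapping (31-day margin) — contradicts the ongoing status
                category = ReportingCategory.INCONSISTENT
                reason = InconsistencyReason.ONGOING_PAST_COMPLETION
                pcd, _ = _sample_pcd(
                    rng, lo, as_of - timedelta(days=31), params.p_month_precision
                )
            else:
                # resolved PCD on or after as_of
                category = ReportingCategory.ONGOING
                pcd, _ = _sample_pcd(
                    rng,
                    as_of,
                    as_of + timedelta(days=5 * 365),
                    params.p_month_precision,
                )

        record = TrialRecord(
            nct_id=nct_id,
            lead_sponsor=sponsor,
            study_type=StudyType.INTERVENTIONAL,
            overall_status=status,
            primary_completion_date=pcd,
            results_first_posted=posted,
        )
        out.append(GeneratedTrial(record, category, reason))
    return out
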