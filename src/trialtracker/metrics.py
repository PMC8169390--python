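"""Per-sponsor aggregation of classified trials and delay statistics.

The sponsor summary is the row of the audit table: counts per reporting
category, the due-trial denominator, the percentage of due trials left
unreported, and reporting-delay statistics over the trials that did
report.  Percentages are rounded half-up to one decimal; the total row
of a multi-sponsor audit recomputes its percentage from summed counts,
never by averaging per-sponsor percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .classifier import DUE_CATEGORIES, ClassifiedTrial, ReportingCategory
from .ingest import normalise_sponsor

__all__ = [
    "SponsorSummary",
    "AggregationError",
    "summarise_sponsor",
    "summarise_total",
    "delay_statistics",
    "percent",
]


class AggregationError(ValueError):
    """Input trials do not all belong to the stated sponsor."""


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SponsorSummary:
    """One audit-table row: category counts and compliance statistics.

    ``pct_unreported`` is 100 * DUE_UNREPORTED / n_due, absent (None)
    when the sponsor has no due trials — a sponsor without due trials
    has no compliance score, not a perfect or a zero one.  Delay
    statistics cover the trials with a measurable ``days_to_report``.
    """

    sponsor: str
    n_registered: int
    counts: dict[ReportingCategory, int]
    n_due: int
    pct_unreported: float | None
    mean_delay_days: int | None = None
    median_delay_days: int | None = None
    min_delay_days: int | None = None
    min_delay_nct_id: str | None = None
    max_delay_days: int | None = None
    max_delay_nct_id: str | None = None

    def count(self, category: ReportingCategory) -> int:
        return self.counts.get(category, 0)


def _count_categories(
    classified: Sequence[ClassifiedTrial],
) -> dict[ReportingCategory, int]:
    counts = {cat: 0 for cat in ReportingCategory}
    for ct in classified:
        counts[ct.category] += 1
    return counts


def summarise_sponsor(
    classified: Sequence[ClassifiedTrial], sponsor: str
) -> SponsorSummary:
    """Aggregate one sponsor's classified trials into a summary row.

    Every input trial must carry the given lead sponsor; a mismatch is
    an :class:`AggregationError` rather than a silent mis-count.
    Delay statistics are computed only over the *due reported* trials
    (timely or late) whose ``days_to_report`` is measurable.
    """
    expected = normalise_sponsor(sponsor)
    for ct in classified:
        if normalise_sponsor(ct.record.lead_sponsor) != expected:
            raise AggregationError(
                f"trial {ct.record.nct_id} has sponsor "
                f"{ct.record.lead_sponsor!r}, expected {sponsor!r}"
            )
    counts = _count_categories(classified)
    n_due = sum(counts[c] for c in DUE_CATEGORIES)
    pct = percent(counts[ReportingCategory.DUE_UNREPORTED], n_due) if n_due else None

    reported = [
        ct
        for ct in classified
        if ct.category
        in (ReportingCategory.DUE_REPORTED_TIMELY, ReportingCategory.DUE_REPORTED_LATE)
        and ct.days_to_report is not None
    ]
    mean = median = mn = mx = None
    mn_id = mx_id = None
    if reported:
        mean, median, _ = delay_statistics(reported)
        fastest = min(reported, key=lambda ct: ct.days_to_report)
        slowest = max(reported, key=lambda ct: ct.days_to_report)
        mn, mn_id = fastest.days_to_report, fastest.record.nct_id
        mx, mx_id = slowest.days_to_report, slowest.record.nct_id

    return SponsorSummary(
        sponsor=sponsor,
        n_registered=len(classified),
        counts=counts,
        n_due=n_due,
        pct_unreported=pct,
        mean_delay_days=mean,
        median_delay_days=median,
        min_delay_days=mn,
        min_delay_nct_id=mn_id,
        max_delay_days=mx,
        max_delay_nct_id=mx_id,
    )


def summarise_total(
    summaries: Sequence[SponsorSummary], label: str | None = None
) -> SponsorSummary:
    """Element-wise sum of sponsor summaries, percentage recomputed.

    The total percentage is recomputed from the summed counts; averaging
    the per-sponsor percentages would weight small sponsors equally with
    large ones.  A single input summary passes through unchanged (bar an
    explicit ``label``).  Extreme-delay holders are carried through;
    mean/median of the pooled delays cannot be recovered from summaries
    alone and are left absent for multi-sponsor totals (use
    :func:`delay_statistics` on the pooled trials instead).
    """
    counts = {cat: 0 for cat in ReportingCategory}
    n_registered = 0
    mn = mx = None
    mn_id = mx_id = None
    for s in summaries:
        n_registered += s.n_registered
        for cat in ReportingCategory:
            counts[cat] += s.count(cat)
        if s.min_delay_days is not None and (mn is None or s.min_delay_days < mn):
            mn, mn_id = s.min_delay_days, s.min_delay_nct_id
        if s.max_delay_days is not None and (mx is None or s.max_delay_days > mx):
            mx, mx_id = s.max_delay_days, s.max_delay_nct_id
    n_due = sum(counts[c] for c in DUE_CATEGORIES)
    pct = percent(counts[ReportingCategory.DUE_UNREPORTED], n_due) if n_due else None
    if len(summaries) == 1:
        s = summaries[0]
        return SponsorSummary(
            sponsor=label if label is not None else s.sponsor,
            n_registered=s.n_registered, counts=dict(s.counts),
            n_due=s.n_due, pct_unreported=s.pct_unreported,
            mean_delay_days=s.mean_delay_days, median_delay_days=s.median_delay_days,
            min_delay_days=s.min_delay_days, min_delay_nct_id=s.min_delay_nct_id,
            max_delay_days=s.max_delay_days, max_delay_nct_id=s.max_delay_nct_id,
        )
    return SponsorSummary(
        sponsor=label if label is not None else "Total",
        n_registered=n_registered,
        counts=counts,
        n_due=n_due,
        pct_unreported=pct,
        min_delay_days=mn,
        min_delay_nct_id=mn_id,
        max_delay_days=mx,
        max_delay_nct_id=mx_id,
    )


def delay_statistics(
    classified: Iterable[ClassifiedTrial],
) -> tuple[int | None, int | None, int]:
    """(mean, median, n) of reporting delays in days.

    Computed over every trial with a measurable ``days_to_report``.
    The mean is rounded half-up to the nearest whole day; the median is
    the lower-middle element for even n (exact order statistic, no
    interpolated half-days).  Returns (None, None, 0) when no trial has
    a measurable delay.
    """
    delays = sorted(
        ct.days_to_report for ct in classified if ct.days_to_report is not None
    )
    n = len(delays)
    if n == 0:
        return None, None, 0
    mean = int(
        (Decimal(sum(delays)) / Decimal(n)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    median = delays[(n - 1) // 2]
    return mean, median, n
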