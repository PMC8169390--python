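"""CSV report writing and the fetch → classify → summarise pipeline.

Two CSV outputs per audit run: a trial-level file (one row per
classified trial) and a sponsor-summary file (the audit table: due,
timely, late, unreported, percent unreported, plus all category
counts), together with a run-metadata text file recording the reference
date, thresholds and source.  Output bytes are stable for fixed input:
fixed column order, no timestamps in the data body.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

from . import __version__
from .classifier import ClassifiedTrial, ReportingCategory, classify_all
from .ingest import (
    filter_interventional,
    normalise_sponsor,
    parse_study,
    fetch_sponsor_records,
    read_fixture,
)
from .metrics import SponsorSummary, delay_statistics, summarise_sponsor, summarise_total
from .registry_model import ClassificationConfig, TrialRecord

logger = logging.getLogger(__name__)

__all__ = ["ReportRow", "AuditResult", "write_report", "run_audit", "rows_from_classified"]

TRIAL_COLUMNS = (
    "nct_id",
    "lead_sponsor",
    "overall_status",
    "primary_completion_date",
    "resolved_pcd",
    "results_first_posted",
    "category",
    "inconsistency",
    "days_since_pcd",
    "days_to_report",
    "days_overdue",
)

SUMMARY_COLUMNS = (
    "sponsor",
    "n_registered",
    "n_due",
    "due_reported_timely",
    "due_reported_late",
    "due_unreported",
    "pct_unreported",
    "not_due_unreported",
    "not_due_reported",
    "ongoing",
    "inconsistent",
    "no_requirement",
    "mean_delay_days",
    "median_delay_days",
    "min_delay_days",
    "min_delay_nct_id",
    "max_delay_days",
    "max_delay_nct_id",
)


@dataclass(frozen=True)
class ReportRow:
    """One trial-level output line; all values already serialised."""

    values: dict[str, str]


def _opt(v) -> str:
    return "" if v is None else str(v)


def rows_from_classified(
    classified: Sequence[ClassifiedTrial], config: ClassificationConfig
) -> list[ReportRow]:
    rows = []
    for ct in classified:
        r = ct.record
        resolved = (
            config.resolve(r.primary_completion_date).isoformat()
            if r.primary_completion_date is not None
            else ""
        )
        rows.append(
            ReportRow(
                {
                    "nct_id": r.nct_id,
                    "lead_sponsor": r.lead_sponsor,
                    "overall_status": r.overall_status.value,
                    "primary_completion_date": (
                        r.primary_completion_date.isoformat()
                        if r.primary_completion_date
                        else ""
                    ),
                    "resolved_pcd": resolved,
                    "results_first_posted": (
                        r.results_first_posted.isoformat()
                        if r.results_first_posted
                        else ""
                    ),
                    "category": ct.category.value,
                    "inconsistency": ct.inconsistency.value,
                    "days_since_pcd": _opt(ct.days_since_pcd),
                    "days_to_report": _opt(ct.days_to_report),
                    "days_overdue": _opt(ct.days_overdue),
                }
            )
        )
    return rows


def _summary_row(s: SponsorSummary) -> dict[str, str]:
    return {
        "sponsor": s.sponsor,
        "n_registered": str(s.n_registered),
        "n_due": str(s.n_due),
        "due_reported_timely": str(s.count(ReportingCategory.DUE_REPORTED_TIMELY)),
        "due_reported_late": str(s.count(ReportingCategory.DUE_REPORTED_LATE)),
        "due_unreported": str(s.count(ReportingCategory.DUE_UNREPORTED)),
        "pct_unreported": "" if s.pct_unreported is None else f"{s.pct_unreported:.1f}",
        "not_due_unreported": str(s.count(ReportingCategory.NOT_DUE_UNREPORTED)),
        "not_due_reported": str(s.count(ReportingCategory.NOT_DUE_REPORTED)),
        "ongoing": str(s.count(ReportingCategory.ONGOING)),
        "inconsistent": str(s.count(ReportingCategory.INCONSISTENT)),
        "no_requirement": str(s.count(ReportingCategory.NO_REQUIREMENT)),
        "mean_delay_days": _opt(s.mean_delay_days),
        "median_delay_days": _opt(s.median_delay_days),
        "min_delay_days": _opt(s.min_delay_days),
        "min_delay_nct_id": _opt(s.min_delay_nct_id),
        "max_delay_days": _opt(s.max_delay_days),
        "max_delay_nct_id": _opt(s.max_delay_nct_id),
    }


def write_report(
    rows: Sequence[ReportRow],
    summaries: Sequence[SponsorSummary],
    out_dir: str | Path,
    config: ClassificationConfig | None = None,
    source: str = "",
) -> tuple[Path, Path]:
    """Write the trial-level and sponsor-summary CSVs into ``out_dir``.

    Returns the two paths.  Also writes ``run_metadata.txt`` when a
    config is given (reference date, thresholds, source, tool version);
    metadata lives outside the CSV bodies so the data files stay
    byte-stable for fixed input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_path = out_dir / "trials.csv"
    summary_path = out_dir / "sponsor_summary.csv"

    with open(trials_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=TRIAL_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row.values)

    with open(summary_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SUMMARY_COLUMNS)
        writer.writeheader()
        for s in summaries:
            writer.writerow(_summary_row(s))

    if config is not None:
        meta = out_dir / "run_metadata.txt"
        meta.write_text(
            "as_of={}\nreporting_window_days={}\ngrace_days={}\n"
            "due_threshold_days={}\ndate_convention={}\nsource={}\nversion={}\n".format(
                config.as_of.isoformat(),
                config.reporting_window_days,
                config.grace_days,
                config.due_threshold_days,
                config.date_convention.value,
                source,
                __version__,
            ),
            encoding="utf-8",
        )
    return trials_path, summary_path


@dataclass(frozen=True)
class AuditResult:
    classified: list[ClassifiedTrial]
    summaries: list[SponsorSummary]  # per sponsor, plus the total row last
    trials_path: Path
    summary_path: Path


def run_audit(
    sponsors: Sequence[str],
    config: ClassificationConfig,
    out_dir: str | Path,
    source: str | Path = "live",
    fixture_format: str | None = None,
) -> AuditResult:
    """Run the full audit: ingest → filter → classify → summarise → write.

    ``source`` is either the string ``"live"`` (fetch each sponsor from
    the registry API) or a path to an offline fixture file.  Sponsor
    matching is exact on the normalised (case-folded,
    whitespace-collapsed) lead-sponsor name.  Deterministic given a
    fixture source.  A sponsor with zero matching records yields a
    zero-count summary row, not an error.
    """
    if not sponsors:
        raise ValueError("sponsor list must be non-empty")

    if str(source) == "live":
        records: list[TrialRecord] = []
        for sponsor in sponsors:
            raw = fetch_sponsor_records(sponsor)
            records.extend(parse_study(s) for s in raw)
        source_label = "live"
    else:
        records = read_fixture(source, fixture_format)
        source_label = str(source)

    interventional = filter_interventional(records)
    by_sponsor: dict[str, list[TrialRecord]] = {s: [] for s in sponsors}
    norm_to_name = {normalise_sponsor(s): s for s in sponsors}
    for r in interventional:
        key = norm_to_name.get(normalise_sponsor(r.lead_sponsor))
        if key is not None:
            by_sponsor[key].append(r)

    all_classified: list[ClassifiedTrial] = []
    summaries: list[SponsorSummary] = []
    for sponsor in sponsors:
        classified = classify_all(by_sponsor[sponsor], config)
        all_classified.extend(classified)
        summary = summarise_sponsor(classified, sponsor)
        summaries.append(summary)
        logger.info(
            "sponsor=%r fetched=%d interventional=%d classified=%d due=%d",
            sponsor,
            len(records),
            len(by_sponsor[sponsor]),
            len(classified),
            summary.n_due,
        )
    total = summarise_total(summaries, label="Total")
    mean, median, n = delay_statistics(
        [
            ct
            for ct in all_classified
            if ct.category
            in (
                ReportingCategory.DUE_REPORTED_TIMELY,
                ReportingCategory.DUE_REPORTED_LATE,
            )
        ]
    )
    total = SponsorSummary(
        sponsor=total.sponsor,
        n_registered=total.n_registered,
        counts=total.counts,
        n_due=total.n_due,
        pct_unreported=total.pct_unreported,
        mean_delay_days=mean,
        median_delay_days=median,
        min_delay_days=total.min_delay_days,
        min_delay_nct_id=total.min_delay_nct_id,
        max_delay_days=total.max_delay_days,
        max_delay_nct_id=total.max_delay_nct_id,
    )
    summaries.append(total)

    rows = rows_from_classified(all_classified, config)
    trials_path, summary_path = write_report(
        rows, summaries, out_dir, config, source=source_label
    )
    return AuditResult(all_classified, summaries, trials_path, summary_path)
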