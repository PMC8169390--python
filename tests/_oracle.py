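"""Independent brute-force rule-list oracle for the reporting taxonomy.

Written as a flat transcription of the category definitions, deliberately
not sharing code or structure with the package classifier: each category
is an independent predicate over (status, resolved completion date,
results-posted date, audit date, threshold), and the oracle asserts that
exactly one predicate fires.
"""

from datetime import date

from trialtracker import OverallStatus, ReportingCategory

FINISHED = {OverallStatus.COMPLETED, OverallStatus.TERMINATED}
EXEMPT = {OverallStatus.SUSPENDED, OverallStatus.WITHDRAWN}
ONGOING = {
    OverallStatus.NOT_YET_RECRUITING,
    OverallStatus.RECRUITING,
    OverallStatus.ENROLLING_BY_INVITATION,
    OverallStatus.ACTIVE_NOT_RECRUITING,
}


def oracle_category(
    status: OverallStatus,
    pcd: date | None,
    results: date | None,
    as_of: date,
    threshold: int = 395,
) -> ReportingCategory:
    """Return the unique category the written rules assign."""
    if results is not None and results > as_of:
        results = None  # future-dated posting is ignored at this as_of

    def due() -> bool:
        return pcd is not None and (as_of - pcd).days > threshold

    predicates = {
        ReportingCategory.NO_REQUIREMENT: status in EXEMPT,
        ReportingCategory.DUE_UNREPORTED: (
            status in FINISHED
            and results is None
            and (pcd is None or due())
        ),
        ReportingCategory.DUE_REPORTED_TIMELY: (
            status in FINISHED
            and results is not None
            and pcd is not None
            and due()
            and (results - pcd).days <= threshold
        ),
        ReportingCategory.DUE_REPORTED_LATE: (
            status in FINISHED
            and results is not None
            and (
                pcd is None  # timeliness unverifiable: conservatively late
                or (due() and (results - pcd).days > threshold)
            )
        ),
        ReportingCategory.NOT_DUE_UNREPORTED: (
            status in FINISHED and pcd is not None and not due() and results is None
        ),
        ReportingCategory.NOT_DUE_REPORTED: (
            status in FINISHED and pcd is not None and not due() and results is not None
        ),
        ReportingCategory.ONGOING: (
            status in ONGOING and pcd is not None and pcd >= as_of
        ),
        ReportingCategory.INCONSISTENT: (
            status is OverallStatus.UNKNOWN
            or (status in ONGOING and (pcd is None or pcd < as_of))
        ),
    }
    fired = [cat for cat, hit in predicates.items() if hit]
    assert len(fired) == 1, f"oracle predicates not exclusive: {fired}"
    return fired[0]
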