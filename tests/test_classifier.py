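"""Classifier correctness: oracle equivalence, boundaries, invariants."""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialtracker import (
    DUE_CATEGORIES,
    ClassificationConfig,
    InconsistencyReason,
    OverallStatus,
    PartialDate,
    ReportingCategory,
    classify,
    is_due,
)

from _oracle import oracle_category
from conftest import AS_OF, make_record


def enumerate_truth_table(as_of=AS_OF, threshold=395):
    """All status x completion-date-relation x results-relation combos."""
    pcd_choices = [
        None,
        as_of - timedelta(days=3000),
        as_of - timedelta(days=threshold + 1),  # just due
        as_of - timedelta(days=threshold),  # just not due
        as_of - timedelta(days=100),
        as_of - timedelta(days=1),
        as_of,
        as_of + timedelta(days=100),
    ]
    cases = []
    for status in OverallStatus:
        for pcd in pcd_choices:
            if pcd is None:
                results_choices = [None, as_of - timedelta(days=10)]
            else:
                results_choices = [
                    None,
                    pcd + timedelta(days=threshold),  # timely boundary
                    pcd + timedelta(days=threshold + 1),  # late boundary
                    pcd + timedelta(days=22),
                    as_of + timedelta(days=5),  # future-dated posting
                ]
            for results in results_choices:
                cases.append((status, pcd, results))
    return cases


def test_classifier_matches_brute_force_oracle(config):
    """Exhaustive truth-table equivalence with the independent rule list."""
    mismatches = []
    for status, pcd, results in enumerate_truth_table():
        record = make_record(status=status, pcd=pcd, results=results)
        got = classify(record, config).category
        want = oracle_category(status, pcd, results, config.as_of)
        if got is not want:
            mismatches.append((status, pcd, results, got, want))
    assert not mismatches, mismatches[:10]


def test_worked_example_fastest_timely_report(config):
    """A trial posting 22 days after completion is due-reported-timely."""
    record = make_record(
        nct_id="NCT01245270",  # synthetic stand-in dates for this accession
        status=OverallStatus.COMPLETED,
        pcd=PartialDate(2010, 10),
        results=date(2010, 11, 22),
    )
    ct = classify(record, config)
    assert ct.category is ReportingCategory.DUE_REPORTED_TIMELY
    assert ct.days_to_report == 22


def test_worked_example_longest_late_report(config):
    """A trial posting 5943 days after completion is due-reported-late."""
    record = make_record(
        nct_id="NCT00390949",  # synthetic stand-in dates for this accession
        status=OverallStatus.COMPLETED,
        pcd=PartialDate(2004, 1),
        results=date(2020, 5, 9),
    )
    ct = classify(record, config)
    assert ct.category is ReportingCategory.DUE_REPORTED_LATE
    assert ct.days_to_report == 5943


@pytest.mark.parametrize(
    "days_ago, results, expected",
    [
        (396, None, ReportingCategory.DUE_UNREPORTED),
        (395, None, ReportingCategory.NOT_DUE_UNREPORTED),
        (395, 395, ReportingCategory.NOT_DUE_REPORTED),
        (396, 395, ReportingCategory.DUE_REPORTED_TIMELY),
        (396, 396, ReportingCategory.DUE_REPORTED_LATE),
        (1000, 395, ReportingCategory.DUE_REPORTED_TIMELY),
        (1000, 396, ReportingCategory.DUE_REPORTED_LATE),
    ],
)
def test_due_threshold_boundaries(config, days_ago, results, expected):
    """Due-ness is strict (> 395 days ago); timely is inclusive (<= 395)."""
    pcd = config.as_of - timedelta(days=days_ago)
    results_date = pcd + timedelta(days=results) if results is not None else None
    ct = classify(make_record(pcd=pcd, results=results_date), config)
    assert ct.category is expected


def test_is_due_boundary_and_exemption(config):
    assert is_due(make_record(pcd=config.as_of - timedelta(days=396)), config)
    assert not is_due(make_record(pcd=config.as_of - timedelta(days=395)), config)
    assert not is_due(
        make_record(
            status=OverallStatus.SUSPENDED, pcd=config.as_of - timedelta(days=10000)
        ),
        config,
    )


def test_withdrawn_with_results_is_exempt_and_results_ignored(config):
    """Suspended/withdrawn trials carry no requirement; posted results are ignored."""
    record = make_record(
        status=OverallStatus.WITHDRAWN,
        pcd=config.as_of - timedelta(days=2000),
        results=config.as_of - timedelta(days=100),
    )
    ct = classify(record, config)
    assert ct.category is ReportingCategory.NO_REQUIREMENT
    assert ct.days_to_report is None


def test_finished_no_pcd_no_results_is_due_unreported(config):
    ct = classify(make_record(status=OverallStatus.TERMINATED), config)
    assert ct.category is ReportingCategory.DUE_UNREPORTED
    assert ct.days_since_pcd is None and ct.days_overdue is None


def test_finished_no_pcd_with_results_is_late_with_unverifiable_timing(config):
    ct = classify(
        make_record(
            status=OverallStatus.TERMINATED, results=config.as_of - timedelta(days=5)
        ),
        config,
    )
    assert ct.category is ReportingCategory.DUE_REPORTED_LATE
    assert ct.days_to_report is None


def test_future_dated_results_are_ignored(config):
    """A posting date after as_of is malformed and must not rescue the trial."""
    pcd = config.as_of - timedelta(days=1000)
    ct = classify(
        make_record(pcd=pcd, results=config.as_of + timedelta(days=30)), config
    )
    assert ct.category is ReportingCategory.DUE_UNREPORTED


@pytest.mark.parametrize(
    "status, pcd_offset, reason",
    [
        (OverallStatus.UNKNOWN, None, InconsistencyReason.UNKNOWN_STATUS),
        (OverallStatus.RECRUITING, -1, InconsistencyReason.ONGOING_PAST_COMPLETION),
        (OverallStatus.RECRUITING, None, InconsistencyReason.ONGOING_NO_COMPLETION_DATE),
        (OverallStatus.ACTIVE_NOT_RECRUITING, -500, InconsistencyReason.ONGOING_PAST_COMPLETION),
    ],
)
def test_inconsistent_records(config, status, pcd_offset, reason):
    pcd = config.as_of + timedelta(days=pcd_offset) if pcd_offset is not None else None
    ct = classify(make_record(status=status, pcd=pcd), config)
    assert ct.category is ReportingCategory.INCONSISTENT
    assert ct.inconsistency is reason


def test_ongoing_with_future_pcd(config):
    ct = classify(
        make_record(
            status=OverallStatus.RECRUITING, pcd=config.as_of + timedelta(days=200)
        ),
        config,
    )
    assert ct.category is ReportingCategory.ONGOING
    assert ct.inconsistency is InconsistencyReason.NONE


def test_overdue_days(config):
    pcd = config.as_of - timedelta(days=1000)
    ct = classify(make_record(pcd=pcd), config)
    assert ct.category is ReportingCategory.DUE_UNREPORTED
    assert ct.days_since_pcd == 1000
    assert ct.days_overdue == 605


# --- property-based invariants ------------------------------------------

record_strategy = st.builds(
    make_record,
    status=st.sampled_from(OverallStatus),
    pcd=st.one_of(
        st.none(),
        st.dates(date(2000, 1, 1), date(2025, 12, 31)),
        st.builds(PartialDate, year=st.integers(2000, 2025)),
        st.builds(
            PartialDate, year=st.integers(2000, 2025), month=st.integers(1, 12)
        ),
    ),
    results=st.one_of(st.none(), st.dates(date(2000, 1, 1), date(2025, 12, 31))),
)


@given(record=record_strategy)
@settings(max_examples=300, derandomize=True)
def test_partition_every_record_gets_exactly_one_category(record):
    """Exhaustiveness: every well-formed record classifies, without error."""
    cfg = ClassificationConfig(as_of=AS_OF)
    ct = classify(record, cfg)
    assert isinstance(ct.category, ReportingCategory)
    assert (ct.inconsistency is InconsistencyReason.NONE) == (
        ct.category is not ReportingCategory.INCONSISTENT
    )
    if ct.category is ReportingCategory.DUE_REPORTED_TIMELY:
        assert ct.days_to_report <= cfg.due_threshold_days
    if ct.category is ReportingCategory.DUE_REPORTED_LATE and ct.days_to_report is not None:
        assert ct.days_to_report > cfg.due_threshold_days


@given(record=record_strategy, advance=st.integers(0, 4000))
@settings(max_examples=200, derandomize=True)
def test_monotonic_in_as_of(record, advance):
    """An unreported finished trial never reverts from due to not-due."""
    early = ClassificationConfig(as_of=AS_OF)
    late = ClassificationConfig(as_of=AS_OF + timedelta(days=advance))
    if record.results_first_posted is not None:
        return
    before = classify(record, early).category
    after = classify(record, late).category
    if before is ReportingCategory.DUE_UNREPORTED:
        assert after is ReportingCategory.DUE_UNREPORTED


@given(
    pcd=st.dates(date(2000, 1, 1), date(2018, 12, 31)),
    delay=st.integers(1, 3000),
    extra=st.integers(1, 2000),
)
@settings(max_examples=200, derandomize=True)
def test_monotonic_in_results_date(pcd, delay, extra):
    """Delaying the posting date never turns a late report timely."""
    cfg = ClassificationConfig(as_of=AS_OF)
    r1 = make_record(pcd=pcd, results=pcd + timedelta(days=delay))
    r2 = make_record(pcd=pcd, results=pcd + timedelta(days=delay + extra))
    c1 = classify(r1, cfg).category
    c2 = classify(r2, cfg).category
    if c1 is ReportingCategory.DUE_REPORTED_LATE:
        assert c2 is not ReportingCategory.DUE_REPORTED_TIMELY


@given(record=record_strategy)
@settings(max_examples=200, derandomize=True)
def test_grace_period_identity(record):
    """window=365 + grace=30 classifies identically to window=395 + grace=0."""
    a = ClassificationConfig(as_of=AS_OF, reporting_window_days=365, grace_days=30)
    b = ClassificationConfig(as_of=AS_OF, reporting_window_days=395, grace_days=0)
    ca, cb = classify(record, a), classify(record, b)
    assert ca.category is cb.category
    assert ca.days_to_report == cb.days_to_report
    assert ca.days_overdue == cb.days_overdue


@given(record=record_strategy)
@settings(max_examples=200, derandomize=True)
def test_is_due_consistent_with_classify(record):
    cfg = ClassificationConfig(as_of=AS_OF)
    assert is_due(record, cfg) == (classify(record, cfg).category in DUE_CATEGORIES)
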