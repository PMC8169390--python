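# Methods

## What the tracker measures

`trialtracker` audits a lead sponsor's interventional trials on
ClinicalTrials.gov for adherence to the WHO best-practice disclosure
window: summary results (structured outcome/adverse-event tables on the
registry record itself, distinct from journal publication) should be
posted within 12 months of the trial's primary completion date (PCD).
The unit of analysis is the registry record; the unit of aggregation is
the lead sponsor. Collaborator entries are ignored. Legal compliance
determination under FDAAA 2007 (applicable-clinical-trial status,
responsible parties, certificates of delay, fines) is out of scope.

## The due-date model

All timing arithmetic is exact signed calendar-day counting between
civil dates; "12 months" is operationalised exclusively through the
constant

```
due_threshold_days = reporting_window_days + grace_days = 365 + 30 = 395
```

with no month arithmetic anywhere. The 30-day grace term absorbs the
registry's quality-control interval between a sponsor's results
submission and public posting: the only posting date visible in
registry records is `results_first_posted`, so both due-ness and
timeliness are measured against it, and the grace period compensates
for the unobservable submission-to-posting lag.

Boundary semantics are frozen by complementarity: a trial is *due* when
`as_of − PCD > 395` (strict), and a posted result is *timely* when
`results_first_posted − PCD ≤ 395` (inclusive). A trial completed
exactly 395 days ago is therefore not yet due, and a result posted
exactly 395 days after completion is timely.

`reporting_window_days` must be strictly positive; `grace_days` may be
zero, so that the identity "window 365 + grace 30 ≡ window 395 + grace
0" is expressible and is enforced as a property test.

## Partial-precision dates

Registry completion dates, especially pre-2017 registrations, often
carry only month ("June 2014") or year precision. The package stores
these losslessly (`PartialDate`) and resolves them deterministically at
classification time under a configurable convention:

* `LAST_DAY` (default): latest consistent day — 2014-06 → 2014-06-30,
  2014 → 2014-12-31. Chosen as default because it postpones due-ness,
  giving sponsors the benefit of the doubt in what is ultimately an
  accusation of non-reporting.
* `FIRST_DAY`: earliest consistent day.
* `MID_MONTH`: day 15, or July 1 for year-only precision.

Resolution is idempotent on complete dates and ordered
(`FIRST_DAY ≤ MID_MONTH ≤ LAST_DAY`) for every partial date.
Results-posted dates are always day-precise in the registry and are
required to be so here.

## The classification tree

Rules are evaluated in fixed order; every well-formed record receives
exactly one category (exhaustiveness is property-tested, and the whole
tree is checked against an independently written brute-force rule list
over the exhaustive status × date-relation × results-relation truth
table):

1. Suspended/Withdrawn → `NO_REQUIREMENT`, unconditionally; missing
   dates or even posted results never move such a trial elsewhere (the
   results are ignored).
2. Completed/Terminated:
   - no PCD and no results → `DUE_UNREPORTED` (a finished trial without
     a completion date cannot demonstrate timeliness);
   - no PCD but results posted → `DUE_REPORTED_LATE` with the timing
     fields absent. This configuration is not covered by the category
     definitions above; the package's documented extension is to treat
     the results as real but their timeliness as unverifiable, hence
     conservatively late, with a warning logged.
   - PCD more than 395 days ago → due: `DUE_UNREPORTED`,
     `DUE_REPORTED_TIMELY` (delay ≤ 395) or `DUE_REPORTED_LATE`;
   - otherwise → `NOT_DUE_UNREPORTED` / `NOT_DUE_REPORTED`.
3. Unknown status → `INCONSISTENT` (reason `UNKNOWN_STATUS`).
4. Ongoing family (not-yet-recruiting, recruiting,
   enrolling-by-invitation, active-not-recruiting): no PCD →
   `INCONSISTENT` (`ONGOING_NO_COMPLETION_DATE`); PCD strictly before
   `as_of` → `INCONSISTENT` (`ONGOING_PAST_COMPLETION`); else
   `ONGOING`.

A `results_first_posted` after `as_of` is treated as malformed: the
results are ignored at that reference date, with a warning. Status
vocabulary is normalised case-insensitively with punctuation tolerated;
unrecognised strings degrade to `UNKNOWN` (hence the inconsistent
bucket) rather than crashing an audit.

Whether enrolling-by-invitation and not-yet-recruiting belong to the
ongoing family is a design choice here (both do): they are registry
statuses of trials that have not finished, and the inconsistency rules
apply to them identically.

## Aggregation

Per sponsor: exact integer category counts;
`n_due = DUE_UNREPORTED + DUE_REPORTED_LATE + DUE_REPORTED_TIMELY`;
`pct_unreported = 100 · DUE_UNREPORTED / n_due`, rounded **half-up** to
one decimal (this convention reproduces every arithmetically checkable
row of the October 2020 UK-university audit table: 137/224 → 61.2,
216/234 → 92.3, 1468/1634 → 89.8). A sponsor with no due trials gets an
absent percentage, not 0 or 100 — no compliance score is fabricated.
Totals over sponsors are element-wise count sums with the percentage
recomputed from the summed counts, never averaged over sponsors.

Delay statistics cover trials with a measurable `days_to_report`
(due-reported trials in sponsor summaries): mean rounded half-up to
whole days; median defined as the lower-middle order statistic for even
n (no interpolated half-days; the choice is documented because only one
convention can be frozen). Extreme delays are reported with their NCT
IDs.

`INCONSISTENT` is a category disjoint from the due trials. Because the
published cohort-level inconsistency figure is expressed as a
percentage of the *due* denominator (687/1634 = 42.0%), the acceptance
script additionally reports `pct_inconsistent_of_due` so that figure is
reproducible as arithmetic.

## The synthetic registry generator

`generate_registry(SimulationParams)` emulates a sponsor cohort:

* `status_mix` — per-status probabilities (default: 56% finished, 28%
  ongoing family, 10% unknown, 6% suspended/withdrawn), validated to
  sum to 1 within 1e-9.
* `p_report_given_due = 0.10` — roughly one due academic trial in ten
  has tabular registry results, matching the order of magnitude of
  observed academic-sponsor compliance.
* Reporting delays are log-normal with `delay_log_mu = 6.59`,
  `delay_log_sigma = 0.772` (log-days), i.e. median ≈ 728 days and
  analytic mean ≈ 981 days: positive, heavily right-skewed, mean well
  above median, as real academic reporting delays are. Delays are
  clamped to keep the posting on or before `as_of`, so the realised
  mean in a finite cohort sits below the analytic mean.
* `p_month_precision = 0.50` — half the completion dates lack day
  precision, as in pre-2017 registrations. Month-precision dates are
  placed at their month's end so that `LAST_DAY` resolution is lossless
  and every generated record's intended category is unambiguous.
* `p_ongoing_past_pcd = 0.25`, `p_ongoing_missing_pcd = 0.10` — the
  fractions of ongoing-family records that are internally inconsistent.

Each record is emitted together with the category its construction
implies (ground truth bookkept by the generator itself, never by
calling the classifier), enabling genuine recovery tests. The generator
never emits the ambiguous configurations (future-dated results,
finished-with-results-but-no-PCD); those are pinned by dedicated
hand-built fixtures.

What the generator does **not** emulate: sponsor-name noise and
collaborator structure, observational studies mixed into the fetch
result, registry field corruption, within-sponsor heterogeneity of
reporting culture, and any correlation between trial age and reporting
probability. Passing recovery tests therefore demonstrate correctness
of the classification and aggregation logic, not robustness to dirty
real-world records (the parsing layer's tolerance is tested
separately).

## Ingest

The live fetcher targets the current public JSON API
(`/api/v2/studies`), querying the lead-sponsor search field and
following `nextPageToken` pagination to exhaustion, with bounded
exponential-backoff retries per page; a page that still fails raises,
so a mid-pagination failure can never silently truncate a cohort. Exact
post-filtering uses the normalised (case-folded, whitespace-collapsed)
lead-sponsor name. It is built on the standard library's HTTP client
and exercised in tests only against a local mock server; offline NDJSON
and CSV fixtures are the first-class test path. Fixture dates are
ISO-8601 with truncation for partial precision; empty string means
absent, and parsing never invents a date.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely offline at desk
scale: the truth-table oracle comparison enumerates 333 combinations;
property tests draw a few hundred derandomised examples each; the
recovery and proportion checks use seeded cohorts of 5000 trials; the
delay-distribution check uses 10,000 draws against the log-normal's
closed-form moments (3-standard-error band, plus 1 day for the integer
floor). Statistical assertions on stochastic quantities use exact
binomial 99% intervals or a chi-square goodness-of-fit at the 0.1%
level on the full status multinomial. The cohort-level mean/median
delay of a live October 2020 snapshot is snapshot-dependent and is not
asserted anywhere; the acceptance script reports the synthetic cohort's
delay statistics as computed.

## Known limitations

* Month-precision resolution conventions other than `LAST_DAY` are
  provided but the audit defaults to the sponsor-favourable choice; an
  audit wanting worst-case due-ness should pass `FIRST_DAY` explicitly.
* Only the lead sponsor is audited; trials where an audited institution
  is a collaborator are invisible.
* The submission date of results is not modelled; a sponsor who
  submitted within 12 months but whose posting was delayed more than 30
  days by registry review is counted late.
* Cross-registry reporting (EU CTR, ISRCTN, journal publication) does
  not count as reported here: the measure is registry-record
  completeness on ClinicalTrials.gov itself.
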