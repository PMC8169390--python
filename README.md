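# trialtracker

Audit the results-reporting compliance of clinical trial sponsors on
ClinicalTrials.gov against WHO best practice.

## The problem

The WHO considers 12 months after primary completion "the longest
possible acceptable timeframe" for posting a trial's summary results on
the registry where it was registered. Most interventional trials
registered on ClinicalTrials.gov by non-commercial sponsors carry no
legal reporting obligation (FDAAA 2007 covers only a small subset), so
adherence to this best practice must be measured directly from registry
records. `trialtracker` does that: it classifies every interventional
trial of a lead sponsor into a mutually exclusive reporting taxonomy,
computes reporting delays, and produces per-sponsor audit tables.

## The classification

A trial is **due** when its resolved primary completion date (PCD) lies
strictly more than *T* = 365 + 30 = 395 days before the audit reference
date: the 365-day WHO window plus a 30-day grace period for the
registry's quality-control review between submission and posting.
Every record receives exactly one category:

| category | rule |
|---|---|
| `NO_REQUIREMENT` | status Suspended or Withdrawn (posted results, if any, are ignored) |
| `DUE_UNREPORTED` | finished (Completed/Terminated), no results, PCD > *T* days ago — or no PCD at all |
| `DUE_REPORTED_TIMELY` | finished, due, results posted ≤ *T* days after PCD |
| `DUE_REPORTED_LATE` | finished, due, results posted > *T* days after PCD |
| `NOT_DUE_UNREPORTED` / `NOT_DUE_REPORTED` | finished ≤ *T* days ago |
| `ONGOING` | recruiting-family status with PCD not in the past |
| `INCONSISTENT` | unknown status; ongoing with PCD in the past; ongoing without a PCD |

Per sponsor, the headline statistic is
`pct_unreported = 100 · DUE_UNREPORTED / (DUE_UNREPORTED + DUE_REPORTED_LATE + DUE_REPORTED_TIMELY)`,
rounded half-up to one decimal, alongside mean/median reporting delay
(days from PCD to results posting) over the due trials that reported.

All arithmetic is exact calendar-day counting; partial-precision
registry dates ("June 2014") resolve to the last consistent day by
default, which postpones due-ness and so gives sponsors the benefit of
the doubt.

## Worked example

Generate a seeded synthetic registry, then audit it:

```bash
trialtracker simulate --n 300 --seed 3 --out cohort.ndjson \
    --sponsors "Uni One,Uni Two"
printf "Uni One\nUni Two\n" > sponsors.txt
trialtracker audit --sponsors sponsors.txt --source cohort.ndjson \
    --as-of 2020-10-19 --out audit_out
```

which prints

```
wrote 300 synthetic records to cohort.ndjson
audited 2 sponsors, 300 interventional trials, 154 due, 91.6% of due unreported -> audit_out/sponsor_summary.csv
```

i.e. of the 300 synthetic interventional trials, 154 had a primary
completion date more than 395 days before 2020-10-19, and 91.6% of
those had no posted results — the per-sponsor breakdown, the trial-level
classifications and the run metadata are in `audit_out/`. The same
pipeline runs against the live registry with `--source live`, and the
classification thresholds (`--reporting-window`, `--grace`,
`--date-convention`) and reference date (`--as-of`) are all settable.

From Python:

```python
from datetime import date
from trialtracker import ClassificationConfig, PartialDate, classify
from trialtracker.registry_model import OverallStatus, StudyType, TrialRecord

cfg = ClassificationConfig(as_of=date(2020, 10, 19))
trial = TrialRecord("NCT00000001", "Some University", StudyType.INTERVENTIONAL,
                    OverallStatus.COMPLETED,
                    primary_completion_date=PartialDate(2014, 6),
                    results_first_posted=date(2014, 7, 22))
ct = classify(trial, cfg)
print(ct.category.value, ct.days_to_report)   # DUE_REPORTED_TIMELY 22
```

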