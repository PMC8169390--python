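"""Obtain trial records from the registry API or from offline fixtures.

Two sources are supported and produce identical :class:`TrialRecord`
sequences: the public ClinicalTrials.gov JSON API (v2 study shape,
paginated), and flat offline fixture files (NDJSON or CSV) that every
downstream module is tested against without network access.

Fixture dialect: UTF-8, keys/columns ``nct_id``, ``lead_sponsor``,
``study_type``, ``overall_status``, ``primary_completion_date``,
``results_first_posted``; dates are ISO-8601 with truncation for partial
precision ('2014', '2014-06', '2014-06-30'); empty string means absent.
"""

from __future__ import annotations

import csv
import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from datetime import date
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Sequence

from .registry_model import (
    MalformedDateError,
    OverallStatus,
    PartialDate,
    StudyType,
    TrialRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ENDPOINT",
    "RejectedRecordError",
    "FetchError",
    "FixtureFormatError",
    "parse_study",
    "fetch_sponsor_records",
    "filter_interventional",
    "read_fixture",
    "write_fixture",
    "read_sponsor_list",
    "normalise_sponsor",
]

DEFAULT_ENDPOINT = "https://clinicaltrials.gov/api/v2/studies"

FIXTURE_FIELDS = (
    "nct_id",
    "lead_sponsor",
    "study_type",
    "overall_status",
    "primary_completion_date",
    "results_first_posted",
)


class RejectedRecordError(ValueError):
    """A raw study lacks the minimum identification (an NCT ID)."""


class FetchError(RuntimeError):
    """The registry API could not be fetched after bounded retries."""


class FixtureFormatError(ValueError):
    """An offline fixture file is malformed; the message names the line."""


def _get(tree: Mapping[str, Any], *path: str) -> Any:
    cur: Any = tree
    for key in path:
        if not isinstance(cur, Mapping) or key not in cur:
            return None
        cur = cur[key]
    return cur


def parse_study(raw: Mapping[str, Any]) -> TrialRecord:
    """Extract a :class:`TrialRecord` from a raw study tree.

    Accepts both the nested API v2 study shape (``protocolSection...``)
    and the flat fixture shape.  Absent fields stay absent — no sentinel
    strings, and no invented dates.

    Raises
    ------
    RejectedRecordError
        if no NCT ID can be found.
    MalformedDateError
        if a date field is present but unparseable; the message carries
        the NCT ID.
    """
    flat = "nct_id" in raw
    if flat:
        nct_id = raw.get("nct_id")
        sponsor = raw.get("lead_sponsor") or ""
        type_text = raw.get("study_type") or ""
        status_text = raw.get("overall_status") or ""
        pcd_text = raw.get("primary_completion_date") or None
        posted_text = raw.get("results_first_posted") or None
    else:
        nct_id = _get(raw, "protocolSection", "identificationModule", "nctId")
        sponsor = (
            _get(
                raw,
                "protocolSection",
                "sponsorCollaboratorsModule",
                "leadSponsor",
                "name",
            )
            or ""
        )
        type_text = _get(raw, "protocolSection", "designModule", "studyType") or ""
        status_text = (
            _get(raw, "protocolSection", "statusModule", "overallStatus") or ""
        )
        pcd_text = _get(
            raw,
            "protocolSection",
            "statusModule",
            "primaryCompletionDateStruct",
            "date",
        )
        posted_text = _get(
            raw,
            "protocolSection",
            "statusModule",
            "resultsFirstPostDateStruct",
            "date",
        )

    if not nct_id:
        raise RejectedRecordError(f"raw study has no NCT ID: {dict(raw)!r:.200}")

    try:
        pcd = PartialDate.parse(pcd_text) if pcd_text else None
    except MalformedDateError as e:
        raise MalformedDateError(f"{nct_id}: primary completion date: {e}") from e
    try:
        posted = None
        if posted_text:
            pp = PartialDate.parse(posted_text)
            if not pp.is_complete:
                raise MalformedDateError("results-posted date lacks day precision")
            posted = date(pp.year, pp.month, pp.day)
    except MalformedDateError as e:
        raise MalformedDateError(f"{nct_id}: results first posted: {e}") from e

    return TrialRecord(
        nct_id=nct_id,
        lead_sponsor=sponsor,
        study_type=StudyType.parse(type_text),
        overall_status=OverallStatus.parse(status_text),
        primary_completion_date=pcd,
        results_first_posted=posted,
    )


def normalise_sponsor(name: str) -> str:
    """Case-folded, whitespace-collapsed sponsor name for exact matching."""
    return " ".join(name.split()).casefold()


def fetch_sponsor_records(
    sponsor: str,
    page_size: int = 100,
    endpoint: str = DEFAULT_ENDPOINT,
    max_retries: int = 3,
    backoff_seconds: float = 1.0,
) -> list[dict[str, Any]]:
    """Fetch every raw study whose lead sponsor matches ``sponsor``.

    Follows pagination to exhaustion; transient failures on each page are
    retried up to ``max_retries`` times with exponential backoff.  A page
    that still fails raises :class:`FetchError` — a mid-pagination
    failure never yields a silently truncated result.  The sponsor query
    uses the registry's lead-sponsor search field; exact post-filtering
    on the normalised name is done by the caller (see ``run_audit``).
    """
    if not sponsor.strip():
        raise ValueError("sponsor name must be non-empty")
    studies: list[dict[str, Any]] = []
    page_token: str | None = None
    page_no = 0
    while True:
        page_no += 1
        params = {
            "query.lead": sponsor,
            "pageSize": str(page_size),
            "format": "json",
        }
        if page_token:
            params["pageToken"] = page_token
        url = f"{endpoint}?{urllib.parse.urlencode(params)}"
        payload = _fetch_page(url, sponsor, page_no, max_retries, backoff_seconds)
        studies.extend(payload.get("studies", []))
        page_token = payload.get("nextPageToken")
        if not page_token:
            break
    logger.info("fetched %d studies for sponsor %r", len(studies), sponsor)
    return studies


def _fetch_page(
    url: str, sponsor: str, page_no: int, max_retries: int, backoff_seconds: float
) -> dict[str, Any]:
    last_error: Exception | None = None
    for attempt in range(max_retries):
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as e:
            last_error = e
            if attempt + 1 < max_retries:
                time.sleep(backoff_seconds * 2**attempt)
    raise FetchError(
        f"failed to fetch page {page_no} for sponsor {sponsor!r}: {last_error}"
    ) from last_error


def filter_interventional(records: Iterable[TrialRecord]) -> list[TrialRecord]:
    """Keep exactly the interventional records, preserving order."""
    return [r for r in records if r.study_type is StudyType.INTERVENTIONAL]


def _record_to_row(r: TrialRecord) -> dict[str, str]:
    return {
        "nct_id": r.nct_id,
        "lead_sponsor": r.lead_sponsor,
        "study_type": r.study_type.value,
        "overall_status": r.overall_status.value,
        "primary_completion_date": (
            r.primary_completion_date.isoformat() if r.primary_completion_date else ""
        ),
        "results_first_posted": (
            r.results_first_posted.isoformat() if r.results_first_posted else ""
        ),
    }


def read_fixture(path: str | Path, format: str | None = None) -> list[TrialRecord]:
    """Read trial records from an NDJSON or CSV fixture file.

    ``format`` is 'ndjson' or 'csv'; inferred from the file suffix when
    omitted.  Round-trips with :func:`write_fixture` field-for-field,
    including partial-date precision.  Malformed rows raise
    :class:`FixtureFormatError` naming the line number.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("ndjson", "jsonl", "json"):
        return _read_ndjson(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FixtureFormatError(f"unknown fixture format {fmt!r} for {path}")


def _read_ndjson(path: Path) -> list[TrialRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as e:
                raise FixtureFormatError(f"{path}:{lineno}: invalid JSON: {e}") from e
            try:
                records.append(parse_study(raw))
            except (RejectedRecordError, MalformedDateError, ValueError) as e:
                raise FixtureFormatError(f"{path}:{lineno}: {e}") from e
    return records


def _read_csv(path: Path) -> list[TrialRecord]:
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):  # line 1 is the header
            try:
                records.append(parse_study(row))
            except (RejectedRecordError, MalformedDateError, ValueError) as e:
                raise FixtureFormatError(f"{path}:{lineno}: {e}") from e
    return records


def write_fixture(
    records: Sequence[TrialRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records to an NDJSON or CSV fixture file (see module docs)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("ndjson", "jsonl", "json"):
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(_record_to_row(r)) + "\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=FIXTURE_FIELDS)
            writer.writeheader()
            for r in records:
                writer.writerow(_record_to_row(r))
    else:
        raise FixtureFormatError(f"unknown fixture format {fmt!r} for {path}")


def read_sponsor_list(path: str | Path) -> list[str]:
    """Read a plain-text sponsor list, one name per line; '#' comments."""
    names = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                names.append(name)
    return names
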