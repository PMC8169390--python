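from datetime import date

import pytest

from trialtracker import (
    ClassificationConfig,
    OverallStatus,
    PartialDate,
    StudyType,
    TrialRecord,
)

AS_OF = date(2020, 10, 19)


@pytest.fixture
def config() -> ClassificationConfig:
    return ClassificationConfig(as_of=AS_OF)


def make_record(
    status=OverallStatus.COMPLETED,
    pcd=None,
    results=None,
    nct_id="NCT00000001",
    sponsor="University of Synthetica",
    study_type=StudyType.INTERVENTIONAL,
) -> TrialRecord:
    if isinstance(pcd, date):
        pcd = PartialDate.from_date(pcd)
    return TrialRecord(
        nct_id=nct_id,
        lead_sponsor=sponsor,
        study_type=study_type,
        overall_status=status,
        primary_completion_date=pcd,
        results_first_posted=results,
    )
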