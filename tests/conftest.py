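"""Shared fixtures: reference tables, tiny report builders, listing files."""
from __future__ import annotations

import pytest

from pvsignal import (
    AgeGroup,
    ATCCatalogue,
    CaseReport,
    Dialect,
    DrugExposure,
    MedDRAMap,
    Outcome,
    ReactionRecord,
    Region,
    Reporter,
    Seriousness,
    Sex,
)


@pytest.fixture(scope="session")
def catalogue() -> ATCCatalogue:
    return ATCCatalogue.load_default()


@pytest.fixture(scope="session")
def demo_map() -> MedDRAMap:
    return MedDRAMap.load_demo()


@pytest.fixture
def dialect() -> Dialect:
    return Dialect()


def make_report(report_id="R1", year=2015, sex=Sex.FEMALE,
                age_group=AgeGroup.A18_64, reporter=Reporter.HEALTHCARE_PROFESSIONAL,
                region=Region.EEA, drugs=("Phenobarbital",), reactions=None):
    if reactions is None:
        reactions = [ReactionRecord(pt="Seizure")]
    return CaseReport(
        report_id=report_id, receipt_year=year, sex=sex, age_group=age_group,
        reporter=reporter, region=region,
        drugs=[DrugExposure(substance=d) for d in drugs],
        reactions=list(reactions),
    )


@pytest.fixture
def report_factory():
    return make_report


LISTING_3ROWS = """\
report_id,receipt_date,sex,age_group,reporter_qualification,region,suspect_drugs,reaction_list
R1,2015-03-02,Female,18-64,Healthcare Professional,EEA,Phenobarbital,Seizure (n/a – Recovered/Resolved – Caused/Prolonged Hospitalisation)
R2,2016-07-15,Male,3-17,Non Healthcare Professional,Non EEA,Carbamazepine; Levetiracetam,"Rash (2d – Fatal – Results in Death; Life Threatening),
Dizziness (n/a – Recovering/Resolving – Not Specified/Unknown)"
R3,2018-01-01,Not Specified,>64,Healthcare Professional,EEA,Pregabalin,Somnolence (n/a – Unknown – Other Medically Important Condition)
"""


@pytest.fixture
def listing_path(tmp_path):
    path = tmp_path / "listing.csv"
    path.write_text(LISTING_3ROWS, encoding="utf-8")
    return path
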