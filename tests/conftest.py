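import numpy as np
import pytest

from otobayes import (
    HistoricalStudy,
    PriorConfig,
    SurveyDataset,
    Respondent,
    complete_case_filter,
    paper_margins_dataset,
)


@pytest.fixture(scope="session")
def prior() -> PriorConfig:
    return PriorConfig()


@pytest.fixture(scope="session")
def two_studies() -> list[HistoricalStudy]:
    """Hand-checkable pair: numerators 1·100·0.16 = 16 and 6·200·0.24 = 288."""
    return [
        HistoricalStudy("A", 2014, 100, 0.2),
        HistoricalStudy("B", 2019, 200, 0.6),
    ]


@pytest.fixture(scope="session")
def margins_dataset() -> SurveyDataset:
    return paper_margins_dataset(seed=1)


@pytest.fixture(scope="session")
def complete_margins(margins_dataset) -> SurveyDataset:
    return complete_case_filter(margins_dataset)


def make_respondent(i: int = 0, **overrides) -> Respondent:
    base = dict(
        respondent_id=f"T{i:03d}",
        province="ON",
        age_group="le40",
        role="staff",
        setting="academic",
        subspecialty="general",
        annual_volume_group="gt50",
        technique="extracapsular_monopolar",
        opioid_sparing=1,
    )
    base.update(overrides)
    return Respondent(**base)


@pytest.fixture
def tiny_dataset() -> SurveyDataset:
    """6 respondents over 2 provinces, one field missing for the last."""
    rows = [
        make_respondent(0, province="ON", opioid_sparing=1),
        make_respondent(1, province="ON", opioid_sparing=0, age_group="gt40"),
        make_respondent(2, province="QC", opioid_sparing=1, subspecialty="pediatric"),
        make_respondent(3, province="QC", opioid_sparing=1, setting="community"),
        make_respondent(4, province="ON", opioid_sparing=0, technique="cold_steel"),
        make_respondent(5, province="QC", opioid_sparing=None),
    ]
    return SurveyDataset(rows)
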