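import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import pvsignal as pv
from pvsignal.pipeline import default_event_vocab

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def event_vocab():
    return default_event_vocab()


@pytest.fixture(scope="session")
def small_config(event_vocab):
    """10k reports, one planted montelukast-nightmare signal."""
    return pv.GeneratorConfig(
        n_reports=10000,
        drug_vocab=("MONTELUKAST", "ASPIRIN", "IBUPROFEN", "OMEPRAZOLE", "METFORMIN"),
        event_vocab=event_vocab,
        baseline_event_prob=0.02,
        planted_signals=(("MONTELUKAST", "Nightmare", 4.0),),
        drug_exposure_prob=0.3,
        seed=20240701,
    )


@pytest.fixture(scope="session")
def small_reports(small_config):
    return pv.generate_reports(small_config)


def make_report(
    case_id="1",
    drugs=(("MONTELUKAST", "PS"),),
    events=(("Nightmare", "Psychiatric disorders"),),
    sex="male",
    age_group="<18",
    country="US",
    reporter="consumer",
    year=2013,
    outcomes=(),
    version=1,
):
    return pv.SpontaneousReport(
        case_id=case_id,
        case_version=version,
        receipt_year=year,
        sex=sex,
        age_group=age_group,
        country=country,
        reporter=reporter,
        drugs=tuple(drugs),
        events=tuple(events),
        serious_outcomes=tuple(outcomes),
    )


def make_raw(
    case_id="1",
    version=1,
    date=dt.date(2013, 6, 1),
    drugs=(("MONTELUKAST", "PS"),),
    events=("Nightmare",),
    outcomes=(),
    **kw,
):
    return pv.RawCaseRecord(
        case_id=case_id,
        case_version=version,
        receipt_date=date,
        sex=kw.get("sex", "male"),
        age=kw.get("age", 10),
        country=kw.get("country", "US"),
        reporter=kw.get("reporter", "consumer"),
        drug_entries=tuple(drugs),
        event_entries=tuple(events),
        outcome_codes=tuple(outcomes),
    )
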