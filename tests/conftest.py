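import pytest

from srsafety.frames import reports_to_frame
from srsafety.srs_data import AdrReport
from srsafety.synthetic_srs import reference_fixture

_DEFAULTS = dict(
    report_id="R1",
    year=2019,
    age=55,
    sex="female",
    causality="probable",
    drug_name="Cisplatin",
    atc_class="L01",
    drug_class="non_mab",
    mab_type="none",
    patent_status="none",
    adr_term="Nausea",
    soc="Gastrointestinal disorders",
    onset_days=2,
    severity="non_serious",
    impact="no_effect",
    n_diseases=1,
    n_medications=2,
    past_adr_history=False,
    outcome_death=False,
)


def make_report(**overrides) -> AdrReport:
    """A valid retained-grade report with field overrides."""
    return AdrReport(**{**_DEFAULTS, **overrides})


@pytest.fixture
def mk():
    return make_report


@pytest.fixture(scope="session")
def fixture_reports():
    return reference_fixture()


@pytest.fixture(scope="session")
def fixture_frame(fixture_reports):
    return reports_to_frame(fixture_reports)
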