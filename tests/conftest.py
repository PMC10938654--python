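import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from kampovig import formulary as fm
from kampovig import jader_io as io
from kampovig.synthetic import DrugSpec, SimConfig, generate_tables

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory):
    """A small synthetic four-table dataset with duplicates and missingness."""
    cfg = SimConfig(n_reports=2000, seed=11, duplicate_rate=0.1)
    return generate_tables(cfg, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def bundle(sim_paths):
    return io.read_tables(
        sim_paths["demo"], sim_paths["drug"], sim_paths["reac"], sim_paths["hist"]
    )


@pytest.fixture(scope="session")
def reports(bundle):
    return io.filter_suspected(io.integrate_reports(bundle))


@pytest.fixture(scope="session")
def registry():
    return fm.example_formulary()


@pytest.fixture
def make_report():
    """Factory for hand-built integrated reports."""

    def build(case_id="X1", drugs=(), events=(), sex="male", age="60s",
              year=2015, history=()):
        return io.AEReport(
            case_id=case_id,
            sex=sex,
            age_decade=age,
            reporting_year=year,
            drugs=[
                io.DrugUse(name=n, role=role, daily_dose_g=dose, start_date=start)
                for (n, role, dose, start) in drugs
            ],
            events=[
                io.EventOccurrence(pt_code=c, pt_name=n, onset_date=o)
                for (c, n, o) in events
            ],
            history=list(history),
        )

    return build


@pytest.fixture
def dild_event():
    return ("10022611", "interstitial lung disease", dt.date(2020, 2, 5))
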