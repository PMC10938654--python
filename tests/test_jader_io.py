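"""Table parsing, integration, cleaning and event flagging."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kampovig import jader_io as io


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.fixture
def tiny_tables(tmp_path):
    demo = _write(
        tmp_path, "demo.csv",
        "case_id,sex,age,reporting_year\n"
        "A,female,60s,2015\n"
        "B,unknown,aged,2016\n"
        "A,male,70s,2015\n",  # later version of case A supersedes the first
    )
    drug = _write(
        tmp_path, "drug.csv",
        "case_id,drug_name,role_code,daily_dose_g,start_date\n"
        "A,Saireito,suspected,2.5g,2020-01-01\n"
        "A,rebamipide,concomitant,,2020-01\n"
        "B,Yokukansan,suspected,7.5,2020-03-05\n"
        "Z,ghost,suspected,1.0,2020-01-01\n",  # orphan case id
    )
    reac = _write(
        tmp_path, "reac.csv",
        "case_id,pt_code,pt_name,onset_date\n"
        "A,10022611,interstitial lung disease,2020-02-05\n"
        "B,10028813,nausea,2020-04-01\n",
    )
    hist = _write(tmp_path, "hist.csv", "case_id,disease_name\nA,hypertension\n")
    return demo, drug, reac, hist


def test_round_trip_row_counts(sim_paths, bundle):
    for name in ("demo", "drug", "reac", "hist"):
        n_lines = sum(1 for _ in open(sim_paths[name])) - 1
        assert len(getattr(bundle, name)) == n_lines


def test_unit_suffixed_dose_coerced_and_logged(tiny_tables):
    b = io.read_tables(*tiny_tables)
    doses = dict(zip(b.drug["case_id"] + "/" + b.drug["drug_name"], b.drug["daily_dose_g"]))
    assert doses["A/Saireito"] == 2.5
    assert b.parse_report.coerced["drug.daily_dose_g.unit_stripped"] == 1


def test_partial_date_becomes_missing_and_counted(tiny_tables):
    b = io.read_tables(*tiny_tables)
    conc = b.drug.query("drug_name == 'rebamipide'").iloc[0]
    assert conc["start_date"] is None
    assert b.parse_report.coerced["drug.start_date.partial_or_invalid"] == 1


def test_missing_column_error_names_file_and_column(tmp_path, tiny_tables):
    demo, drug, reac, hist = tiny_tables
    bad = _write(tmp_path, "bad_reac.csv", "case_id,pt_code,onset_date\nA,1,2020-01-01\n")
    with pytest.raises(ValueError, match=r"reac.*pt_name"):
        io.read_tables(demo, drug, bad, hist)


def test_empty_event_table_is_not_an_error(tmp_path, tiny_tables):
    demo, drug, _, hist = tiny_tables
    empty = _write(tmp_path, "empty_reac.csv", "case_id,pt_code,pt_name,onset_date\n")
    b = io.read_tables(demo, drug, empty, hist)
    assert len(b.reac) == 0


def test_integration_last_version_wins_and_orphans_dropped(tiny_tables):
    b = io.read_tables(*tiny_tables)
    reports = {r.case_id: r for r in io.integrate_reports(b)}
    assert set(reports) == {"A", "B"}
    assert reports["A"].sex == "male" and reports["A"].age_decade == "70s"
    assert reports["B"].sex is None and reports["B"].age_decade is None
    assert b.parse_report.dropped_orphans["drug"] == 1
    assert b.parse_report.duplicate_demo_rows == 1


def test_integration_one_report_per_case(sim_paths, bundle, reports):
    demo = pd.read_csv(sim_paths["demo"])
    assert len(reports) == demo["case_id"].nunique()
    # duplicate emission made the raw demo longer than the distinct count
    assert len(demo) > len(reports)


def test_integration_idempotent(reports):
    again = io.integrate_reports(io.bundle_from_reports(reports))
    assert {r.case_id: r for r in again} == {r.case_id: r for r in reports}


def test_filter_suspected_keeps_reports_drops_roles(make_report):
    r = make_report(
        drugs=[
            ("Saireito", "suspected", 7.5, None),
            ("rebamipide", "concomitant", None, None),
            ("warfarin", "interacting", None, None),
        ]
    )
    out = io.filter_suspected([r])
    assert len(out) == 1 and [d.name for d in out[0].drugs] == ["Saireito"]
    only_conc = make_report(case_id="X2", drugs=[("rebamipide", "concomitant", None, None)])
    out = io.filter_suspected([only_conc])
    assert len(out) == 1 and out[0].drugs == []
    all_susp = make_report(case_id="X3", drugs=[("a", "suspected", None, None)])
    assert io.filter_suspected([all_susp])[0] == all_susp


def test_demographic_subset_excludes_missing_at_configured_rate(reports):
    kept, excl = io.demographic_subset(reports, {"sex"})
    frac = excl["missing_sex"] / len(reports)
    assert abs(frac - 0.1) < 0.03  # generator's missing_sex_rate 0.1
    assert len(kept) + excl["missing_sex"] == len(reports)
    # each additional requirement is monotone decreasing
    kept_both, _ = io.demographic_subset(reports, {"sex", "age"})
    assert len(kept_both) <= len(kept) <= len(reports)


def test_demographic_subset_empty_requirement_is_identity(reports):
    kept, excl = io.demographic_subset(reports, set())
    assert kept == list(reports) and excl == {}


def test_flag_dild_matches_code_or_name(make_report, dild_event):
    assert io.flag_dild(make_report(events=[dild_event]))
    assert not io.flag_dild(make_report(events=[]))
    multi = make_report(
        events=[("10028813", "nausea", None), dild_event, ("10037844", "rash", None)]
    )
    assert io.flag_dild(multi)
    by_name = make_report(events=[("", "Interstitial Lung Disease", None)])
    assert io.flag_dild(by_name)
    other = make_report(events=[("10028813", "nausea", None)])
    assert not io.flag_dild(other)


@given(st.floats(min_value=0, max_value=100, allow_nan=False).map(lambda x: round(x, 3)))
def test_dose_parsing_strips_unit_suffix(value):
    rep = io.ParseReport()
    assert io._parse_dose(f"{value}g", rep) == pytest.approx(value)
    assert io._parse_dose(str(value), rep) == pytest.approx(value)
    assert io._parse_dose("not-a-dose", rep) is None
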