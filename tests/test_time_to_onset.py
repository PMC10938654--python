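"""Onset-duration extraction, Weibull shape analysis and survival curves."""

import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats

from kampovig.time_to_onset import (
    OnsetSample,
    WeibullFit,
    classify_hazard,
    extract_durations,
    fit_weibull,
    km_curve,
    onset_summary_table,
    summarize_durations,
)


def _sample(durations, label="x"):
    return OnsetSample(label, list(durations))


def _weibull_days(alpha, beta, n, seed, window=365):
    rng = np.random.default_rng(seed)
    t = np.maximum(1, np.rint(alpha * rng.weibull(beta, n))).astype(int)
    return t[t <= window]


def test_duration_is_onset_minus_start_in_days(make_report, dild_event):
    r = make_report(
        drugs=[("Saireito", "suspected", 7.5, dt.date(2020, 1, 1))],
        events=[dild_event],  # onset 2020-02-05
    )
    s = extract_durations([r], "Saireito")
    assert s.durations == [35]


def test_onset_before_start_excluded_as_inconsistent(make_report):
    r = make_report(
        drugs=[("Saireito", "suspected", 7.5, dt.date(2020, 3, 1))],
        events=[("10022611", "interstitial lung disease", dt.date(2020, 2, 5))],
    )
    s = extract_durations([r], "Saireito")
    assert s.durations == [] and s.n_excluded_incomplete_dates == 1


def test_partial_dates_beyond_window_and_duplicates_counted(make_report):
    start = dt.date(2020, 1, 1)
    r = make_report(
        drugs=[
            ("Saireito", "suspected", 7.5, start),
            ("Saireito", "suspected", 7.5, start),  # duplicate prescription
            ("Saireito", "suspected", 7.5, None),  # missing start date
        ],
        events=[("10022611", "interstitial lung disease", dt.date(2021, 6, 1))],
    )
    s = extract_durations([r], "Saireito")
    assert s.n_excluded_duplicates == 1
    assert s.n_excluded_incomplete_dates == 1
    assert s.n_excluded_beyond_window == 1 and s.durations == []


def test_extracted_median_matches_weibull_closed_form():
    alpha, beta = 40.0, 1.36
    days = _weibull_days(alpha, beta, 4000, seed=1)
    med = summarize_durations(_sample(days))["median"]
    assert med == pytest.approx(alpha * math.log(2) ** (1 / beta), rel=0.06)


def test_summary_closed_forms():
    s = summarize_durations(_sample([1, 2, 3, 4, 5]))
    assert (s["median"], s["q1"], s["q3"]) == (3, 2, 4)
    s1 = summarize_durations(_sample([7]))
    assert (s1["median"], s1["q1"], s1["q3"]) == (7, 7, 7)
    assert s1["text"] == "7.0 (7.0–7.0)"
    with pytest.raises(ValueError):
        summarize_durations(_sample([]))


def test_weibull_fit_matches_scipy_mle():
    days = _weibull_days(40, 1.36, 2000, seed=7)
    fit = fit_weibull(_sample(days))
    c, _, scale = stats.weibull_min.fit(days.astype(float), floc=0)
    assert fit.beta == pytest.approx(c, rel=1e-4)
    assert fit.alpha == pytest.approx(scale, rel=1e-4)
    assert fit.beta_ci[0] < fit.beta < fit.beta_ci[1]


def test_weibull_refuses_small_samples():
    with pytest.raises(ValueError, match="at least"):
        fit_weibull(_sample([5] * 9))


def test_degenerate_equal_durations_flagged():
    fit = fit_weibull(_sample([30] * 50))
    assert not fit.converged


def test_exponential_data_classified_random_failure():
    random_type = 0
    for seed in range(10):
        days = _weibull_days(40, 1.0, 800, seed=seed)
        fit = fit_weibull(_sample(days))
        random_type += fit.classification == "random_failure"
    assert random_type >= 8


def test_mle_scale_invariance():
    days = _weibull_days(40, 1.36, 1500, seed=9).astype(float)
    f1 = fit_weibull(_sample(days))
    f2 = fit_weibull(_sample(days * 3.0))
    assert f2.beta == pytest.approx(f1.beta, rel=1e-6)
    assert f2.alpha == pytest.approx(3.0 * f1.alpha, rel=1e-6)


@pytest.mark.parametrize(
    "beta,ci,expected",
    [
        (1.36, (1.20, 1.52), "wear_out"),
        (1.31, (0.98, 1.68), "random_failure"),
        (0.70, (0.50, 0.90), "initial_failure"),
        (1.00, (0.90, 1.10), "random_failure"),
    ],
)
def test_hazard_classification_rule(beta, ci, expected):
    fit = WeibullFit(alpha=40.0, beta=beta, alpha_ci=(30, 50), beta_ci=ci, n=100)
    assert classify_hazard(fit) == expected


def test_km_single_observation_and_no_tie_closed_form():
    km = km_curve(_sample([10]))
    assert km.time.tolist() == [0.0, 10.0]
    assert km.survival.tolist() == [1.0, 0.0]
    km2 = km_curve(_sample([3, 1, 4, 2, 5]))
    assert km2.survival.tolist() == pytest.approx([1.0, 0.8, 0.6, 0.4, 0.2, 0.0])


def test_km_equals_empirical_survival_and_lifelines():
    days = _weibull_days(40, 1.36, 400, seed=11)
    km = km_curve(_sample(days))
    # product-limit with no censoring = empirical survival function
    for t, s in zip(km.time[1:], km.survival[1:]):
        assert s == pytest.approx((days > t).mean())
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter().fit(days)
    ours = dict(zip(km.time, km.survival))
    for t, s in kmf.survival_function_["KM_estimate"].items():
        if t in ours:
            assert ours[t] == pytest.approx(s, abs=1e-10)


def test_weibull_ci_cross_checked_against_lifelines():
    days = _weibull_days(40, 1.36, 1500, seed=13).astype(float)
    fit = fit_weibull(_sample(days))
    from lifelines import WeibullFitter

    wf = WeibullFitter().fit(days)
    assert fit.alpha == pytest.approx(wf.lambda_, rel=1e-3)
    assert fit.beta == pytest.approx(wf.rho_, rel=1e-3)


def test_summary_table_restricted_to_more_than_ten_cases():
    big = _sample(_weibull_days(40, 1.36, 200, seed=15), label="big")
    small = _sample([5, 9, 12], label="small")
    table = onset_summary_table([big, small])
    assert table.label.tolist() == ["big"]
    assert set(table.columns) >= {"median_iqr", "beta", "classification"}
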