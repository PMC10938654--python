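"""Logistic fitting, stepwise selection, adjusted ORs, dose-response, ROC."""

import math

import numpy as np
import pandas as pd
import pytest

from kampovig.modeling import (
    adjusted_or,
    age_indicator,
    fit_dose_response,
    fit_logistic,
    lrt,
    roc_analysis,
    stepwise_select,
)
from kampovig.synthetic import EQ1_TERMS, simulate_covariate_outcome


def test_age_indicator_dichotomizes_at_sixty():
    assert [age_indicator(a) for a in ("<20", "50s", "60s", "80s+")] == [0, 0, 1, 1]
    assert age_indicator(None) is None


def test_intercept_only_recovers_logit_prevalence():
    y = np.array([1] * 30 + [0] * 70)
    design = pd.DataFrame({"const": np.ones(100)})
    fit = fit_logistic(design, y)
    assert fit.coef("const") == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)
    assert fit.converged


def test_constant_outcome_rejected():
    design = pd.DataFrame({"const": np.ones(20)})
    with pytest.raises(ValueError):
        fit_logistic(design, np.ones(20))


def test_parameter_recovery_within_three_se():
    true = {"const": -3.0, "D1": 0.38, "S": 0.37, "A": 0.65}
    df = simulate_covariate_outcome(50_000, true, seed=101)
    fit = fit_logistic(df, df.outcome, ["const", "D1", "S", "A"])
    for term, b in true.items():
        assert abs(fit.coef(term) - b) < 3 * fit.se(term)


def test_perfect_separation_is_flagged_not_silent():
    x = np.concatenate([np.zeros(20), np.ones(20)])
    design = pd.DataFrame({"const": np.ones(40), "x": x})
    fit = fit_logistic(design, x.astype(int))
    assert not fit.converged


def test_lrt_identical_models_p_one_and_nested_checks():
    df = simulate_covariate_outcome(2000, {"const": -1.0, "D1": 0.5}, seed=5)
    full = fit_logistic(df, df.outcome, ["const", "D1"])
    assert lrt(full, full) == 1.0
    reduced = fit_logistic(df, df.outcome, ["const"])
    assert 0.0 <= lrt(full, reduced) < 1.0
    other = fit_logistic(df, df.outcome, ["const", "S"])
    with pytest.raises(ValueError, match="nested"):
        lrt(full, other)


def test_lrt_detects_strong_effect():
    df = simulate_covariate_outcome(20_000, {"const": -2.0, "D1": 0.5}, seed=6)
    full = fit_logistic(df, df.outcome, ["const", "D1"])
    reduced = fit_logistic(df, df.outcome, ["const"])
    assert lrt(full, reduced) < 1e-6


def test_stepwise_disabled_selection_equals_plain_fit():
    df = simulate_covariate_outcome(3000, {"const": -1.5, "D1": 0.4}, seed=7)
    terms = ["const", "D1", "S"]
    forced = fit_logistic(df, df.outcome, terms)
    via_stepwise = stepwise_select([], df, df.outcome, forced_terms=terms)
    assert via_stepwise.terms == forced.terms
    assert np.allclose(via_stepwise.coefficients, forced.coefficients)


def test_stepwise_retains_true_interaction_drops_null_term():
    """With a real D1*A interaction and null D2, selection keeps the
    hierarchy D1, A, D1:A and almost always discards D2."""
    true = {"const": -3.0, "D1": 0.38, "A": 0.65, "D1:A": 0.25}
    kept_triple = dropped_d2 = 0
    reps = 10
    for rep in range(reps):
        df = simulate_covariate_outcome(20_000, true, seed=4000 + rep)
        fit = stepwise_select(["Y", "D1", "D2", "S", "A", "D1:A", "D1:D2"], df, df.outcome)
        terms = set(fit.terms)
        kept_triple += {"D1", "A", "D1:A"} <= terms
        dropped_d2 += "D2" not in terms
    assert kept_triple >= reps - 1
    assert dropped_d2 >= reps - 2


def test_stepwise_usually_intercept_only_under_global_null():
    count = 0
    for rep in range(10):
        df = simulate_covariate_outcome(5000, {"const": -2.5}, seed=5000 + rep)
        fit = stepwise_select(["Y", "D1", "D2", "S", "A", "D1:A", "D1:D2"], df, df.outcome)
        count += fit.terms == ["const"]
    assert count >= 5  # loose: selection is intercept-only most of the time


def test_stepwise_enforces_interaction_hierarchy():
    """An interaction can only be selected alongside both components."""
    true = {"const": -2.5, "D1": 0.4, "A": 0.7, "D1:A": 0.3}
    df = simulate_covariate_outcome(20_000, true, seed=77)
    fit = stepwise_select(["D1", "A", "D1:A", "D1:D2", "D2"], df, df.outcome)
    for t in fit.terms:
        if ":" in t:
            assert all(part in fit.terms for part in t.split(":"))


def test_adjusted_or_single_term_is_exp_coefficient():
    df = simulate_covariate_outcome(5000, {"const": -2.0, "D1": 0.4}, seed=8)
    fit = fit_logistic(df, df.outcome, ["const", "D1", "S"])
    orv, lo, hi = adjusted_or(fit, "D1")
    assert orv == pytest.approx(math.exp(fit.coef("D1")))
    assert (lo, hi) == pytest.approx(tuple(math.exp(v) for v in fit.wald_ci("D1")))
    with pytest.raises(ValueError, match="not in fit"):
        adjusted_or(fit, "missing")


def test_adjusted_or_combination_matches_published_arithmetic():
    """The combined-effect rule: exp(sum of component + interaction
    estimates). On the published estimates 0.38 + 0.65 + 0.17 this gives
    exp(1.20) = 3.32, matching the tabulated 3.35 at rounding precision."""
    assert math.exp(0.38 + 0.65 + 0.17) == pytest.approx(3.32, abs=0.005)
    df = simulate_covariate_outcome(
        20_000, {"const": -3.0, "D1": 0.4, "A": 0.6, "D1:A": 0.2}, seed=9
    )
    fit = fit_logistic(df, df.outcome, ["const", "D1", "A", "D1:A"])
    orv, lo, hi = adjusted_or(fit, ["D1", "A", "D1:A"])
    s = fit.coef("D1") + fit.coef("A") + fit.coef("D1:A")
    assert orv == pytest.approx(math.exp(s))
    e = np.array([0.0, 1.0, 1.0, 1.0])
    var = float(e @ fit.covariance @ e)
    assert lo == pytest.approx(math.exp(s - 1.96 * math.sqrt(var)))
    assert lo < orv < hi


def test_zero_coefficient_gives_unit_odds_ratio():
    fit = fit_logistic(
        pd.DataFrame({"const": np.ones(100), "x": np.r_[np.zeros(50), np.ones(50)]}),
        np.tile([0, 1], 50),
    )
    orv, _, _ = adjusted_or(fit, "x")
    assert orv == pytest.approx(1.0, abs=0.05)


def test_dose_response_slope_recovery_and_null():
    rng = np.random.default_rng(10)
    d = np.where(rng.random(20_000) < 0.5, 0.0, rng.gamma(2.0, 0.8, 20_000))
    y = rng.random(20_000) < 1 / (1 + np.exp(-(-2.0 + 0.40 * d)))
    fit, curve = fit_dose_response(d, y.astype(int))
    assert abs(fit.coef("D") - 0.40) < 3 * fit.se("D")
    assert set(curve.columns) == {"intake_g_per_day", "p_event"}
    assert curve.p_event.is_monotonic_increasing
    y_null = rng.random(20_000) < 0.1
    fit0, _ = fit_dose_response(d, y_null.astype(int))
    assert abs(fit0.coef("D")) < 3 * fit0.se("D")
    with pytest.raises(ValueError, match="constant"):
        fit_dose_response(np.ones(100), np.tile([0, 1], 50))


def test_roc_perfect_separation_and_null():
    scores = np.r_[np.zeros(50), np.ones(50)]
    labels = scores.astype(int)
    r = roc_analysis(scores, labels)
    assert r.auc == pytest.approx(1.0)
    assert 0.0 < r.cutoff <= 1.0
    rng = np.random.default_rng(11)
    r0 = roc_analysis(rng.random(5000), rng.integers(0, 2, 5000))
    assert abs(r0.auc - 0.5) < 0.03
    with pytest.raises(ValueError):
        roc_analysis(scores, np.ones(100))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(12)
    s = rng.gamma(2.0, 1.0, 500)
    y = (rng.random(500) < 1 / (1 + np.exp(-(s - 2)))).astype(int)
    a1 = roc_analysis(s, y).auc
    a2 = roc_analysis(np.log1p(s), y).auc
    assert a1 == pytest.approx(a2)


def test_youden_cutoff_ties_break_toward_smaller_threshold():
    # two thresholds achieve the same J; the smaller must win
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0, 0, 1, 1])
    r = roc_analysis(scores, labels)
    assert r.auc == pytest.approx(1.0)
    assert r.cutoff == 3.0  # smallest threshold reaching J = 1
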