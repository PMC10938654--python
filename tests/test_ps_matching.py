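"""Propensity estimation, caliper matching, balance and matched RORs."""

import numpy as np
import pandas as pd
import pytest

from kampovig.ps_matching import (
    MatchedCohort,
    compute_smd,
    estimate_ps,
    match_caliper,
    matched_ror,
)
from kampovig.synthetic import simulate_confounded_cohort

COVS = ["male", "age60", "co1_g", "co2_g"]


def test_null_covariates_give_flat_scores_and_half_auc():
    rng = np.random.default_rng(0)
    n = 4000
    df = pd.DataFrame({c: rng.random(n) for c in COVS})
    exposure = (rng.random(n) < 0.3).astype(int)
    scores, fit, auc = estimate_ps(df, exposure, COVS)
    assert np.allclose(scores, exposure.mean(), atol=0.05)
    assert abs(auc - 0.5) < 0.03


def test_confounded_scores_rank_with_confounder():
    df = simulate_confounded_cohort(4000, seed=1, confounding=1.2)
    scores, fit, auc = estimate_ps(df, df.exposed, COVS)
    assert auc > 0.6
    assert scores[df.age60 == 1].mean() > scores[df.age60 == 0].mean()
    # scores are exactly the logistic-fit predictions
    X = df[COVS].copy()
    X.insert(0, "const", 1.0)
    assert np.allclose(scores, fit.predict(X))


def test_identical_distributions_match_everyone():
    scores = np.tile(np.linspace(0.2, 0.8, 50), 2)
    exposed = np.r_[np.ones(50, bool), np.zeros(50, bool)]
    cohort = match_caliper(scores, exposed, seed=0)
    assert len(cohort.pairs) == 50
    assert all(abs(scores[i] - scores[j]) < 1e-12 for i, j in cohort.pairs)


def test_single_admissible_pair_is_found():
    scores = np.array([0.50, 0.51, 0.95])
    exposed = np.array([True, False, False])
    cohort = match_caliper(scores, exposed, caliper_mult=0.2, seed=0)
    assert cohort.pairs == [(0, 1)]


def test_matching_without_replacement_and_caliper_bound():
    df = simulate_confounded_cohort(3000, seed=2)
    scores, _, _ = estimate_ps(df, df.exposed, COVS)
    cohort = match_caliper(scores, df.exposed.to_numpy(bool), seed=3)
    lp = np.log(scores / (1 - scores))
    exp_ids = [i for i, _ in cohort.pairs]
    ctl_ids = [j for _, j in cohort.pairs]
    assert len(set(exp_ids)) == len(exp_ids)
    assert len(set(ctl_ids)) == len(ctl_ids)
    assert all(abs(lp[i] - lp[j]) <= cohort.caliper + 1e-12 for i, j in cohort.pairs)
    assert len(cohort.pairs) <= min(cohort.n_exposed_input, cohort.n_control_input)


def test_shrinking_caliper_never_adds_pairs():
    for rep in range(10):
        df = simulate_confounded_cohort(1500, seed=100 + rep)
        scores, _, _ = estimate_ps(df, df.exposed, COVS)
        exposed = df.exposed.to_numpy(bool)
        sizes = [
            len(match_caliper(scores, exposed, caliper_mult=m, seed=0).pairs)
            for m in (0.4, 0.2, 0.1, 0.05)
        ]
        assert sizes == sorted(sizes, reverse=True)


def test_degenerate_scores_rejected():
    with pytest.raises(ValueError, match="zero SD"):
        match_caliper(np.full(10, 0.5), np.r_[np.ones(5, bool), np.zeros(5, bool)])
    with pytest.raises(ValueError):
        match_caliper(np.random.default_rng(0).random(10), np.ones(10, bool))


def test_greedy_matches_obvious_optimal_assignment():
    """Well-separated exposed/control pairs: greedy finds every pair the
    exhaustive assignment would (each exposed has exactly one control
    within the caliper, so the optimum is forced)."""
    rng = np.random.default_rng(4)
    centers = np.linspace(0.1, 0.9, 8)
    scores = np.concatenate([centers, centers + 1e-4])
    exposed = np.r_[np.ones(8, bool), np.zeros(8, bool)]
    cohort = match_caliper(scores, exposed, caliper_mult=0.01, seed=0)
    assert sorted(cohort.pairs) == [(i, i + 8) for i in range(8)]


def test_smd_closed_forms():
    same = np.r_[np.arange(10.0), np.arange(10.0)]
    g = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    assert compute_smd(same, g) == 0.0
    x = np.r_[np.random.default_rng(5).normal(1, 1, 5000),
              np.random.default_rng(6).normal(0, 1, 5000)]
    g2 = np.r_[np.ones(5000, bool), np.zeros(5000, bool)]
    assert compute_smd(x, g2) == pytest.approx(1.0, abs=0.06)
    binary = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(15)]
    gb = np.r_[np.ones(20, bool), np.zeros(20, bool)]
    p1, p2 = 0.5, 0.25
    expected = abs(p1 - p2) / np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
    assert compute_smd(binary, gb, "binary") == pytest.approx(expected)
    assert compute_smd(np.zeros(40), gb, "binary") == 0.0


def test_matched_ror_with_no_events_is_undefined():
    cohort = MatchedCohort(pairs=[(0, 1), (2, 3)], caliper=0.1,
                           n_exposed_input=2, n_control_input=2)
    tab = matched_ror(cohort, np.zeros(4, bool))
    assert tab.ror is None
    with pytest.raises(ValueError):
        matched_ror(MatchedCohort([], 0.1, 0, 0), np.zeros(4, bool))


def test_matching_removes_confounding_bias():
    """Null direct effect + confounding: the matched ROR is nearer 1 than
    the crude ROR in the clear majority of replicates."""
    closer = 0
    reps = 15
    for rep in range(reps):
        df = simulate_confounded_cohort(6000, seed=200 + rep, direct_log_or=0.0,
                                        confounding=1.0)
        scores, _, _ = estimate_ps(df, df.exposed, COVS)
        exposed = df.exposed.to_numpy(bool)
        ev = df.event.to_numpy(bool)
        from kampovig.disproportionality import ContingencySignal, compute_ror

        crude = compute_ror(ContingencySignal(
            int((exposed & ev).sum()), int((exposed & ~ev).sum()),
            int((~exposed & ev).sum()), int((~exposed & ~ev).sum())))
        cohort = match_caliper(scores, exposed, seed=rep)
        matched = matched_ror(cohort, ev)
        if abs(np.log(matched.ror)) < abs(np.log(crude.ror)):
            closer += 1
    assert closer >= reps - 3
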