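"""Logistic modeling of DIILD reporting odds and dose-response analysis.

Two model families are fit:

* a multivariate logistic model of the DIILD reporting odds on reporting
  year (Y), daily Scutellariae radix intake (D1, g/day), daily Pinelliae
  tuber intake (D2, g/day), sex (S, male = 1) and age (A, >= 60 years = 1),
  with the interactions D1*A and D1*D2; terms are screened by forward-
  backward stepwise selection on likelihood-ratio p-values at alpha = 0.05,
  and adjusted reporting odds ratios are exp(coefficient) with Wald CIs
  (interaction rows report the combined effect of the components plus the
  interaction, with a delta-method CI on the summed linear combination);

* a per-crude-drug dose-response logistic, log(odds) = b0 + b1 * D, whose
  slope exponentiates to the crude ROR per gram, accompanied by an
  empirical ROC analysis whose cutoff maximizes Youden's J.

Fits go through statsmodels (Newton/IRLS maximum likelihood; covariance =
inverse observed information); ROC curves go through scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.metrics import roc_curve

__all__ = [
    "LogisticFit",
    "ROCResult",
    "fit_logistic",
    "stepwise_select",
    "lrt",
    "adjusted_or",
    "fit_dose_response",
    "roc_analysis",
    "age_indicator",
]

Z95 = 1.96

#: decade strings dichotomized at >= 60 years
_OLD_DECADES = {"60s", "70s", "80s+"}


def age_indicator(age_decade: str | None) -> float | None:
    """Age >= 60 indicator from a canonical decade string (None = missing)."""
    if age_decade is None:
        return None
    return 1.0 if age_decade in _OLD_DECADES else 0.0


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance and fit metadata."""

    terms: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        i = self.terms.index(term)
        return float(np.sqrt(self.covariance[i, i]))

    def wald_ci(self, term: str) -> tuple[float, float]:
        b, s = self.coef(term), self.se(term)
        return b - Z95 * s, b + Z95 * s

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = X[self.terms].to_numpy() @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            lo, hi = self.wald_ci(t)
            rows.append(
                {"term": t, "estimate": self.coef(t), "ci_low": lo, "ci_high": hi,
                 "odds_ratio": np.exp(self.coef(t)),
                 "or_ci_low": np.exp(lo), "or_ci_high": np.exp(hi)}
            )
        return pd.DataFrame(rows)


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC and a Youden-optimal intake cutoff."""

    points: np.ndarray  # (1 - specificity, sensitivity) rows
    thresholds: np.ndarray
    auc: float
    cutoff: float
    youden_j: float


def fit_logistic(
    design: pd.DataFrame, outcome: Sequence[int] | np.ndarray, terms: Sequence[str] | None = None
) -> LogisticFit:
    """Maximum-likelihood logistic fit of ``outcome`` on ``design[terms]``.

    The design must already contain an intercept column if one is wanted
    (conventionally named "const"). Perfect separation or non-convergence
    yields a fit flagged ``converged=False`` rather than a silent result.
    """
    terms = list(terms) if terms is not None else list(design.columns)
    y = np.asarray(outcome, dtype=float)
    X = design[terms].to_numpy(dtype=float)
    if len(y) <= len(terms):
        raise ValueError("need more observations than model terms")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model is undefined")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, PerfectSeparationError):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="bfgs")
            converged = False
    params = np.asarray(res.params, dtype=float)
    try:
        cov = np.asarray(res.cov_params(), dtype=float)
    except Exception:
        cov = np.full((len(terms), len(terms)), np.nan)
        converged = False
    if not np.all(np.isfinite(cov)):
        converged = False
    return LogisticFit(
        terms=terms, coefficients=params, covariance=cov,
        log_likelihood=float(res.llf), converged=converged, n_obs=len(y),
    )


def lrt(full: LogisticFit, reduced: LogisticFit) -> float:
    """Likelihood-ratio p-value for nested logistic fits.

    Chi-square on 2*(llf_full - llf_reduced) with df = the term-count
    difference. The models must be nested and fit on the same observations.
    """
    if not set(reduced.terms) < set(full.terms) and set(reduced.terms) != set(full.terms):
        raise ValueError("models are not nested (reduced terms must be a subset)")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fit on different numbers of observations")
    df = len(full.terms) - len(reduced.terms)
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def _interaction_parts(term: str) -> list[str]:
    return term.split(":") if ":" in term else []


def stepwise_select(
    candidate_terms: Sequence[str],
    design: pd.DataFrame,
    outcome: Sequence[int] | np.ndarray,
    alpha: float = 0.05,
    forced_terms: Sequence[str] = ("const",),
) -> LogisticFit:
    """Forward-backward stepwise selection on likelihood-ratio p-values.

    Entry and stay thresholds both equal ``alpha``. Model hierarchy is
    enforced: an interaction "X:Z" may enter only while X and Z are both in
    the model, and a main effect cannot leave while one of its interactions
    remains. Deterministic given input order: ties break by smaller p-value,
    then candidate order. ``forced_terms`` (the intercept) are never
    removed. With an empty candidate list this reduces to
    :func:`fit_logistic` on the forced terms.
    """
    candidates = [t for t in candidate_terms if t not in forced_terms]
    selected: list[str] = []

    def fit_with(terms: list[str]) -> LogisticFit:
        return fit_logistic(design, outcome, list(forced_terms) + terms)

    current = fit_with(selected)
    while True:
        changed = False
        # forward: best admissible candidate by LRT p-value
        best: tuple[float, int, str] | None = None
        for i, t in enumerate(candidates):
            if t in selected:
                continue
            parts = _interaction_parts(t)
            if parts and not all(p in selected for p in parts):
                continue
            trial = fit_with(selected + [t])
            p = lrt(trial, current)
            if p < alpha and (best is None or (p, i) < (best[0], best[1])):
                best = (p, i, t)
        if best is not None:
            selected.append(best[2])
            current = fit_with(selected)
            changed = True
        # backward: drop the worst removable term with p >= alpha
        worst: tuple[float, int, str] | None = None
        for i, t in enumerate(selected):
            if any(t in _interaction_parts(u) for u in selected if u != t):
                continue  # keep main effects under their interactions
            reduced = fit_with([u for u in selected if u != t])
            p = lrt(current, reduced)
            if p >= alpha and (worst is None or (-p, i) < (-worst[0], worst[1])):
                worst = (p, i, t)
        if worst is not None:
            selected.remove(worst[2])
            current = fit_with(selected)
            changed = True
        if not changed:
            return current


def adjusted_or(
    fit: LogisticFit, terms: str | Sequence[str]
) -> tuple[float, float, float]:
    """Adjusted reporting odds ratio with 95% CI for a term or combination.

    For a single term this is exp(coefficient) with its Wald CI. For a list
    of terms (an interaction together with its components, evaluated at unit
    values) it is exp(sum of the coefficients), with the CI from the delta
    method on the summed linear combination: Var = e' Cov e for the 0/1
    selector e of the named terms.
    """
    names = [terms] if isinstance(terms, str) else list(terms)
    missing = [t for t in names if t not in fit.terms]
    if missing:
        raise ValueError(f"term(s) not in fit: {missing}")
    e = np.array([1.0 if t in names else 0.0 for t in fit.terms])
    est = float(e @ fit.coefficients)
    se = float(np.sqrt(e @ fit.covariance @ e))
    return np.exp(est), np.exp(est - Z95 * se), np.exp(est + Z95 * se)


def fit_dose_response(
    intake: Sequence[float] | np.ndarray, outcome: Sequence[int] | np.ndarray
) -> tuple[LogisticFit, pd.DataFrame]:
    """Two-term logistic of the event on one crude drug's daily intake.

    Returns the fit (terms "const", "D"; crude ROR per gram = exp(slope))
    and the fitted logistic curve as (intake, predicted probability) pairs
    over the observed intake range, for plotting.
    """
    intake = np.asarray(intake, dtype=float)
    if intake.min() == intake.max():
        raise ValueError("intake is constant; dose-response model is undefined")
    design = pd.DataFrame({"const": np.ones(len(intake)), "D": intake})
    fit = fit_logistic(design, outcome)
    grid = np.linspace(intake.min(), intake.max(), 200)
    curve = pd.DataFrame({"intake_g_per_day": grid})
    curve["p_event"] = fit.predict(
        pd.DataFrame({"const": np.ones(len(grid)), "D": grid})
    )
    return fit, curve


def roc_analysis(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    criterion: Literal["youden", "closest"] = "youden",
) -> ROCResult:
    """Empirical ROC over all distinct thresholds, AUC, and intake cutoff.

    AUC is the trapezoid integral of the curve (equal to the Mann-Whitney
    concordance probability). The cutoff maximizes Youden's J = sensitivity
    + specificity - 1 (ties broken toward the smaller threshold); the
    alternative ``closest`` criterion minimizes the distance to (0, 1).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present for a ROC analysis")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    finite = np.isfinite(thr)
    if criterion == "youden":
        crit = tpr - fpr
    else:
        crit = -np.hypot(fpr, 1.0 - tpr)
    crit = np.where(finite, crit, -np.inf)
    best = np.flatnonzero(crit == crit.max())[-1]  # thresholds descend
    return ROCResult(
        points=np.column_stack([fpr, tpr]),
        thresholds=thr,
        auc=auc,
        cutoff=float(thr[best]),
        youden_j=float((tpr - fpr)[best]),
    )
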