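"""Time-to-onset profiling of adverse events with Weibull shape analysis.

For each drug or exposure group the days from administration start to event
onset are collected (complete dates only, duplicate same-day prescriptions
collapsed, non-positive durations excluded as inconsistent, truncated at a
365-day window), summarized by median and interquartile range, and fit with
a two-parameter Weibull distribution. The Weibull shape parameter beta
describes the hazard trend without a reference population: beta > 1 with a
95% CI excluding 1 means the hazard increases over time (wear-out failure
type), beta < 1 with CI excluding 1 a decreasing hazard (initial failure),
and otherwise the hazard is compatible with constancy (random failure).

Because a spontaneous report exists only when the event occurred, all
observations are events: there is no censoring, the 365-day window is a
truncation filter, and the Kaplan-Meier product-limit estimator coincides
with the empirical survival function.

Maximum likelihood uses Newton iteration on the profile equation for the
shape (tolerance 1e-10); CIs are Wald intervals on the log-parameter scale
from the observed information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .jader_io import AEReport, flag_dild

__all__ = [
    "OnsetSample",
    "WeibullFit",
    "extract_durations",
    "summarize_durations",
    "fit_weibull",
    "classify_hazard",
    "km_curve",
    "onset_summary_table",
]

WINDOW_DAYS = 365
MIN_WEIBULL_N = 10
Z95 = 1.96


@dataclass
class OnsetSample:
    """Onset durations (days) for one drug or exposure group."""

    label: str
    durations: list[int]
    n_excluded_duplicates: int = 0
    n_excluded_incomplete_dates: int = 0
    n_excluded_beyond_window: int = 0

    @property
    def n(self) -> int:
        return len(self.durations)


@dataclass
class WeibullFit:
    """Two-parameter Weibull MLE with Wald CIs and hazard classification."""

    alpha: float  # scale, days
    beta: float  # shape
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n: int
    converged: bool = True

    @property
    def classification(self) -> str:
        return classify_hazard(self)


def extract_durations(
    reports: Iterable[AEReport],
    target: str | Callable[[AEReport], bool],
    event: Callable[[AEReport], bool] = flag_dild,
    window: int = WINDOW_DAYS,
    drug_names: Sequence[str] | None = None,
    label: str | None = None,
) -> OnsetSample:
    """Collect onset durations for reports matching ``target`` and ``event``.

    ``target`` is a suspected-drug name, or a report predicate combined with
    ``drug_names`` naming which suspected drugs provide the administration
    start dates (for exposure groups). Durations are onset minus start in
    whole days, from the earliest matching event onset and each distinct
    (drug, start date) pair; duplicate prescriptions of the same drug on the
    same day collapse to one. Rows with partial or missing dates, durations
    <= 0 (onset on or before the start -- inconsistent) and durations beyond
    the window are excluded and counted.
    """
    if isinstance(target, str):
        names = {target}
        pred = lambda r: any(d.name == target and d.role == "suspected" for d in r.drugs)
        label = label or target
    else:
        if drug_names is None:
            raise ValueError("drug_names is required when target is a predicate")
        names = set(drug_names)
        pred = target
        label = label or "group"

    durations: list[int] = []
    n_dup = n_inc = n_win = 0
    for r in reports:
        if not pred(r) or not event(r):
            continue
        onsets = [e.onset_date for e in r.events if e.onset_date is not None]
        uses = [d for d in r.drugs if d.name in names and d.role == "suspected"]
        seen: set[tuple[str, object]] = set()
        for d in uses:
            key = (d.name, d.start_date)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            if d.start_date is None or not onsets:
                n_inc += 1
                continue
            onset = min(onsets)
            days = (onset - d.start_date).days
            if days <= 0:
                n_inc += 1
            elif days > window:
                n_win += 1
            else:
                durations.append(days)
    return OnsetSample(
        label=label,
        durations=durations,
        n_excluded_duplicates=n_dup,
        n_excluded_incomplete_dates=n_inc,
        n_excluded_beyond_window=n_win,
    )


def summarize_durations(sample: OnsetSample) -> dict[str, float | str]:
    """Median and IQR (25th/75th percentiles, linear interpolation).

    Returns the numbers plus the conventional "36.0 (27.0-63.0)" string.
    """
    if sample.n == 0:
        raise ValueError("cannot summarize an empty onset sample")
    x = np.asarray(sample.durations, dtype=float)
    med = float(np.percentile(x, 50))
    q1 = float(np.percentile(x, 25))
    q3 = float(np.percentile(x, 75))
    return {
        "median": med, "q1": q1, "q3": q3,
        "text": f"{med:.1f} ({q1:.1f}–{q3:.1f})",
    }


def _profile_shape(t: np.ndarray, tol: float = 1e-10, maxiter: int = 200) -> float:
    """Newton solve of the Weibull profile score equation for the shape."""
    logt = np.log(t)
    mlog = logt.mean()

    def score_and_deriv(b: float) -> tuple[float, float]:
        w = t**b
        sw = w.sum()
        swl = (w * logt).sum()
        swl2 = (w * logt**2).sum()
        g = 1.0 / b + mlog - swl / sw
        dg = -1.0 / b**2 - (swl2 * sw - swl**2) / sw**2
        return g, dg

    # moment-based start (Menon): beta ~ 1.2 / sd(log t)
    sd = logt.std()
    b = 1.2 / sd if sd > 0 else float("nan")
    if not math.isfinite(b) or b <= 0:
        raise FloatingPointError("degenerate durations (zero spread)")
    with np.errstate(all="ignore"):
        for _ in range(maxiter):
            g, dg = score_and_deriv(b)
            if not (math.isfinite(g) and math.isfinite(dg)) or dg == 0:
                raise FloatingPointError("profile score is not finite")
            b_new = b - g / dg
            if b_new <= 0:
                b_new = b / 2.0
            if abs(b_new - b) <= tol * max(1.0, b):
                return b_new
            b = b_new
    raise FloatingPointError("profile Newton iteration did not converge")


def fit_weibull(sample: OnsetSample) -> WeibullFit:
    """Maximum-likelihood Weibull fit on uncensored durations.

    Requires n >= 10 (below that a CI is meaningless and the call refuses).
    Degenerate samples (all durations equal, shape diverging) yield a fit
    flagged ``converged=False``.
    """
    if sample.n < MIN_WEIBULL_N:
        raise ValueError(
            f"need at least {MIN_WEIBULL_N} onset durations for a Weibull fit "
            f"(got {sample.n})"
        )
    t = np.asarray(sample.durations, dtype=float)
    try:
        beta = _profile_shape(t)
    except FloatingPointError:
        return WeibullFit(
            alpha=float(t.mean()), beta=float("nan"),
            alpha_ci=(float("nan"), float("nan")), beta_ci=(float("nan"), float("nan")),
            n=sample.n, converged=False,
        )
    alpha = float((t**beta).mean() ** (1.0 / beta))

    # observed information for (u, v) = (log alpha, log beta)
    n = len(t)
    s = np.log(t) - math.log(alpha)
    z = np.exp(beta * s)
    h_uu = -(beta**2) * z.sum()
    h_uv = -n * beta + beta * z.sum() + beta**2 * (s * z).sum()
    h_vv = beta * s.sum() - beta * (s * z).sum() - beta**2 * (s**2 * z).sum()
    info = -np.array([[h_uu, h_uv], [h_uv, h_vv]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return WeibullFit(alpha, beta, (math.nan, math.nan), (math.nan, math.nan),
                          n=sample.n, converged=False)
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return WeibullFit(alpha, beta, (math.nan, math.nan), (math.nan, math.nan),
                          n=sample.n, converged=False)
    se_u, se_v = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    alpha_ci = (alpha * math.exp(-Z95 * se_u), alpha * math.exp(Z95 * se_u))
    beta_ci = (beta * math.exp(-Z95 * se_v), beta * math.exp(Z95 * se_v))
    return WeibullFit(alpha, beta, alpha_ci, beta_ci, n=sample.n, converged=True)


def classify_hazard(fit: WeibullFit) -> str:
    """Hazard trend from the shape parameter and its CI.

    wear_out: beta > 1 and CI excludes 1; initial_failure: beta < 1 and CI
    excludes 1; otherwise random_failure (hazard compatible with constant).
    """
    lo, hi = fit.beta_ci
    if not (math.isfinite(lo) and math.isfinite(hi)):
        return "random_failure"
    if fit.beta > 1 and lo > 1:
        return "wear_out"
    if fit.beta < 1 and hi < 1:
        return "initial_failure"
    return "random_failure"


def km_curve(sample: OnsetSample) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival over the onset durations.

    With every observation an event the estimator equals the empirical
    survival function: right-continuous steps from S(0) = 1 dropping by the
    tied-event count over n at each distinct duration.
    """
    if sample.n == 0:
        raise ValueError("cannot build a survival curve from an empty sample")
    t = np.asarray(sorted(sample.durations), dtype=float)
    times, counts = np.unique(t, return_counts=True)
    n = len(t)
    surv = 1.0 - np.cumsum(counts) / n
    return pd.DataFrame(
        {"time": np.concatenate([[0.0], times]),
         "survival": np.concatenate([[1.0], surv])}
    )


def onset_summary_table(
    samples: Iterable[OnsetSample], min_cases: int = MIN_WEIBULL_N
) -> pd.DataFrame:
    """Per-drug/group rows: n, median (IQR), alpha (CI), beta (CI), class.

    Restricted to samples with more than ``min_cases`` onset cases, as is
    conventional for drug-level time-to-onset reporting.
    """
    rows = []
    for s in samples:
        if s.n <= min_cases:
            continue
        summ = summarize_durations(s)
        fit = fit_weibull(s)
        rows.append(
            {
                "label": s.label,
                "n": s.n,
                "median_iqr": summ["text"],
                "alpha": fit.alpha,
                "alpha_ci_low": fit.alpha_ci[0],
                "alpha_ci_high": fit.alpha_ci[1],
                "beta": fit.beta,
                "beta_ci_low": fit.beta_ci[0],
                "beta_ci_high": fit.beta_ci[1],
                "classification": fit.classification if fit.converged else "unstable",
            }
        )
    return pd.DataFrame(rows)
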