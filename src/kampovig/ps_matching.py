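"""Propensity-score caliper matching for crude-drug exposure.

The propensity score (PS) is the modeled probability of exposure to one
crude drug given sex, the age >= 60 indicator and the daily intakes of the
other two crude drugs. Exposed reports are matched 1:1 without replacement
to controls by greedy nearest-neighbor on the logit PS, within a caliper of
0.2 times the standard deviation of the logit PS (the usual convention).
Exposed subjects are processed in descending logit-PS order; randomness is
used only to break exact distance ties, so results are deterministic given
a seed. Covariate balance is assessed by standardized mean differences
(SMD; < 0.1 regarded as balanced), and the exposure-event reporting odds
ratio is recomputed on the matched cohort as a plain (unpaired) 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disproportionality import ContingencySignal, compute_ror, detect_signal
from .modeling import LogisticFit, fit_logistic, roc_analysis

__all__ = [
    "MatchedCohort",
    "estimate_ps",
    "match_caliper",
    "compute_smd",
    "matched_ror",
    "balance_table",
]


@dataclass
class MatchedCohort:
    """1:1 matched pairs of (exposed index, control index) with diagnostics."""

    pairs: list[tuple[int, int]]
    caliper: float  # in logit-PS units
    n_exposed_input: int
    n_control_input: int
    smd_before: dict[str, float] = field(default_factory=dict)
    smd_after: dict[str, float] = field(default_factory=dict)

    @property
    def exposed_idx(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=int)

    @property
    def control_idx(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=int)


def estimate_ps(
    design: pd.DataFrame,
    exposure: Sequence[int] | np.ndarray,
    covariates: Sequence[str],
) -> tuple[np.ndarray, LogisticFit, float]:
    """Propensity scores from a logistic model of exposure on covariates.

    Returns (scores in (0,1), the fit, the model's ROC AUC for treatment
    allocation). An intercept is added automatically. A non-converged fit
    (separation) raises, because matching on degenerate scores is
    meaningless.
    """
    X = design[list(covariates)].copy()
    X.insert(0, "const", 1.0)
    fit = fit_logistic(X, exposure)
    if not fit.converged:
        raise ValueError("propensity model did not converge (separation?); matching aborted")
    scores = fit.predict(X)
    auc = roc_analysis(scores, exposure).auc
    return scores, fit, auc


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def match_caliper(
    scores: Sequence[float] | np.ndarray,
    exposed: Sequence[bool] | np.ndarray,
    caliper_mult: float = 0.2,
    seed: int | None = 0,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching on the logit PS within a caliper.

    caliper = caliper_mult * SD(logit PS) over all subjects. Exposed
    subjects are visited in descending logit-PS order; each takes the
    nearest still-unmatched control within the caliper (exact distance ties
    broken by the seeded RNG). Exposed subjects with no admissible control
    are dropped. Matching is without replacement on both sides.
    """
    scores = np.asarray(scores, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    if exposed.all() or (~exposed).all():
        raise ValueError("both exposed and control subjects are required")
    lp = _logit(scores)
    sd = float(np.std(lp, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate propensity scores: zero SD of the logit")
    caliper = caliper_mult * sd
    rng = np.random.default_rng(seed)

    exp_idx = np.flatnonzero(exposed)
    ctl_idx = np.flatnonzero(~exposed)
    exp_idx = exp_idx[np.argsort(-lp[exp_idx], kind="stable")]
    ctl_lp = lp[ctl_idx]
    available = np.ones(len(ctl_idx), dtype=bool)

    pairs: list[tuple[int, int]] = []
    for i in exp_idx:
        dist = np.abs(ctl_lp - lp[i])
        dist[~available] = np.inf
        dmin = dist.min()
        if not math.isfinite(dmin) or dmin > caliper:
            continue
        tied = np.flatnonzero(dist == dmin)
        k = tied[0] if len(tied) == 1 else rng.choice(tied)
        available[k] = False
        pairs.append((int(i), int(ctl_idx[k])))
    return MatchedCohort(
        pairs=pairs,
        caliper=caliper,
        n_exposed_input=int(exposed.sum()),
        n_control_input=int((~exposed).sum()),
    )


def compute_smd(
    values: Sequence[float] | np.ndarray,
    group: Sequence[bool] | np.ndarray,
    kind: Literal["continuous", "binary"] = "continuous",
) -> float:
    """Standardized mean difference between two groups (always >= 0).

    Continuous: |m1 - m2| / sqrt((s1^2 + s2^2)/2) with sample variances.
    Binary: |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2))/2). Returns 0 when both
    the numerator and the denominator are 0.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be nonempty")
    x1, x2 = x[g], x[~g]
    if kind == "binary":
        p1, p2 = x1.mean(), x2.mean()
        num = abs(p1 - p2)
        den = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
    else:
        num = abs(x1.mean() - x2.mean())
        den = math.sqrt((x1.var(ddof=1) + x2.var(ddof=1)) / 2)
    if num == 0 and den == 0:
        return 0.0
    return num / den if den > 0 else math.inf


def matched_ror(
    cohort: MatchedCohort, events: Sequence[bool] | np.ndarray
) -> ContingencySignal:
    """ROR of the exposure on the matched cohort (unpaired 2x2 table).

    a/b: matched exposed with/without the event; c/d: matched controls
    with/without. A zero cell leaves the ROR undefined, not an exception.
    """
    if not cohort.pairs:
        raise ValueError("matched cohort has no pairs")
    ev = np.asarray(events, dtype=bool)
    e, c = cohort.exposed_idx, cohort.control_idx
    tab = ContingencySignal(
        a=int(ev[e].sum()), b=int((~ev[e]).sum()),
        c=int(ev[c].sum()), d=int((~ev[c]).sum()),
        label="matched",
    )
    compute_ror(tab, "subtracted")
    detect_signal(tab)
    return tab


def balance_table(
    data: pd.DataFrame,
    exposed: Sequence[bool] | np.ndarray,
    cohort: MatchedCohort,
    covariates: dict[str, Literal["continuous", "binary"]],
) -> pd.DataFrame:
    """Before/after covariate balance in the published layout.

    Per covariate: group summaries (mean +/- SD, or count and proportion),
    a p-value (two-sample t for continuous, chi-square for binary -- the
    conventional choices) and the SMD, before and after matching. Also
    fills the cohort's ``smd_before``/``smd_after`` maps.
    """
    exposed = np.asarray(exposed, dtype=bool)
    rows = []
    m_idx = np.concatenate([cohort.exposed_idx, cohort.control_idx]) if cohort.pairs else None
    for cov, kind in covariates.items():
        x = data[cov].to_numpy(dtype=float)
        entry = {"covariate": cov, "type": kind}
        for tag, idx in (("before", None), ("after", m_idx)):
            if idx is None:
                xx, gg = x, exposed
            else:
                xx = x[idx]
                gg = np.zeros(len(idx), dtype=bool)
                gg[: len(cohort.pairs)] = True
            smd = compute_smd(xx, gg, kind)
            if kind == "binary":
                t1 = np.array([[ (xx[gg] == 1).sum(), (xx[gg] == 0).sum()],
                               [ (xx[~gg] == 1).sum(), (xx[~gg] == 0).sum()]])
                if (t1.sum(axis=0) > 0).all() and (t1.sum(axis=1) > 0).all():
                    p = float(stats.chi2_contingency(t1, correction=False)[1])
                else:
                    p = float("nan")
                entry[f"{tag}_exposed"] = f"{(xx[gg] == 1).sum()} ({xx[gg].mean():.4f})"
                entry[f"{tag}_control"] = f"{(xx[~gg] == 1).sum()} ({xx[~gg].mean():.4f})"
            else:
                p = float(stats.ttest_ind(xx[gg], xx[~gg], equal_var=False).pvalue)
                entry[f"{tag}_exposed"] = f"{xx[gg].mean():.2f} ± {xx[gg].std(ddof=1):.2f}"
                entry[f"{tag}_control"] = f"{xx[~gg].mean():.2f} ± {xx[~gg].std(ddof=1):.2f}"
            entry[f"{tag}_p"] = p
            entry[f"{tag}_smd"] = smd
            (cohort.smd_before if tag == "before" else cohort.smd_after)[cov] = smd
        rows.append(entry)
    return pd.DataFrame(rows)
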