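"""End-to-end orchestration of the DIILD herbal-medicine analysis.

Runs the full workflow over a four-table JADER-dialect dataset: integration
and cleaning, suspected-drug restriction, crude-drug exposure grouping,
ROR signal tables (per product, per group, per sex, per age decade), the
multivariate logistic model with stepwise selection, per-crude-drug
dose-response and ROC cutoffs, propensity-score matched RORs, time-to-onset
summaries with Weibull shape classification, and the underlying-disease
frequency table. Every exclusion step logs its count; outputs are CSV files
and are deterministic given the config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import disproportionality as dp
from . import formulary as fm
from . import jader_io as io
from . import modeling as md
from . import ps_matching as psm
from . import time_to_onset as tto

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "tabulate_history"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    demo: str
    drug: str
    reac: str
    hist: str
    formulary: str | None = None  # None = packaged example registry
    pt_code: str = io.TARGET_PT_CODE
    min_cases: int = 3
    caliper_mult: float = 0.2
    window_days: int = 365
    stepwise_alpha: float = 0.05
    others_cutoff: float = 0.01  # history tail collapse threshold
    do_signals: bool = True
    do_model: bool = True
    do_match: bool = True
    do_tto: bool = True
    do_history: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("demo", "drug", "reac", "hist"):
            if not Path(getattr(self, name)).exists():
                raise ValueError(f"input table {name!r} not found: {getattr(self, name)}")
        if self.formulary is not None and not Path(self.formulary).exists():
            raise ValueError(f"formulary registry not found: {self.formulary}")
        for name in ("min_cases", "caliper_mult", "window_days", "stepwise_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def tabulate_history(
    reports: Sequence[io.AEReport],
    group_of: Callable[[io.AEReport], str],
    event: Callable[[io.AEReport], bool] = io.flag_dild,
    others_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Underlying-disease frequencies per exposure group among event cases.

    Percentages are of the group's history entries (not of reports);
    diseases below ``others_cutoff`` of the group's entries collapse into an
    "Others" row, so each group's percentages sum to 100 up to rounding.
    """
    buckets: dict[str, list[str]] = {}
    for r in reports:
        if not event(r) or not r.history:
            continue
        buckets.setdefault(group_of(r), []).extend(r.history)
    rows = []
    for grp in sorted(buckets):
        entries = buckets[grp]
        total = len(entries)
        counts = pd.Series(entries).value_counts()
        others = 0
        for disease, n in counts.items():
            if n / total < others_cutoff:
                others += int(n)
            else:
                rows.append({"group": grp, "disease": disease, "n": int(n),
                             "pct": 100.0 * n / total})
        if others:
            rows.append({"group": grp, "disease": "Others", "n": others,
                         "pct": 100.0 * others / total})
    return pd.DataFrame(rows)


@_stage("io")
def _load(config: PipelineConfig, log: list[str]) -> list[io.AEReport]:
    bundle = io.read_tables(config.demo, config.drug, config.reac, config.hist)
    reports = io.integrate_reports(bundle)
    pr = bundle.parse_report
    log.append(f"io: {len(reports)} integrated reports "
               f"({pr.duplicate_demo_rows} superseded versions, "
               f"orphans dropped: {pr.dropped_orphans or 0}, coercions: {pr.coerced or 0})")
    reports = io.filter_suspected(reports)
    log.append("io: drug lists restricted to suspected role")
    return reports


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the configured stages and write one CSV per output table.

    Returns the mapping of output name to file path; a ``run_log.txt`` with
    the stage-by-stage exclusion counts is always written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        outputs[name] = path

    reports = _load(config, log)
    registry = (
        fm.load_formulary(config.formulary) if config.formulary else fm.example_formulary()
    )
    event = lambda r: io.flag_dild(r, config.pt_code)
    group_of = {r.case_id: fm.classify_group(r, registry) for r in reports}
    profiles = {r.case_id: fm.report_daily_intake(r, registry) for r in reports}
    n_mixed = sum(1 for g in group_of.values() if g == "MIXED")
    herbal = [r for r in reports if group_of[r.case_id] not in ("NONE",)]
    log.append(f"formulary: {len(herbal)} herbal reports "
               f"({n_mixed} MIXED excluded from group-level counts)")

    if config.do_signals:
        _signals(config, reports, registry, group_of, event, emit, log)
    if config.do_model or config.do_match:
        frame = _dose_frame(reports, group_of, profiles, event, log)
    if config.do_model:
        _model(config, frame, emit, log)
    if config.do_match:
        _match(config, frame, emit, log)
    if config.do_tto:
        _tto(config, reports, registry, group_of, event, emit, log)
    if config.do_history:
        hist = tabulate_history(
            [r for r in reports if group_of[r.case_id] in fm.GROUPS],
            lambda r: group_of[r.case_id], event, config.others_cutoff,
        )
        emit("history_by_group", hist)
        log.append(f"history: {len(hist)} disease rows")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    outputs["run_log"] = out / "run_log.txt"
    return outputs


@_stage("disproportionality")
def _signals(config, reports, registry, group_of, event, emit, log) -> None:
    signals = []
    for grp in fm.GROUPS:
        tab = dp.build_contingency(
            reports, lambda r, g=grp: group_of[r.case_id] == g, event, label=grp
        )
        if tab.a + tab.b == 0:
            continue
        dp.compute_ror(tab)
        dp.detect_signal(tab, config.min_cases)
        signals.append(tab)
    for product in sorted(registry):
        tab = dp.build_contingency(
            reports,
            lambda r, p=product: any(
                d.name == p and d.role == "suspected" for d in r.drugs
            ),
            event, label=product,
        )
        if tab.a + tab.b == 0:
            continue
        dp.compute_ror(tab)
        dp.detect_signal(tab, config.min_cases)
        signals.append(tab)
    emit("signals_products_groups", dp.signal_table(signals))

    herbal_exposed = lambda r: group_of[r.case_id] in fm.GROUPS
    sex_subset, excl = io.demographic_subset(reports, {"sex"})
    log.append(f"signals: sex subset excludes {excl['missing_sex']} reports")
    by_sex = dp.stratified_signals(
        sex_subset, lambda r: r.sex, herbal_exposed, event, min_cases=config.min_cases
    )
    age_subset, excl = io.demographic_subset(reports, {"age"})
    log.append(f"signals: age subset excludes {excl['missing_age']} reports")
    by_age = dp.stratified_signals(
        age_subset, lambda r: r.age_decade, herbal_exposed, event,
        min_cases=config.min_cases,
    )
    emit("signals_sex_age", dp.signal_table(by_sex + by_age))
    log.append(f"signals: {len(by_sex)} sex strata, {len(by_age)} age strata")


@_stage("analysis_set")
def _dose_frame(reports, group_of, profiles, event, log) -> pd.DataFrame:
    rows = []
    for r in reports:
        if group_of[r.case_id] == "NONE":
            continue
        p = profiles[r.case_id]
        a = md.age_indicator(r.age_decade)
        if (r.sex is None or a is None or r.reporting_year is None
                or p.sr_g_per_day is None):
            continue
        rows.append(
            {
                "case_id": r.case_id,
                "Y": float(r.reporting_year - 2013),
                "D1": p.sr_g_per_day, "D2": p.pt_g_per_day, "D_BR": p.br_g_per_day,
                "S": 1.0 if r.sex == "male" else 0.0, "A": a,
                "outcome": int(event(r)),
            }
        )
    frame = pd.DataFrame(rows)
    log.append(f"analysis set: {len(frame)} dose- and demographics-complete herbal reports")
    if len(frame):
        frame["const"] = 1.0
        frame["D1:A"] = frame.D1 * frame.A
        frame["D1:D2"] = frame.D1 * frame.D2
    return frame


@_stage("modeling")
def _model(config, frame, emit, log) -> None:
    if len(frame) < 50 or frame.outcome.nunique() < 2:
        log.append("modeling: analysis set too small; skipped")
        return
    terms = ["Y", "D1", "D2", "S", "A", "D1:A", "D1:D2"]
    full = md.fit_logistic(frame, frame.outcome, ["const"] + terms)
    selected = md.stepwise_select(terms, frame, frame.outcome, config.stepwise_alpha)
    reduced_terms = [t for t in selected.terms if t != "Y"]
    year_p = None
    if "Y" in selected.terms:
        year_p = md.lrt(selected, md.fit_logistic(frame, frame.outcome, reduced_terms))
    tab = selected.summary_frame()
    combos = {"D1:A": ["D1", "A", "D1:A"], "D1:D2": ["D1", "D2", "D1:D2"]}
    adj_rows = []
    for t in selected.terms:
        if t == "const":
            continue
        names = combos.get(t, t) if set(combos.get(t, [t])) <= set(selected.terms) else t
        orv, lo, hi = md.adjusted_or(selected, names)
        adj_rows.append({"term": t, "adjusted_ror": orv,
                         "adj_ci_low": lo, "adj_ci_high": hi})
    tab = tab.merge(pd.DataFrame(adj_rows), on="term", how="left")
    emit("model_multivariate", tab)
    log.append(
        f"modeling: stepwise kept {selected.terms}"
        + (f"; reporting-year LRT p = {year_p:.4f}" if year_p is not None else "")
    )

    dr_rows, roc_rows, curve_frames = [], [], []
    for crude, col in [("SR", "D1"), ("BR", "D_BR"), ("PT", "D2")]:
        x = frame[col].to_numpy()
        if np.ptp(x) == 0 or frame.outcome.nunique() < 2:
            continue
        fit, curve = md.fit_dose_response(x, frame.outcome)
        curve.insert(0, "crude", crude)
        curve_frames.append(curve)
        lo, hi = fit.wald_ci("D")
        roc = md.roc_analysis(x, frame.outcome)
        dr_rows.append(
            {"crude": crude, "slope": fit.coef("D"), "slope_ci_low": lo,
             "slope_ci_high": hi, "crude_ror_per_g": np.exp(fit.coef("D")),
             "ror_ci_low": np.exp(lo), "ror_ci_high": np.exp(hi),
             "auc": roc.auc, "cutoff_g_per_day": roc.cutoff}
        )
        roc_rows.append(
            pd.DataFrame({"crude": crude, "fpr": roc.points[:, 0], "tpr": roc.points[:, 1]})
        )
    emit("dose_response", pd.DataFrame(dr_rows))
    if curve_frames:
        emit("dose_response_curves", pd.concat(curve_frames, ignore_index=True))
    if roc_rows:
        emit("roc_points", pd.concat(roc_rows, ignore_index=True))
    log.append(f"modeling: dose-response fit for {len(dr_rows)} crude drugs")


@_stage("ps_matching")
def _match(config, frame, emit, log) -> None:
    if len(frame) < 100:
        log.append("ps_matching: analysis set too small; skipped")
        return
    covmap = {"SR": ("D1", ["S", "A", "D_BR", "D2"]),
              "BR": ("D_BR", ["S", "A", "D1", "D2"]),
              "PT": ("D2", ["S", "A", "D1", "D_BR"])}
    rows, bal_frames = [], []
    for crude, (col, covs) in covmap.items():
        exposed = (frame[col] > 0).to_numpy()
        if exposed.sum() < 10 or (~exposed).sum() < 10:
            continue
        try:
            scores, fit, auc = psm.estimate_ps(frame, exposed.astype(int), covs)
            cohort = psm.match_caliper(scores, exposed, config.caliper_mult, config.seed)
        except ValueError as exc:
            log.append(f"ps_matching: {crude}: {exc}")
            continue
        if not cohort.pairs:
            log.append(f"ps_matching: {crude}: no pairs within caliper")
            continue
        ev = frame.outcome.to_numpy().astype(bool)
        crude_tab = dp.compute_ror(dp.ContingencySignal(
            a=int(ev[exposed].sum()), b=int((~ev)[exposed].sum()),
            c=int(ev[~exposed].sum()), d=int((~ev)[~exposed].sum()), label=crude))
        matched = psm.matched_ror(cohort, ev)
        kinds = {"S": "binary", "A": "binary"}
        bal = psm.balance_table(
            frame, exposed, cohort,
            {c: kinds.get(c, "continuous") for c in covs},
        )
        bal.insert(0, "crude", crude)
        bal_frames.append(bal)
        rows.append(
            {"crude": crude, "ps_auc": auc, "n_pairs": len(cohort.pairs),
             "caliper_logit": cohort.caliper,
             "ror_before": crude_tab.ror, "before_ci_low": crude_tab.ci_low,
             "before_ci_high": crude_tab.ci_high,
             "ror_after": matched.ror, "after_ci_low": matched.ci_low,
             "after_ci_high": matched.ci_high,
             "max_smd_after": max(cohort.smd_after.values())}
        )
        log.append(f"ps_matching: {crude}: {len(cohort.pairs)} pairs, AUC {auc:.3f}")
    emit("ps_matched_ror", pd.DataFrame(rows))
    if bal_frames:
        emit("ps_balance", pd.concat(bal_frames, ignore_index=True))


@_stage("time_to_onset")
def _tto(config, reports, registry, group_of, event, emit, log) -> None:
    samples = []
    for product in sorted(registry):
        samples.append(tto.extract_durations(
            reports, product, event, config.window_days
        ))
    for grp in fm.GROUPS:
        names = [p for p, e in registry.items() if e.group == grp]
        if not names:
            continue
        samples.append(tto.extract_durations(
            reports, lambda r, g=grp: group_of[r.case_id] == g, event,
            config.window_days, drug_names=names, label=grp,
        ))
    emit("time_to_onset", tto.onset_summary_table(samples))
    km_frames = []
    for s in samples:
        if s.n > tto.MIN_WEIBULL_N:
            curve = tto.km_curve(s)
            curve.insert(0, "label", s.label)
            km_frames.append(curve)
    if km_frames:
        emit("km_curves", pd.concat(km_frames, ignore_index=True))
    log.append(f"time_to_onset: {sum(1 for s in samples if s.n > tto.MIN_WEIBULL_N)} "
               f"labels with > {tto.MIN_WEIBULL_N} cases")
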