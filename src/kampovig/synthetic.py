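"""Synthetic JADER-dialect spontaneous-report data.

Emulates the four-table relational structure of the Japanese Adverse Drug
Event Report database (demographics, drugs, adverse events, primary illness)
with configurable drug-event association strength, demographic mix, dose
distributions, Weibull onset-time structure and missingness, so every
downstream analysis stage can be exercised without the public download.

The event model is logistic: for each report,

    log-odds(event) = logit(background_event_rate)
                      + sum over exposed drugs of log(odds multiplier)

so the realized reporting odds ratio of a drug converges to its configured
multiplier as the number of reports grows. Onset dates are the index drug's
start date plus a draw from that drug's Weibull(alpha, beta), rounded to
whole days with a minimum of 1. The index drug of a report is its first
exposed catalog drug; when several catalog drugs co-occur the other drugs'
measured durations are contaminated by the index drug's clock, so per-drug
onset-distribution checks should use single-drug configurations.

Two compact cohort simulators (:func:`simulate_covariate_outcome`,
:func:`simulate_confounded_cohort`) generate analysis-ready covariate frames
with known ground truth for logistic-recovery and matching studies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrugSpec",
    "SimConfig",
    "DEFAULT_DIALECT",
    "generate_frames",
    "generate_tables",
    "simulate_covariate_outcome",
    "simulate_confounded_cohort",
]

TARGET_PT_CODE = "10022611"
TARGET_PT_NAME = "interstitial lung disease"

# background adverse events assigned to non-case reports
_OTHER_PTS = [
    ("10028813", "nausea"),
    ("10019211", "hepatic function abnormal"),
    ("10037844", "rash"),
    ("10012735", "diarrhoea"),
]

_DISEASES = [
    "hypertension",
    "constipation",
    "diabetes",
    "hyperlipidemia",
    "insomnia",
    "asthma",
    "dementia",
    "gastro esophageal reflux disease",
]

AGE_DECADES = ["10s", "20s", "30s", "40s", "50s", "60s", "70s", "80s or older"]

#: default column names of the emitted tables (JADER dialect, snake_case)
DEFAULT_DIALECT: dict[str, dict[str, str]] = {
    "demo": {"case_id": "case_id", "sex": "sex", "age": "age", "reporting_year": "reporting_year"},
    "drug": {
        "case_id": "case_id",
        "drug_name": "drug_name",
        "role_code": "role_code",
        "daily_dose_g": "daily_dose_g",
        "start_date": "start_date",
    },
    "reac": {
        "case_id": "case_id",
        "pt_code": "pt_code",
        "pt_name": "pt_name",
        "onset_date": "onset_date",
    },
    "hist": {"case_id": "case_id", "disease_name": "disease_name"},
}

_EXTRACT_START = dt.date(2004, 4, 1)
_EXTRACT_DAYS = 6900  # ~April 2004 .. March 2023


@dataclass
class DrugSpec:
    """One catalog drug: exposure frequency, event association, dosing, onset.

    ``odds_multiplier`` is the target reporting odds ratio; ``dose_support``
    and ``dose_probs`` define a finite grams-per-day distribution for the
    emitted daily-dose string; ``onset_alpha``/``onset_beta`` are the Weibull
    scale (days) and shape of the onset-time distribution.
    """

    name: str
    exposure_prob: float
    odds_multiplier: float
    dose_support: tuple[float, ...] = (2.5, 5.0, 7.5)
    dose_probs: tuple[float, ...] = (0.2, 0.3, 0.5)
    onset_alpha: float = 40.0
    onset_beta: float = 1.36

    def validate(self) -> None:
        if not 0.0 < self.exposure_prob < 1.0:
            raise ValueError(f"drug {self.name!r}: exposure_prob must be in (0,1)")
        if self.odds_multiplier <= 0:
            raise ValueError(f"drug {self.name!r}: odds_multiplier must be > 0")
        if len(self.dose_support) != len(self.dose_probs) or not self.dose_support:
            raise ValueError(f"drug {self.name!r}: dose_support/dose_probs mismatch")
        if any(p < 0 for p in self.dose_probs) or abs(sum(self.dose_probs) - 1) > 1e-9:
            raise ValueError(f"drug {self.name!r}: dose_probs must be a distribution")
        if self.onset_alpha <= 0 or self.onset_beta <= 0:
            raise ValueError(f"drug {self.name!r}: onset_weibull parameters must be > 0")


@dataclass
class SimConfig:
    """Study conditions for one synthetic JADER-like dataset.

    Defaults describe a medium database (50,000 reports) with the DIILD
    background reporting rate of the public extract (36,745/830,079 = 0.044)
    and a three-drug catalog planting one strong, one moderate and one null
    association. Identical config + seed reproduces byte-identical files.
    """

    n_reports: int = 50_000
    background_event_rate: float = 0.044
    drug_catalog: Sequence[DrugSpec] = field(
        default_factory=lambda: [
            DrugSpec("Saireito", 0.010, 8.0),
            DrugSpec("Bofutsushosan", 0.012, 5.0, dose_support=(3.75, 7.5), dose_probs=(0.4, 0.6)),
            DrugSpec("Hangeshashinto", 0.010, 4.0),
            DrugSpec("Yokukansan", 0.020, 2.0, onset_alpha=60.0, onset_beta=1.0),
            DrugSpec("Rikkunshito", 0.015, 1.5, onset_alpha=55.0, onset_beta=1.1),
            DrugSpec("Kamishoyosan", 0.020, 1.0, onset_alpha=50.0, onset_beta=0.9),
        ]
    )
    sex_mix: float = 0.45  # probability male
    age_decade_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "10s": 2, "20s": 5, "30s": 8, "40s": 12, "50s": 16,
            "60s": 20, "70s": 22, "80s or older": 15,
        }
    )
    missing_sex_rate: float = 0.1
    missing_age_rate: float = 0.1
    missing_date_rate: float = 0.2
    duplicate_rate: float = 0.02
    concomitant_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be a positive integer")
        if not 0.0 < self.background_event_rate < 1.0:
            raise ValueError("background_event_rate must be in (0,1)")
        if not 0.0 <= self.sex_mix <= 1.0:
            raise ValueError("sex_mix must be in [0,1]")
        for rate in ("missing_sex_rate", "missing_age_rate", "missing_date_rate",
                     "duplicate_rate", "concomitant_rate"):
            v = getattr(self, rate)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{rate} must be in [0,1)")
        w = self.age_decade_weights
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("age_decade_weights must be nonnegative and not all zero")
        unknown = set(w) - set(AGE_DECADES) - {"unknown"}
        if unknown:
            raise ValueError(f"age_decade_weights has unknown keys: {sorted(unknown)}")
        names = [d.name for d in self.drug_catalog]
        if len(names) != len(set(names)):
            raise ValueError("drug_catalog contains duplicate drug names")
        for d in self.drug_catalog:
            d.validate()


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _partial_date(date: dt.date, rng: np.random.Generator) -> str:
    # JADER's partial-date dialect: year-month or year-only strings
    return date.strftime("%Y-%m") if rng.random() < 0.5 else date.strftime("%Y")


def generate_frames(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Generate the four tables in memory.

    One RNG stream per table (demo/drug/reac/hist), all derived from
    ``config.seed``, so perturbing the content of one table does not shift
    the randomness of the others.
    """
    config.validate()
    streams = {
        name: np.random.default_rng(np.random.SeedSequence((config.seed, k)))
        for k, name in enumerate(["demo", "drug", "reac", "hist"])
    }
    n = config.n_reports
    rng_demo, rng_drug, rng_reac, rng_hist = (
        streams["demo"], streams["drug"], streams["reac"], streams["hist"]
    )

    case_ids = [f"C{i:08d}" for i in range(1, n + 1)]

    # --- demographics -----------------------------------------------------
    male = rng_demo.random(n) < config.sex_mix
    sex = np.where(male, "male", "female").astype(object)
    sex[rng_demo.random(n) < config.missing_sex_rate] = "unknown"

    decades = [k for k in config.age_decade_weights if k in AGE_DECADES]
    wts = np.array([config.age_decade_weights[k] for k in decades], float)
    age = rng_demo.choice(decades, size=n, p=wts / wts.sum()).astype(object)
    miss_age = rng_demo.random(n) < config.missing_age_rate
    sentinel = np.where(rng_demo.random(n) < 0.5, "unknown", "aged")
    age[miss_age] = sentinel[miss_age]

    # --- drug exposures, doses, start dates -------------------------------
    catalog = list(config.drug_catalog)
    exposed = np.column_stack(
        [rng_drug.random(n) < d.exposure_prob for d in catalog]
    ) if catalog else np.zeros((n, 0), bool)
    doses = np.column_stack(
        [rng_drug.choice(d.dose_support, size=n, p=d.dose_probs) for d in catalog]
    ) if catalog else np.zeros((n, 0))
    start_offsets = rng_drug.integers(0, _EXTRACT_DAYS, size=n)
    start_dates = [_EXTRACT_START + dt.timedelta(days=int(o)) for o in start_offsets]
    reporting_year = np.array([d.year for d in start_dates])
    concomitant = rng_drug.random(n) < config.concomitant_rate
    drop_start = rng_drug.random(n) < config.missing_date_rate
    partial_roll = rng_drug  # consumed lazily per emitted partial date

    # --- events -----------------------------------------------------------
    base = _logit(config.background_event_rate)
    log_mult = np.array([np.log(d.odds_multiplier) for d in catalog])
    logodds = base + (exposed @ log_mult if catalog else 0.0)
    p_event = 1.0 / (1.0 + np.exp(-logodds))
    event = rng_reac.random(n) < p_event
    other_idx = rng_reac.integers(0, len(_OTHER_PTS), size=n)
    drop_onset = rng_reac.random(n) < config.missing_date_rate
    # onset delay from the index (first exposed) drug's Weibull; background
    # delay for unexposed reports
    delays = np.empty(n)
    index_drug = np.full(n, -1)
    for i in range(n):
        j = int(np.argmax(exposed[i])) if catalog and exposed[i].any() else -1
        index_drug[i] = j
        a, b = (catalog[j].onset_alpha, catalog[j].onset_beta) if j >= 0 else (60.0, 1.0)
        delays[i] = a * rng_reac.weibull(b)
    delays = np.maximum(1, np.rint(delays)).astype(int)

    # --- history ----------------------------------------------------------
    n_hist = rng_hist.integers(0, 3, size=n)
    hist_choices = rng_hist.integers(0, len(_DISEASES), size=int(n_hist.sum()))

    # --- duplicates -------------------------------------------------------
    dup = rng_demo.random(n) < config.duplicate_rate

    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    hpos = 0
    for i in range(n):
        cid = case_ids[i]
        demo = (cid, sex[i], age[i], int(reporting_year[i]))
        start = start_dates[i]
        start_str = (
            _partial_date(start, partial_roll) if drop_start[i] else start.isoformat()
        )
        d_rows = []
        for j, spec in enumerate(catalog):
            if exposed[i, j]:
                d_rows.append((cid, spec.name, "suspected", f"{doses[i, j]:g}", start_str))
        if not d_rows:  # every report names at least one suspected drug
            d_rows.append((cid, "loxoprofen", "suspected", "", start_str))
        if concomitant[i]:
            d_rows.append((cid, "rebamipide", "concomitant", "", start_str))
        if event[i]:
            code, name = TARGET_PT_CODE, TARGET_PT_NAME
        else:
            code, name = _OTHER_PTS[other_idx[i]]
        onset = start + dt.timedelta(days=int(delays[i]))
        onset_str = (
            _partial_date(onset, partial_roll) if drop_onset[i] else onset.isoformat()
        )
        r_rows = [(cid, code, name, onset_str)]
        h_rows = []
        for _ in range(int(n_hist[i])):
            h_rows.append((cid, _DISEASES[hist_choices[hpos]]))
            hpos += 1
        reps = 2 if dup[i] else 1
        for _ in range(reps):
            demo_rows.append(demo)
            drug_rows.extend(d_rows)
            reac_rows.extend(r_rows)
            hist_rows.extend(h_rows)

    dial = DEFAULT_DIALECT
    return {
        "demo": pd.DataFrame(demo_rows, columns=list(dial["demo"].values())),
        "drug": pd.DataFrame(drug_rows, columns=list(dial["drug"].values())),
        "reac": pd.DataFrame(reac_rows, columns=list(dial["reac"].values())),
        "hist": pd.DataFrame(hist_rows, columns=list(dial["hist"].values())),
    }


def generate_tables(
    config: SimConfig,
    out_dir: str | Path,
    dialect: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, Path]:
    """Write the four CSV tables (demo, drug, reac, hist) to ``out_dir``.

    ``dialect`` renames columns (canonical name -> file column name);
    defaults to the english snake_case dialect. Returns the file paths.
    """
    frames = generate_frames(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in frames.items():
        if dialect is not None:
            df = df.rename(
                columns={DEFAULT_DIALECT[name][k]: v for k, v in dialect[name].items()}
            )
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# compact cohort simulators with known ground truth
# ---------------------------------------------------------------------------

EQ1_TERMS = ["const", "Y", "D1", "D2", "S", "A", "D1:A", "D1:D2"]


def simulate_covariate_outcome(
    n: int,
    betas: Mapping[str, float],
    seed: int,
    d_zero_prob: float = 0.5,
    d_gamma: tuple[float, float] = (2.0, 0.8),
) -> pd.DataFrame:
    """Covariate frame + outcome from a known multivariate logistic model.

    Terms: const, Y (reporting year centered on 2013, integer in [-9, 10]),
    D1 and D2 (zero-inflated gamma daily intakes in g/day), S (male
    indicator), A (age >= 60 indicator), and the derived interactions D1:A
    and D1:D2. Any term missing from ``betas`` has true coefficient 0.
    """
    rng = np.random.default_rng(seed)
    Y = rng.integers(-9, 11, size=n)
    shape, scale = d_gamma
    D1 = np.where(rng.random(n) < d_zero_prob, 0.0, rng.gamma(shape, scale, n))
    D2 = np.where(rng.random(n) < d_zero_prob, 0.0, rng.gamma(shape, scale, n))
    S = (rng.random(n) < 0.4).astype(float)
    A = (rng.random(n) < 0.6).astype(float)
    X = {
        "const": np.ones(n), "Y": Y.astype(float), "D1": D1, "D2": D2,
        "S": S, "A": A, "D1:A": D1 * A, "D1:D2": D1 * D2,
    }
    eta = sum(betas.get(t, 0.0) * X[t] for t in EQ1_TERMS)
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    out = pd.DataFrame({t: X[t] for t in EQ1_TERMS})
    out["outcome"] = y.astype(int)
    return out


def simulate_confounded_cohort(
    n: int,
    seed: int,
    direct_log_or: float = 0.0,
    confounding: float = 1.2,
) -> pd.DataFrame:
    """Cohort where exposure and event share demographic/dose confounders.

    Age >= 60, male sex and the two co-intake variables shift the exposure
    log-odds by ``confounding`` times a fixed loading, and independently
    shift the event log-odds; the exposure's direct effect on the event is
    exactly ``direct_log_or``. Columns: male, age60, co1_g, co2_g, exposed,
    event. With ``direct_log_or=0`` the crude ROR is biased away from 1 by
    the confounding while the true conditional effect is null.
    """
    rng = np.random.default_rng(seed)
    male = (rng.random(n) < 0.4).astype(float)
    age60 = (rng.random(n) < 0.55).astype(float)
    co1 = np.where(rng.random(n) < 0.5, 0.0, rng.gamma(2.0, 1.0, n))
    co2 = np.where(rng.random(n) < 0.5, 0.0, rng.gamma(2.0, 1.0, n))
    eta_x = -1.8 + confounding * (0.9 * age60 + 0.5 * male + 0.35 * co1 + 0.25 * co2)
    exposed = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_x))
    eta_y = -2.2 + 0.8 * age60 + 0.5 * male + 0.25 * co1 + 0.2 * co2
    eta_y = eta_y + direct_log_or * exposed
    event = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_y))
    return pd.DataFrame(
        {
            "male": male, "age60": age60, "co1_g": co1, "co2_g": co2,
            "exposed": exposed.astype(int), "event": event.astype(int),
        }
    )
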