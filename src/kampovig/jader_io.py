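"""Reading and integrating JADER-dialect four-table CSV extracts.

The spontaneous-report database ships as four relational CSV tables keyed by
a case identifier: patient demographics, drug records (with role codes,
daily dose strings and administration start dates), adverse events (MedDRA
preferred terms with onset dates) and primary-illness history. This module
parses the tables, integrates them into one :class:`AEReport` per case, and
applies the cleaning rules of the published workflow: last-version-wins for
re-submitted cases, orphan child rows dropped with a logged count,
restriction to "suspected" drug records, and exclusion of reports with
incomplete demographics ("missing", "unknown" and "aged" entries).

Unparseable dose and date cells become missing values, never silent drops; a
parse report counts every coerced cell.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic import DEFAULT_DIALECT

__all__ = [
    "DrugUse",
    "EventOccurrence",
    "AEReport",
    "TableBundle",
    "ParseReport",
    "read_tables",
    "integrate_reports",
    "filter_suspected",
    "demographic_subset",
    "flag_dild",
    "flat_table",
    "bundle_from_reports",
]

TARGET_PT_CODE = "10022611"
TARGET_PT_NAME = "interstitial lung disease"

#: raw age strings -> canonical decade; sentinels map to missing (None)
_AGE_MAP = {
    "10s": "<20", "20s": "20s", "30s": "30s", "40s": "40s", "50s": "50s",
    "60s": "60s", "70s": "70s", "80s or older": "80s+", "80s+": "80s+",
    "<20": "<20",
}
_AGE_SENTINELS = {"unknown", "aged", ""}
_ROLE_MAP = {"suspected": "suspected", "concomitant": "concomitant", "interacting": "interacting"}

_DOSE_UNIT_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*[gｇ]\s*$")
_FULL_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass
class DrugUse:
    name: str
    role: str  # suspected | concomitant | interacting
    daily_dose_g: float | None = None  # grams of formulation per day
    start_date: dt.date | None = None  # None = missing or partial date

    def __post_init__(self) -> None:
        if self.daily_dose_g is not None and self.daily_dose_g < 0:
            raise ValueError("daily_dose_g must be nonnegative")


@dataclass
class EventOccurrence:
    pt_code: str = ""
    pt_name: str = ""
    onset_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.pt_code and not self.pt_name:
            raise ValueError("an event needs a PT code or a PT name")


@dataclass
class AEReport:
    """One integrated spontaneous report (one per case id)."""

    case_id: str
    sex: str | None = None  # "male" | "female" | None (missing/unknown)
    age_decade: str | None = None  # "<20".."80s+" | None (missing/unknown/aged)
    reporting_year: int | None = None
    drugs: list[DrugUse] = field(default_factory=list)
    events: list[EventOccurrence] = field(default_factory=list)
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")


@dataclass
class ParseReport:
    """Counts of coerced or dropped cells per table/field."""

    coerced: dict[str, int] = field(default_factory=dict)
    dropped_orphans: dict[str, int] = field(default_factory=dict)
    duplicate_demo_rows: int = 0

    def bump(self, key: str, n: int = 1) -> None:
        self.coerced[key] = self.coerced.get(key, 0) + n


@dataclass
class TableBundle:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame
    parse_report: ParseReport = field(default_factory=ParseReport)


def _parse_dose(cell: object, report: ParseReport) -> float | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        pass
    m = _DOSE_UNIT_RE.match(s)
    if m:  # unit-suffixed number such as "2.5g"
        report.bump("drug.daily_dose_g.unit_stripped")
        return float(m.group(1))
    report.bump("drug.daily_dose_g.unparseable")
    return None


def _parse_date(cell: object, key: str, report: ParseReport) -> dt.date | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    if not s:
        return None
    if _FULL_DATE_RE.match(s):
        try:
            return dt.date.fromisoformat(s)
        except ValueError:
            report.bump(f"{key}.invalid")
            return None
    # partial dates (YYYY or YYYY-MM) carry no day resolution -> missing
    report.bump(f"{key}.partial_or_invalid")
    return None


def read_tables(
    demo: str | Path,
    drug: str | Path,
    reac: str | Path,
    hist: str | Path,
    dialect: Mapping[str, Mapping[str, str]] | None = None,
) -> TableBundle:
    """Read the four CSV tables and coerce typed columns.

    ``dialect`` maps canonical column names to the file's column names per
    table; the default is the english snake_case dialect. A missing required
    column raises with the file and column named. Unparseable dose/date
    cells become missing and are counted in the bundle's parse report.
    """
    dialect = dialect or DEFAULT_DIALECT
    report = ParseReport()
    frames: dict[str, pd.DataFrame] = {}
    for name, path in [("demo", demo), ("drug", drug), ("reac", reac), ("hist", hist)]:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        colmap = dialect[name]
        missing = [v for v in colmap.values() if v not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} ({path}): missing column(s) {missing}")
        df = df.rename(columns={v: k for k, v in colmap.items()})[list(colmap)]
        frames[name] = df

    d = frames["drug"]
    d["daily_dose_g"] = [_parse_dose(x, report) for x in d["daily_dose_g"]]
    d["start_date"] = [_parse_date(x, "drug.start_date", report) for x in d["start_date"]]
    r = frames["reac"]
    r["onset_date"] = [_parse_date(x, "reac.onset_date", report) for x in r["onset_date"]]
    return TableBundle(frames["demo"], d, r, frames["hist"], report)


def _canonical_sex(raw: str) -> str | None:
    s = raw.strip().lower()
    return s if s in ("male", "female") else None


def _canonical_age(raw: str) -> str | None:
    s = raw.strip().lower()
    if s in _AGE_SENTINELS:
        return None
    return _AGE_MAP.get(raw.strip(), None)


def integrate_reports(bundle: TableBundle) -> list[AEReport]:
    """One :class:`AEReport` per distinct case id.

    When a case id appears several times in the demographics table the last
    occurrence in file order wins (re-submitted reports supersede earlier
    versions). Exact duplicate child rows are collapsed. Child rows whose
    case id never appears in demographics are orphans; they are dropped and
    counted in the bundle's parse report.
    """
    rep = bundle.parse_report
    demo = bundle.demo
    dup = int(demo["case_id"].duplicated().sum())
    rep.duplicate_demo_rows += dup
    demo = demo.drop_duplicates(subset="case_id", keep="last")
    known = set(demo["case_id"])

    reports: dict[str, AEReport] = {}
    for row in demo.itertuples(index=False):
        year_raw = str(getattr(row, "reporting_year", "")).strip()
        year = int(float(year_raw)) if year_raw else None
        reports[row.case_id] = AEReport(
            case_id=row.case_id,
            sex=_canonical_sex(str(row.sex)),
            age_decade=_canonical_age(str(row.age)),
            reporting_year=year,
        )

    def children(df: pd.DataFrame, name: str) -> pd.DataFrame:
        orphans = ~df["case_id"].isin(known)
        if orphans.any():
            rep.dropped_orphans[name] = rep.dropped_orphans.get(name, 0) + int(orphans.sum())
        return df[~orphans].drop_duplicates()

    for row in children(bundle.drug, "drug").itertuples(index=False):
        role = _ROLE_MAP.get(str(row.role_code).strip().lower(), "concomitant")
        dose = row.daily_dose_g
        dose = None if dose is None or pd.isna(dose) else float(dose)
        start = row.start_date if isinstance(row.start_date, dt.date) else None
        reports[row.case_id].drugs.append(
            DrugUse(str(row.drug_name), role, dose, start)
        )
    for row in children(bundle.reac, "reac").itertuples(index=False):
        onset = row.onset_date if isinstance(row.onset_date, dt.date) else None
        reports[row.case_id].events.append(
            EventOccurrence(str(row.pt_code).strip(), str(row.pt_name), onset)
        )
    for row in children(bundle.hist, "hist").itertuples(index=False):
        reports[row.case_id].history.append(str(row.disease_name))
    return list(reports.values())


def filter_suspected(reports: Iterable[AEReport]) -> list[AEReport]:
    """Restrict each report's drug list to role = suspected.

    Reports left with zero suspected drugs are retained: they still belong
    to the whole-database background of the contingency tables.
    """
    out = []
    for r in reports:
        out.append(
            AEReport(
                case_id=r.case_id,
                sex=r.sex,
                age_decade=r.age_decade,
                reporting_year=r.reporting_year,
                drugs=[d for d in r.drugs if d.role == "suspected"],
                events=list(r.events),
                history=list(r.history),
            )
        )
    return out


def demographic_subset(
    reports: Sequence[AEReport], require: set[str]
) -> tuple[list[AEReport], dict[str, int]]:
    """Drop reports whose required demographic fields are missing.

    ``require`` is a subset of {"sex", "age"}. Missing covers empty,
    "unknown" and "aged" source strings (already canonicalized to None at
    integration). Returns the kept reports plus per-field exclusion counts
    (a report missing both fields counts under each).
    """
    unknown = require - {"sex", "age"}
    if unknown:
        raise ValueError(f"unknown demographic requirement(s): {sorted(unknown)}")
    excluded = {f"missing_{k}": 0 for k in sorted(require)}
    kept = []
    for r in reports:
        bad = False
        if "sex" in require and r.sex is None:
            excluded["missing_sex"] += 1
            bad = True
        if "age" in require and r.age_decade is None:
            excluded["missing_age"] += 1
            bad = True
        if not bad:
            kept.append(r)
    return kept, excluded


def flag_dild(report: AEReport, pt_code: str = TARGET_PT_CODE) -> bool:
    """True iff any event matches the target PT code (or name fallback)."""
    for e in report.events:
        if e.pt_code == pt_code:
            return True
        if not e.pt_code and e.pt_name.strip().lower() == TARGET_PT_NAME:
            return True
    return False


def flat_table(reports: Iterable[AEReport]) -> pd.DataFrame:
    """Audit view: one row per report with serialized drug/event lists."""
    rows = []
    for r in reports:
        rows.append(
            {
                "case_id": r.case_id,
                "sex": r.sex or "",
                "age_decade": r.age_decade or "",
                "reporting_year": r.reporting_year,
                "drugs": "; ".join(
                    f"{d.name}[{d.role}]"
                    + (f" {d.daily_dose_g:g}g/d" if d.daily_dose_g is not None else "")
                    for d in r.drugs
                ),
                "events": "; ".join(e.pt_name or e.pt_code for e in r.events),
                "history": "; ".join(r.history),
            }
        )
    return pd.DataFrame(rows)


def bundle_from_reports(reports: Iterable[AEReport]) -> TableBundle:
    """Re-emit integrated reports as a four-table bundle (for round trips)."""
    demo, drug, reac, hist = [], [], [], []
    back_age = {v: k for k, v in _AGE_MAP.items() if k != v} | {"80s+": "80s or older"}
    for r in reports:
        demo.append(
            (
                r.case_id,
                r.sex or "unknown",
                back_age.get(r.age_decade, r.age_decade) if r.age_decade else "unknown",
                r.reporting_year if r.reporting_year is not None else "",
            )
        )
        for d in r.drugs:
            drug.append((r.case_id, d.name, d.role, d.daily_dose_g, d.start_date))
        for e in r.events:
            reac.append((r.case_id, e.pt_code, e.pt_name, e.onset_date))
        for h in r.history:
            hist.append((r.case_id, h))
    return TableBundle(
        pd.DataFrame(demo, columns=["case_id", "sex", "age", "reporting_year"]),
        pd.DataFrame(drug, columns=["case_id", "drug_name", "role_code", "daily_dose_g", "start_date"]),
        pd.DataFrame(reac, columns=["case_id", "pt_code", "pt_name", "onset_date"]),
        pd.DataFrame(hist, columns=["case_id", "disease_name"]),
    )
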