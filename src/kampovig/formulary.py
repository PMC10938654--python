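"""Kampo formulation compositions and crude-drug exposure profiles.

A Kampo extract product is a granule formulation compounded from several
crude drugs; the registry records, per product, the grams of granule product
in a full daily dose and the grams of each crude drug contained in that full
daily dose. Analyses focus on three crude drugs implicated in interstitial
lung disease: Scutellariae radix (SR, "ogon"), Bupleuri radix (BR, "saiko")
and Pinelliae tuber (PT, "hange").

Each report is classified into the 2^3 = 8 crude-drug exposure groups by the
SR/BR/PT membership of its suspected Kampo products: reports whose Kampo all
share one group keep that group, reports whose Kampo span groups are MIXED
(excluded from group-level counts), reports with no Kampo are NONE. Daily
crude-drug intake scales linearly with the reported product dose:

    crude g/day = crude_content * (daily_dose_g / full_daily_dose_g)

summed over the report's Kampo products.

Compositions vary by manufacturer, so the registry is a data file, never a
constant. The packaged example registry (``data/formulary_example.csv``)
carries plausible placeholder compositions; see ``docs/formulary_schema.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .jader_io import AEReport

__all__ = [
    "CRUDE_DRUGS",
    "GROUPS",
    "FormularyEntry",
    "ExposureProfile",
    "load_formulary",
    "example_formulary",
    "classify_group",
    "report_daily_intake",
]

#: the three crude drugs under analysis, in group-label order
CRUDE_DRUGS = ("SR", "BR", "PT")

#: the seven analyzable exposure groups (the eighth, no SR/BR/PT, is NONE)
GROUPS = ("SR", "BR", "PT", "SR_BR", "SR_PT", "BR_PT", "SR_BR_PT")


def group_label(contains: frozenset[str] | set[str]) -> str:
    """Canonical label for a subset of {SR, BR, PT} ("NONE" when empty)."""
    members = [c for c in CRUDE_DRUGS if c in contains]
    return "_".join(members) if members else "NONE"


@dataclass
class FormularyEntry:
    """One product's composition: crude grams per full daily dose."""

    product_name: str
    full_daily_dose_g: float  # grams of granule product per full daily dose
    crude_content: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.full_daily_dose_g <= 0:
            raise ValueError(
                f"product {self.product_name!r}: full_daily_dose_g must be > 0"
            )
        for crude, grams in self.crude_content.items():
            if grams <= 0:
                raise ValueError(
                    f"product {self.product_name!r}: content of {crude!r} must be > 0"
                )

    @property
    def contains(self) -> frozenset[str]:
        """SR/BR/PT membership derived from the positive crude contents."""
        return frozenset(c for c in CRUDE_DRUGS if self.crude_content.get(c, 0) > 0)

    @property
    def group(self) -> str:
        return group_label(self.contains)


@dataclass
class ExposureProfile:
    """A report's exposure group and daily crude-drug intakes in grams.

    Intakes are ``None`` when the report contains Kampo but every product
    dose is missing (such reports are excluded from dose-based analyses);
    ``dose_complete`` is False whenever any Kampo dose was missing.
    """

    group: str  # one of GROUPS, or "NONE" or "MIXED"
    sr_g_per_day: float | None = 0.0
    br_g_per_day: float | None = 0.0
    pt_g_per_day: float | None = 0.0
    dose_complete: bool = True

    def intake(self, crude: str) -> float | None:
        return {"SR": self.sr_g_per_day, "BR": self.br_g_per_day, "PT": self.pt_g_per_day}[crude]


Formulary = dict[str, FormularyEntry]


def _entries_from_frame(df: pd.DataFrame) -> Formulary:
    required = {"product_name", "full_daily_dose_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"formulary registry: missing column(s) {sorted(missing)}")
    dupes = df["product_name"][df["product_name"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"formulary registry: duplicated product name(s) {sorted(set(dupes))}")
    crude_cols = [c for c in df.columns if c not in required and not c.startswith("#")]
    out: Formulary = {}
    for row in df.to_dict("records"):
        content = {}
        for c in crude_cols:
            v = row[c]
            if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
                continue
            content[c] = float(v)
        entry = FormularyEntry(
            product_name=str(row["product_name"]),
            full_daily_dose_g=float(row["full_daily_dose_g"]),
            crude_content=content,
        )
        out[entry.product_name] = entry
    return out


def load_formulary(path: str | Path) -> Formulary:
    """Load a registry from CSV (columns: product, dose, one per crude drug)
    or JSON (list of entry objects). Nonpositive contents and duplicate
    product names are rejected with the offending rows named."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame(
            [
                {"product_name": r["product_name"],
                 "full_daily_dose_g": r["full_daily_dose_g"],
                 **r.get("crude_content", {})}
                for r in records
            ]
        )
        return _entries_from_frame(df)
    return _entries_from_frame(pd.read_csv(path))


def example_formulary() -> Formulary:
    """The packaged example registry (placeholder compositions)."""
    with resources.files("kampovig.data").joinpath("formulary_example.csv").open() as fh:
        return _entries_from_frame(pd.read_csv(fh))


def _kampo_uses(report: AEReport, formulary: Formulary):
    return [d for d in report.drugs if d.name in formulary]


def classify_group(report: AEReport, formulary: Formulary) -> str:
    """Exposure group of a report from its suspected Kampo drugs.

    All Kampo in one group -> that group; Kampo spanning groups -> "MIXED"
    (two products of different groups are not counted as one group case);
    no resolvable Kampo -> "NONE". Drug names not in the formulary are
    treated as non-Kampo. Permutation-invariant in the drug list.
    """
    groups = {formulary[d.name].group for d in _kampo_uses(report, formulary)}
    groups.discard("NONE")
    if not groups:
        return "NONE"
    if len(groups) > 1:
        return "MIXED"
    return groups.pop()


def report_daily_intake(report: AEReport, formulary: Formulary) -> ExposureProfile:
    """Daily SR/BR/PT intake in grams for one report.

    Per Kampo product: crude g/day = crude_content * (daily_dose_g /
    full_daily_dose_g); contributions are summed across products (additive,
    linear in dose). Missing product doses propagate: if every Kampo dose is
    missing the intakes are ``None``; if some are missing the intake sums
    the dose-complete products and ``dose_complete`` is False.
    """
    group = classify_group(report, formulary)
    uses = _kampo_uses(report, formulary)
    if not uses:
        return ExposureProfile(group=group)
    dosed = [d for d in uses if d.daily_dose_g is not None]
    if not dosed:
        return ExposureProfile(
            group=group, sr_g_per_day=None, br_g_per_day=None,
            pt_g_per_day=None, dose_complete=False,
        )
    totals = dict.fromkeys(CRUDE_DRUGS, 0.0)
    for d in dosed:
        entry = formulary[d.name]
        scale = d.daily_dose_g / entry.full_daily_dose_g
        for crude in CRUDE_DRUGS:
            totals[crude] += entry.crude_content.get(crude, 0.0) * scale
    return ExposureProfile(
        group=group,
        sr_g_per_day=totals["SR"],
        br_g_per_day=totals["BR"],
        pt_g_per_day=totals["PT"],
        dose_complete=len(dosed) == len(uses),
    )
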