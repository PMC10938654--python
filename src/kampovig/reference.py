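"""Published reference counts for the JADER DIILD herbal-medicine analysis.

The April 2004 - April 2023 public JADER extract holds 830,079 spontaneous
reports, of which 36,745 list interstitial lung disease (MedDRA PT code
10022611) and 793,334 do not. The packaged CSV carries the published
per-product, per-crude-drug-group, per-sex and per-age-decade report counts
(total, case, non-case) for the 54 herbal medicines containing Scutellariae
radix (SR), Bupleuri radix (BR) or Pinelliae tuber (PT), together with the
RORs and 95% CI bounds as printed, at one-decimal precision. Counts are the
inputs for recomputation; the printed statistics are regression anchors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .disproportionality import ContingencySignal, contingency_from_margins

DATABASE_TOTAL = 830_079
DATABASE_EVENTS = 36_745  # DIILD case reports in the full database
DATABASE_NONEVENTS = 793_334

#: Subset sizes after removing incomplete demographics from herbal reports.
SEX_SUBSET = {"total": 6845, "case": 1527, "noncase": 5318}
AGE_SUBSET = {"total": 6741, "case": 1505, "noncase": 5236}


def load_reference_counts() -> pd.DataFrame:
    """The packaged reference-count table as a DataFrame.

    Columns: section (group/product/sex/age), label, group, total_n, case_n,
    noncase_n, and the printed ror/ci_low/ci_high (NaN where the published
    table prints a dash, i.e. fewer than 2 cases).
    """
    with resources.files("kampovig.data").joinpath(
        "reference_signal_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def reference_table(row: pd.Series) -> ContingencySignal:
    """2x2 table for one reference row against the database margins."""
    return contingency_from_margins(
        int(row["case_n"]),
        int(row["noncase_n"]),
        DATABASE_EVENTS,
        DATABASE_NONEVENTS,
        label=str(row["label"]),
    )
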