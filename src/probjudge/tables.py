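"""Trial-table schema shared across modules.

A trial table is a pandas DataFrame with one row per estimate triplet.  The
required columns mirror :class:`probjudge.jpd.EstimateTriplet`; synthetic
tables carry additional ground-truth columns prefixed ``truth_`` and verbal
trials carry the raw labels alongside their anchor-mapped numbers.
"""

from __future__ import annotations

import pandas as pd

from .errors import EmptyTableError, SchemaError
from .jpd import FORMS, EstimateTriplet

__all__ = ["REQUIRED_COLUMNS", "validate_table", "triplet_from_row", "iter_triplets"]

REQUIRED_COLUMNS = [
    "participant_id",
    "content_id",
    "form",
    "scale",
    "order",
    "dependence",
    "pA",
    "pB",
    "pConj",
]

_LABEL_DOMAINS = {
    "form": set(FORMS),
    "scale": {"numeric", "verbal"},
    "order": {"conjunction_first", "conjunction_last"},
    "dependence": {"A_increases_B", "A_decreases_B", ""},
}


def validate_table(df: pd.DataFrame, allow_empty: bool = True) -> pd.DataFrame:
    """Validate a trial table against the schema, raising SchemaError with row numbers."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if not allow_empty and df.empty:
        raise EmptyTableError("trial table is empty")
    for col in ("pA", "pB", "pConj"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 100)]
        if len(bad):
            raise SchemaError(
                f"column {col!r} outside [0, 100] or non-numeric at row(s): {list(bad[:5])}"
            )
    for col, domain in _LABEL_DOMAINS.items():
        ok = df[col].fillna("").astype(str).isin(domain)
        bad = df.index[~ok]
        if len(bad):
            raise SchemaError(f"column {col!r} has unknown label(s) at row(s): {list(bad[:5])}")
    return df


def triplet_from_row(row: pd.Series) -> EstimateTriplet:
    """Build an EstimateTriplet from one table row."""
    return EstimateTriplet(
        pA=float(row["pA"]),
        pB=float(row["pB"]),
        pConj=float(row["pConj"]),
        form=str(row["form"]),
        scale=str(row["scale"]),
        order=str(row["order"]),
        participant_id=str(row["participant_id"]),
        content_id=str(row["content_id"]),
        dependence=str(row["dependence"]) if pd.notna(row["dependence"]) else "",
    )


def iter_triplets(df: pd.DataFrame):
    """Yield (index, EstimateTriplet) for each row of a validated table."""
    for idx, row in df.iterrows():
        yield idx, triplet_from_row(row)
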