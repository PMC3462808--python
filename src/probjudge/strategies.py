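"""Classify estimate triplets by the strategy they reflect.

A triplet counts as *multiplicative* when the conjunction does not exceed
either conjunct and lies within ``mult_tol`` percentage points of the product
pA·pB/100 — the two-constraint rule used to score multiplication trials.
Otherwise it counts as *split* when the conjunction lies within ``split_tol``
points of the conjuncts' midpoint (the split-the-difference signature), and
*other* when neither rule applies.  Multiplication takes precedence when both
match.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import EmptyTableError
from .jpd import EstimateTriplet
from .tables import validate_table

__all__ = ["STRATEGY_LABELS", "StrategyRates", "classify", "classify_table", "strategy_rates"]

STRATEGY_LABELS = ("multiplicative", "split", "other")

DEFAULT_MULT_TOL = 5.0  # percentage points, "within 5%" on the 0-100 scale
DEFAULT_SPLIT_TOL = 5.0


@dataclass(frozen=True)
class StrategyRates:
    """Per-strategy proportions, overall and per participant."""

    overall: dict[str, float]
    per_participant: pd.DataFrame  # index participant_id, columns STRATEGY_LABELS
    n_trials: int


def classify(
    t: EstimateTriplet,
    mult_tol: float = DEFAULT_MULT_TOL,
    split_tol: float = DEFAULT_SPLIT_TOL,
) -> str:
    """Label one triplet as multiplicative, split, or other.

    The rule applies to the reported marginals and conjunction whatever the
    problem form: the strategies operate on the judged events as presented.
    """
    if mult_tol < 0 or split_tol < 0:
        raise ValueError("tolerances must be nonnegative")
    a, b, c = t.pA, t.pB, t.pConj
    product = a * b / 100.0
    if c <= a and c <= b and abs(c - product) <= mult_tol:
        return "multiplicative"
    if abs(c - (a + b) / 2.0) <= split_tol:
        return "split"
    return "other"


def classify_table(
    df: pd.DataFrame,
    mult_tol: float = DEFAULT_MULT_TOL,
    split_tol: float = DEFAULT_SPLIT_TOL,
) -> pd.DataFrame:
    """Return a copy of the table with a ``strategy`` column appended."""
    validate_table(df)
    out = df.copy()
    a = out["pA"].astype(float)
    b = out["pB"].astype(float)
    c = out["pConj"].astype(float)
    product = a * b / 100.0
    is_mult = (c <= a) & (c <= b) & ((c - product).abs() <= mult_tol)
    is_split = ~is_mult & ((c - (a + b) / 2.0).abs() <= split_tol)
    out["strategy"] = "other"
    out.loc[is_split, "strategy"] = "split"
    out.loc[is_mult, "strategy"] = "multiplicative"
    return out


def strategy_rates(
    df: pd.DataFrame,
    mult_tol: float = DEFAULT_MULT_TOL,
    split_tol: float = DEFAULT_SPLIT_TOL,
) -> StrategyRates:
    """Proportion of trials per strategy, overall and per participant.

    Raises
    ------
    EmptyTableError
        For an empty table.
    """
    if df.empty:
        raise EmptyTableError("cannot compute strategy rates on an empty table")
    labeled = classify_table(df, mult_tol=mult_tol, split_tol=split_tol)
    counts = labeled["strategy"].value_counts()
    n = len(labeled)
    overall = {lab: float(counts.get(lab, 0)) / n for lab in STRATEGY_LABELS}
    per = (
        labeled.groupby("participant_id")["strategy"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(STRATEGY_LABELS), fill_value=0.0)
    )
    return StrategyRates(overall=overall, per_participant=per, n_trials=n)
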