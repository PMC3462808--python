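"""Competitor conjunction models, fit metrics, concordance, and violation summaries.

Two published single-formula competitors predict P(A&B) from the conjuncts:
the averaging model, (P(A)+P(B))/2, and an averaging-plus-product model.
The two-mechanism mixture predictor combines the split-the-difference midpoint
and the exact product with weight ``w_mult`` on the product; with the weight
taken from the strategy classifier it is the conditional-mean predictor of the
generative model and anchors the model-comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .jpd import count_violations, is_consistent, jpd_from_form
from .tables import iter_triplets, validate_table

__all__ = [
    "ModelFit",
    "predict_fantino",
    "predict_wyer",
    "predict_split",
    "predict_multiplicative",
    "predict_mixture",
    "fit_metrics",
    "kendalls_w",
    "violation_summary",
    "compare_models",
]


@dataclass(frozen=True)
class ModelFit:
    """Goodness of fit: squared Pearson correlation and RMSE (same scale as inputs)."""

    r_squared: float
    rmse: float


def predict_fantino(pA: float, pB: float) -> float:
    """Averaging model: the arithmetic mean of the two conjuncts."""
    return (pA + pB) / 2.0


def predict_wyer(pA: float, pB: float, variant: str = "mean_of_mean_and_product") -> float:
    """Averaging-plus-product model for P(A&B), on the percentage scale.

    The default ``mean_of_mean_and_product`` variant averages the conjuncts'
    mean with their product, ((pA+pB)/2 + pA·pB/100)/2, which stays within
    [0, 100].  The ``literal`` variant evaluates the printed formula string
    pA + pB/2 + pA·pB/100 at face value (clamped to 100); it exceeds 100 for
    moderate inputs and is retained only for auditing.
    """
    if variant == "mean_of_mean_and_product":
        return ((pA + pB) / 2.0 + pA * pB / 100.0) / 2.0
    if variant == "literal":
        return np.minimum(pA + pB / 2.0 + pA * pB / 100.0, 100.0)
    raise ValueError(f"unknown variant: {variant!r}")


def predict_split(pA: float, pB: float) -> float:
    """Split-the-difference prediction: the midpoint of the conjuncts."""
    return (pA + pB) / 2.0


def predict_multiplicative(pA: float, pB: float) -> float:
    """Exact-product prediction on the percentage scale."""
    return pA * pB / 100.0


def predict_mixture(pA: float, pB: float, w_mult: float = 0.3) -> float:
    """Two-mechanism mixture: weight ``w_mult`` on the product, rest on the midpoint."""
    if not 0.0 <= w_mult <= 1.0:
        raise ValueError("w_mult must lie in [0, 1]")
    return w_mult * predict_multiplicative(pA, pB) + (1.0 - w_mult) * predict_split(pA, pB)


def fit_metrics(predicted, observed) -> ModelFit:
    """R² (squared Pearson correlation) and RMSE between two equal-length series.

    Raises
    ------
    ValueError
        On a length mismatch or empty input.
    UndefinedCorrelationError
        When either series has zero variance.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and observed must be equal-length nonempty 1-D series")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise UndefinedCorrelationError("correlation undefined for a zero-variance series")
    r = stats.pearsonr(p, o).statistic
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    return ModelFit(r_squared=float(r * r), rmse=rmse)


def kendalls_w(scores) -> float:
    """Kendall's coefficient of concordance W for an m-raters × n-items matrix.

    Rows are raters; each row is converted to midranks, ties get the standard
    correction: W = 12·S / (m²(n³−n) − m·ΣT) with T = Σ(t³−t) over each
    rater's tie groups and S the sum of squared deviations of the item rank
    sums from their mean.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 raters and 2 items")
    m, n = x.shape
    ranks = np.vstack([stats.rankdata(row) for row in x])
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:  # every rater ranked all items tied
        return 1.0 if s == 0 else 0.0
    return 12.0 * s / denom


def violation_summary(
    df: pd.DataFrame,
    group_by: list[str] | None = None,
    criterion: str = "full_jpd",
) -> pd.DataFrame:
    """Proportion of trials violating coherence, per group.

    Returns a DataFrame with the grouping columns plus ``violation_rate``,
    ``mean_violations`` (mean count of negative cells) and ``n_trials``.
    With ``group_by=None`` a single overall row is returned.
    """
    validate_table(df, allow_empty=False)
    if group_by:
        for col in group_by:
            if col not in df.columns:
                raise KeyError(f"unknown grouping column: {col!r}")
    work = df.copy()
    violated = []
    n_neg = []
    for _, t in iter_triplets(work):
        violated.append(not is_consistent(t, criterion))
        n_neg.append(count_violations(jpd_from_form(t)))
    work["_violated"] = violated
    work["_n_neg"] = n_neg
    if not group_by:
        return pd.DataFrame(
            {
                "violation_rate": [work["_violated"].mean()],
                "mean_violations": [work["_n_neg"].mean()],
                "n_trials": [len(work)],
            }
        )
    g = work.groupby(group_by, sort=True)
    out = g.agg(
        violation_rate=("_violated", "mean"),
        mean_violations=("_n_neg", "mean"),
        n_trials=("_violated", "size"),
    ).reset_index()
    return out


def compare_models(
    df: pd.DataFrame,
    models: list[str] | None = None,
    w_mult: float | None = None,
) -> dict[str, ModelFit]:
    """Fit each named predictor of pConj from (pA, pB) on a trial table.

    Models: ``split``, ``mult``, ``mixture``, ``wyer``, ``fantino``.  For the
    mixture, ``w_mult`` defaults to the multiplicative proportion found by the
    strategy classifier on the same table (an estimate of the mechanism mix).
    Fits are computed on the proportion scale.
    """
    from .strategies import strategy_rates  # local import avoids a cycle

    validate_table(df, allow_empty=False)
    if models is None:
        models = ["split", "mult", "mixture", "wyer", "fantino"]
    a = df["pA"].astype(float).to_numpy()
    b = df["pB"].astype(float).to_numpy()
    observed = df["pConj"].astype(float).to_numpy() / 100.0
    if w_mult is None and "mixture" in models:
        w_mult = strategy_rates(df).overall["multiplicative"]
    preds = {
        "split": lambda: predict_split(a, b),
        "mult": lambda: predict_multiplicative(a, b),
        "mixture": lambda: predict_mixture(a, b, w_mult),
        "wyer": lambda: predict_wyer(a, b),
        "fantino": lambda: predict_fantino(a, b),
    }
    out = {}
    for name in models:
        if name not in preds:
            raise ValueError(f"unknown model: {name!r}")
        out[name] = fit_metrics(preds[name]() / 100.0, observed)
    return out
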