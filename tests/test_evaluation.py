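"""Competitor predictors, fit metrics, Kendall's W, and violation summaries."""

import numpy as np
import pandas as pd
import pytest

from probjudge import (
    UndefinedCorrelationError,
    compare_models,
    fit_metrics,
    kendalls_w,
    predict_fantino,
    predict_mixture,
    predict_multiplicative,
    predict_wyer,
    violation_summary,
)
from helpers import make_table


class TestCompetitorFormulas:
    def test_fantino_is_arithmetic_mean(self):
        assert predict_fantino(70, 75) == 72.5
        assert predict_fantino(0, 0) == 0
        assert predict_fantino(33, 33) == 33

    def test_wyer_default_variant(self):
        # average of the conjuncts' mean and their product
        assert predict_wyer(70, 75) == pytest.approx(62.5)
        assert predict_wyer(0, 0) == 0
        assert predict_wyer(100, 100) == 100

    def test_wyer_literal_variant_clamps(self):
        # the face-value formula overflows 100 for moderate inputs
        assert predict_wyer(70, 75, variant="literal") == 100
        assert predict_wyer(10, 10, variant="literal") == pytest.approx(16)
        with pytest.raises(ValueError):
            predict_wyer(50, 50, variant="arithmetic")

    def test_mixture_interpolates_midpoint_and_product(self):
        assert predict_mixture(60, 40, w_mult=0.0) == 50
        assert predict_mixture(60, 40, w_mult=1.0) == predict_multiplicative(60, 40)
        assert predict_mixture(60, 40, w_mult=0.5) == pytest.approx(37)


class TestFitMetrics:
    def test_perfect_fit(self):
        fit = fit_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse == 0.0

    def test_constant_offset(self):
        obs = np.array([0.1, 0.3, 0.5])
        fit = fit_metrics(obs, obs + 0.1)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.1)

    def test_matches_brute_force_formulas(self, rng):
        p = rng.uniform(0, 1, 50)
        o = rng.uniform(0, 1, 50)
        fit = fit_metrics(p, o)
        # independent oracle: definitional formulas written out longhand
        r_num = np.sum((p - p.mean()) * (o - o.mean()))
        r_den = np.sqrt(np.sum((p - p.mean()) ** 2) * np.sum((o - o.mean()) ** 2))
        assert fit.r_squared == pytest.approx((r_num / r_den) ** 2)
        assert fit.rmse == pytest.approx(np.sqrt(np.sum((p - o) ** 2) / 50))

    def test_rescaling_preserves_r2_not_rmse(self, rng):
        p = rng.uniform(0, 1, 30)
        o = rng.uniform(0, 1, 30)
        base = fit_metrics(p, o)
        scaled = fit_metrics(2 * p, 2 * o)
        assert scaled.r_squared == pytest.approx(base.r_squared)
        assert scaled.rmse == pytest.approx(2 * base.rmse)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_metrics([0.1, 0.2], [0.1])
        with pytest.raises(UndefinedCorrelationError):
            fit_metrics([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


def kendalls_w_oracle(scores):
    """Brute-force evaluation of the defining W formula (midranks, tie correction)."""
    from scipy.stats import rankdata

    ranks = np.vstack([rankdata(r) for r in scores])
    m, n = ranks.shape
    totals = ranks.sum(axis=0)
    s = np.sum((totals - totals.mean()) ** 2)
    t = sum(
        np.sum(np.array(list(counts.values())) ** 3 - np.array(list(counts.values())))
        for counts in (dict(zip(*np.unique(r, return_counts=True))) for r in ranks)
    )
    return 12 * s / (m**2 * (n**3 - n) - m * t)


class TestKendallsW:
    def test_identical_rankings(self):
        assert kendalls_w([[1, 2, 3, 4], [10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4]]) == pytest.approx(1.0)

    def test_reversed_rankings_cancel(self):
        assert kendalls_w([[1, 2, 3], [3, 2, 1]]) == pytest.approx(0.0)

    def test_matches_brute_force_formula(self, rng):
        x = rng.uniform(0, 100, size=(5, 8))
        x[0, :3] = 42.0  # force some ties to exercise the correction
        assert kendalls_w(x) == pytest.approx(kendalls_w_oracle(x))

    def test_invariant_to_item_relabeling_and_rater_order(self, rng):
        x = rng.uniform(0, 100, size=(4, 6))
        perm_items = rng.permutation(6)
        perm_raters = rng.permutation(4)
        assert kendalls_w(x[perm_raters][:, perm_items]) == pytest.approx(kendalls_w(x))

    def test_degenerate_dimensions(self):
        with pytest.raises(ValueError):
            kendalls_w([[1, 2, 3]])
        with pytest.raises(ValueError):
            kendalls_w([[1], [2]])


class TestViolationSummary:
    def test_counts_on_hand_built_fixture(self):
        # rows 0 and 3 are coherent; rows 1 and 2 imply a negative cell
        table = make_table([(50, 50, 25), (70, 75, 40), (30, 40, 50), (60, 60, 40)])
        out = violation_summary(table)
        assert out["violation_rate"].iloc[0] == 0.5
        assert out["n_trials"].iloc[0] == 4

    def test_all_consistent_table(self):
        # the exact product is coherent for any pair of marginals
        table = make_table([(a, b, a * b / 100) for a in (20, 60) for b in (40, 80)])
        assert (violation_summary(table, ["participant_id"])["violation_rate"] == 0).all()

    def test_unknown_column(self, mixed_batch):
        with pytest.raises(KeyError):
            violation_summary(mixed_batch, ["block"])

    def test_grouped_counts_partition_table(self, exp1_default_table):
        out = violation_summary(exp1_default_table, ["order", "dependence"])
        assert out["n_trials"].sum() == len(exp1_default_table)
        assert out["violation_rate"].between(0, 1).all()


class TestModelComparison:
    def test_mixture_dominates_single_formula_competitors(self, mixed_batch):
        fits = compare_models(mixed_batch, ["mixture", "wyer", "fantino"])
        assert fits["mixture"].r_squared >= fits["wyer"].r_squared
        assert fits["mixture"].r_squared >= fits["fantino"].r_squared
        assert fits["mixture"].rmse <= fits["fantino"].rmse

    def test_pure_split_data_ties_split_and_fantino(self):
        from probjudge import SimParams, run_batch

        df = run_batch("uniform", 500, SimParams(w_mult=0.0, noise_sd=0.0, seed=13), integer_scale=False)
        fits = compare_models(df, ["split", "fantino"])
        assert fits["split"] == fits["fantino"]  # identical formulas on this data
        assert fits["split"].r_squared == pytest.approx(1.0)

    def test_unknown_model(self, mixed_batch):
        with pytest.raises(ValueError):
            compare_models(mixed_batch, ["wolfe"])
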