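"""Synthetic participant datasets with the structure of the two experiments.

The raw participant data were never deposited, so these generators emulate the
two designs end to end: the first experiment's 39 participants × 16 conjunction
problems with two question orders, and the second experiment's 18 participants
× 16 trials crossing verbal/numeric blocks, four (possibly negated) problem
forms and two dependence directions.  Conjunct probabilities are seeded from
the published per-content mean estimates; conjunction estimates come from the
generative model itself (split-the-difference or primitive multiplication plus
mapping noise), so every ground-truth quantity is recorded in ``truth_``
columns for recovery tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .contents import CONTENTS, ContentFixture, load_content_fixture  # noqa: F401  (re-export)
from .icons import (
    BeliefIcon,
    DEFAULT_VERBAL_SCALE,
    VerbalScale,
    icon_to_number,
    icon_to_verbal,
)
from .simulator import SimParams, _conjoin
from .tables import REQUIRED_COLUMNS, validate_table

__all__ = [
    "ContentFixture",
    "load_content_fixture",
    "generate_experiment1",
    "generate_experiment2",
    "read_trials",
    "write_trials",
]


def _participant_w(mu: float, concentration: float, rng: np.random.Generator) -> float:
    """Draw a participant's multiplication propensity from a Beta with the given mean."""
    if mu <= 0.0:
        return 0.0
    if mu >= 1.0:
        return 1.0
    return float(rng.beta(mu * concentration, (1.0 - mu) * concentration))


def _jittered_seed(seed_value: float, sd_points: float, rng: np.random.Generator) -> float:
    """Content seed plus truncated Gaussian jitter, staying within [0, 100]."""
    if sd_points == 0:
        return float(seed_value)
    # rejection sampling keeps the distribution genuinely truncated
    for _ in range(1000):
        v = seed_value + rng.normal(0.0, sd_points)
        if 0.0 <= v <= 100.0:
            return float(v)
    return float(np.clip(seed_value, 0.0, 100.0))


def generate_experiment1(
    n_participants: int = 39,
    params: SimParams | None = None,
    between_participant_sd: float = 0.10,
    w_mult_concentration: float = 5.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the first experiment: 16 numeric conjunction problems per participant.

    Each participant sees all 16 contents once, half in the
    conjunction-first order and half conjunction-last (randomized).  True
    conjunct probabilities are the content seed means plus truncated Gaussian
    jitter of ``between_participant_sd`` (proportion units; 0.10 = 10 points).
    Each participant's multiplication propensity is drawn from a Beta
    distribution with mean ``params.w_mult`` and the given concentration,
    reproducing the very large spread between individuals.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    params = params or SimParams()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    sd_points = between_participant_sd * 100.0
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        w_i = _participant_w(params.w_mult, w_mult_concentration, rng)
        p_params = replace(params, w_mult=w_i)
        content_order = rng.permutation(len(CONTENTS))
        orders = np.array(["conjunction_first"] * 8 + ["conjunction_last"] * 8)
        rng.shuffle(orders)
        for order, ci in zip(orders, content_order):
            content = CONTENTS[ci]
            true_a = _jittered_seed(content.seed_pA, sd_points, rng)
            true_b = _jittered_seed(content.seed_pB, sd_points, rng)
            icon_a = BeliefIcon(true_a / 100.0, provenance="sampled")
            icon_b = BeliefIcon(true_b / 100.0, provenance="sampled")
            conj_icon, strategy = _conjoin(icon_a, icon_b, p_params, rng)
            rows.append(
                {
                    "participant_id": pid,
                    "content_id": content.content_id,
                    "form": "AB",
                    "scale": "numeric",
                    "order": str(order),
                    "dependence": content.dependence,
                    "pA": icon_to_number(icon_a, params.noise_sd, rng),
                    "pB": icon_to_number(icon_b, params.noise_sd, rng),
                    "pConj": icon_to_number(conj_icon, params.noise_sd, rng),
                    "truth_strategy": strategy,
                    "truth_w_mult": w_i,
                    "truth_pA": true_a,
                    "truth_pB": true_b,
                }
            )
    return pd.DataFrame(rows)


def _verbal_report(icon: BeliefIcon, noise_sd: float, scale: VerbalScale, rng) -> tuple[str, float]:
    """Map an icon straight to a verbal category (icon-first, never via numbers).

    The same conversion jitter perturbs the icon before the nearest-anchor
    lookup; on a coarse scale a slight jitter rarely changes the category.
    Returns (label, anchor-mapped percentage).
    """
    m = icon.magnitude
    if noise_sd > 0:
        m = float(np.clip(m + rng.normal(0.0, noise_sd), 0.0, 1.0))
    label = icon_to_verbal(BeliefIcon(m), scale)
    anchor = scale.anchors[scale.labels.index(label)]
    return label, anchor * 100.0


_FORM_CYCLE = ("AB", "notA_B", "A_notB", "notA_notB")


def generate_experiment2(
    n_participants: int = 18,
    params: SimParams | None = None,
    scale: VerbalScale = DEFAULT_VERBAL_SCALE,
    between_participant_sd: float = 0.10,
    w_mult_concentration: float = 5.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the second experiment: verbal and numeric blocks of masked forms.

    Per participant: 16 trials in two blocks of 8 (one verbal, one numeric,
    order counterbalanced across participants), each block crossing the four
    problem forms with the two dependence directions; every content appears
    once per participant.  Each trial records the form's three judgments plus
    the fourth judgment — the conjunction of the negations of the two initial
    propositions (``pConj_neg``).  Verbal trials store the category label and
    its anchor-mapped number; they are generated icon-first.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    params = params or SimParams()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    sd_points = between_participant_sd * 100.0
    decrease = [c for c in CONTENTS if c.dependence == "A_decreases_B"]
    increase = [c for c in CONTENTS if c.dependence == "A_increases_B"]
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        w_i = _participant_w(params.w_mult, w_mult_concentration, rng)
        p_params = replace(params, w_mult=w_i)
        blocks = ("verbal", "numeric") if p % 2 == 0 else ("numeric", "verbal")
        dec = list(rng.permutation(len(decrease)))
        inc = list(rng.permutation(len(increase)))
        for b_idx, block in enumerate(blocks):
            # 4 contents per dependence direction per block, one per form
            form_order_dec = rng.permutation(_FORM_CYCLE)
            form_order_inc = rng.permutation(_FORM_CYCLE)
            trial_specs = [
                (decrease[dec.pop()], f) for f in form_order_dec
            ] + [(increase[inc.pop()], f) for f in form_order_inc]
            rng.shuffle(trial_specs)
            for content, form in trial_specs:
                true_a = _jittered_seed(content.seed_pA, sd_points, rng)
                true_b = _jittered_seed(content.seed_pB, sd_points, rng)
                a, b = true_a / 100.0, true_b / 100.0
                neg_a = form in ("notA_B", "notA_notB")
                neg_b = form in ("A_notB", "notA_notB")
                icon_x = BeliefIcon(1.0 - a if neg_a else a)
                icon_y = BeliefIcon(1.0 - b if neg_b else b)
                conj_icon, strategy = _conjoin(icon_x, icon_y, p_params, rng)
                # fourth judgment: the conjunction of the negations of the
                # form's two propositions
                not_x = BeliefIcon(1.0 - icon_x.magnitude)
                not_y = BeliefIcon(1.0 - icon_y.magnitude)
                neg_icon, strategy_neg = _conjoin(not_x, not_y, p_params, rng)
                row = {
                    "participant_id": pid,
                    "content_id": content.content_id,
                    "form": form,
                    "scale": block,
                    "order": "conjunction_first",
                    "dependence": content.dependence,
                    "block_order": f"{blocks[0]}_first",
                    "truth_strategy": strategy,
                    "truth_strategy_neg": strategy_neg,
                    "truth_w_mult": w_i,
                    "truth_pA": true_a,
                    "truth_pB": true_b,
                }
                if block == "numeric":
                    row.update(
                        pA=icon_to_number(icon_x, params.noise_sd, rng),
                        pB=icon_to_number(icon_y, params.noise_sd, rng),
                        pConj=icon_to_number(conj_icon, params.noise_sd, rng),
                        pConj_neg=icon_to_number(neg_icon, params.noise_sd, rng),
                        pA_label="", pB_label="", pConj_label="", pConj_neg_label="",
                    )
                else:
                    la, va = _verbal_report(icon_x, params.noise_sd, scale, rng)
                    lb, vb = _verbal_report(icon_y, params.noise_sd, scale, rng)
                    lc, vc = _verbal_report(conj_icon, params.noise_sd, scale, rng)
                    ln, vn = _verbal_report(neg_icon, params.noise_sd, scale, rng)
                    row.update(
                        pA=va, pB=vb, pConj=vc, pConj_neg=vn,
                        pA_label=la, pB_label=lb, pConj_label=lc, pConj_neg_label=ln,
                    )
                rows.append(row)
    cols = REQUIRED_COLUMNS + [
        "pConj_neg", "pA_label", "pB_label", "pConj_label", "pConj_neg_label",
        "block_order", "truth_strategy", "truth_strategy_neg", "truth_w_mult",
        "truth_pA", "truth_pB",
    ]
    return pd.DataFrame(rows)[cols]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a validated trial table as CSV (lossless for float64 values)."""
    validate_table(df)
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV, validate its schema, and return the table.

    Empty strings survive the round trip (they are not read as NaN); the
    probability columns come back as floats.
    """
    df = pd.read_csv(path, keep_default_na=False)
    validate_table(df)
    for col in ("pA", "pB", "pConj", "pConj_neg", "truth_pA", "truth_pB", "truth_w_mult"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in ("participant_id", "content_id"):
        df[col] = df[col].astype(str)
    return df
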