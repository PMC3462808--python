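"""The generative model: simulated single-event and conjunction estimates.

On each conjunction trial the intuitive system either splits the difference
between the two conjunct icons or takes a primitive (coarsely quantized)
product of them; the deliberative system then maps the resulting icon onto
the numerical scale with conversion noise.  ``run_batch`` reproduces the
2000-run style simulation in which the model's conjunction estimates are
generated from pairs of conjunct probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .contents import CONTENTS
from .icons import (
    BeliefIcon,
    icon_to_number,
    number_to_icon,
    primitive_multiply,
    sample_icon,
    split_difference,
    build_model,
    DEFAULT_NOISE_SD,
)

__all__ = ["SimParams", "estimate_single_event", "estimate_conjunction", "run_batch"]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the generative model.

    w_mult
        Probability that a conjunction trial uses primitive multiplication
        rather than split-the-difference (independent Bernoulli per trial).
    noise_sd
        SD of icon-to-number conversion error, proportion units.
    granularity
        Steps of primitive multiplication; None selects exact (deliberative)
        multiplication.
    split_weight
        Weight on the second icon when splitting (0.5 = midpoint).
    split_jitter_sd
        SD of the jitter in "roughly" halving the distance; 0 = exact midpoint.
    seed
        Seed for all randomness; identical params + seed give identical output.
    """

    w_mult: float = 0.3
    noise_sd: float = DEFAULT_NOISE_SD
    granularity: int | None = 7
    split_weight: float = 0.5
    split_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_mult <= 1.0:
            raise ValueError("w_mult must lie in [0, 1]")
        if not 0.0 <= self.split_weight <= 1.0:
            raise ValueError("split_weight must lie in [0, 1]")
        if self.noise_sd < 0 or self.split_jitter_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.granularity is not None and self.granularity < 2:
            raise ValueError("granularity must be at least 2 (or None for exact)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimParams":
        return cls(**json.loads(s))


def _conjoin(a: BeliefIcon, b: BeliefIcon, params: SimParams, rng: np.random.Generator) -> tuple[BeliefIcon, str]:
    """Apply one of the two intuitive conjunction operations; return (icon, strategy)."""
    if rng.random() < params.w_mult:
        if params.granularity is None:
            icon = BeliefIcon(a.magnitude * b.magnitude, provenance="combined")
        else:
            icon = primitive_multiply(a, b, params.granularity, max_granularity=None)
        return icon, "multiplicative"
    icon = split_difference(a, b, params.split_weight, params.split_jitter_sd, rng)
    return icon, "split"


def estimate_single_event(
    evidence: list,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> int:
    """Estimate one event's probability from quantified evidence.

    ``evidence`` is a list of quantifier labels, or (quantifier, weight)
    pairs where the weight is used when folding that item in by
    split-the-difference.  Each item is built into a canonical mental model,
    sampled to an icon, and the icons are folded left to right; the result is
    mapped to a percentage.
    """
    if not evidence:
        raise ValueError("at least one piece of evidence is required")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    icons = []
    weights = []
    for item in evidence:
        if isinstance(item, (tuple, list)):
            quantifier, weight = item
        else:
            quantifier, weight = item, params.split_weight
        icons.append(sample_icon(build_model(quantifier)))
        weights.append(weight)
    acc = icons[0]
    for icon, w in zip(icons[1:], weights[1:]):
        acc = split_difference(acc, icon, w, params.split_jitter_sd, rng)
    return icon_to_number(acc, params.noise_sd, rng)


def estimate_conjunction(
    pA: float,
    pB: float,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> int:
    """Estimate P(A&B) from the two conjunct probabilities (percentages)."""
    value, _ = estimate_conjunction_detail(pA, pB, params, rng)
    return value


def estimate_conjunction_detail(
    pA: float,
    pB: float,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[int, str]:
    """As :func:`estimate_conjunction`, also returning the strategy used."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    icon, strategy = _conjoin(number_to_icon(pA), number_to_icon(pB), params, rng)
    return icon_to_number(icon, params.noise_sd, rng), strategy


def _sample_pairs(pairs, n_runs: int, rng: np.random.Generator, pair_jitter_sd: float):
    """Yield n_runs (pA, pB, content_id, dependence) tuples from a sampler spec."""
    if isinstance(pairs, str):
        if pairs == "uniform":
            vals = rng.uniform(0.0, 100.0, size=(n_runs, 2))
            return [(a, b, f"uniform-{i}", "") for i, (a, b) in enumerate(vals)]
        if pairs == "table2":
            idx = rng.integers(0, len(CONTENTS), size=n_runs)
            out = []
            for i in idx:
                c = CONTENTS[i]
                a = float(np.clip(c.seed_pA + rng.normal(0, pair_jitter_sd), 0, 100))
                b = float(np.clip(c.seed_pB + rng.normal(0, pair_jitter_sd), 0, 100))
                out.append((a, b, c.content_id, c.dependence))
            return out
        raise ValueError(f"unknown pair sampler spec: {pairs!r}")
    pairs = list(pairs)
    if not pairs or not all(len(p) == 2 for p in pairs):
        raise ValueError("pairs must be (pA, pB) tuples or a sampler spec")
    idx = rng.integers(0, len(pairs), size=n_runs)
    return [(float(pairs[i][0]), float(pairs[i][1]), f"pair-{i}", "") for i in idx]


def run_batch(
    pairs,
    n_runs: int,
    params: SimParams,
    pair_jitter_sd: float = 10.0,
    integer_scale: bool = True,
) -> pd.DataFrame:
    """Simulate ``n_runs`` conjunction trials and return a trial table.

    ``pairs`` is a list of (pA, pB) percentages, or ``"uniform"`` (pairs drawn
    uniformly on [0, 100]²), or ``"table2"`` (pairs drawn from the 16 content
    seed means with Gaussian jitter of ``pair_jitter_sd`` points).  All three
    reported estimates pass through the noisy icon-to-number mapping; with
    ``integer_scale=False`` the reports stay continuous instead of being
    rounded to integers (useful for exact algebraic checks).

    The returned table carries ground-truth columns ``truth_strategy``,
    ``truth_pA``, ``truth_pB``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    rng = np.random.default_rng(params.seed)
    rows = []
    for a, b, content_id, dependence in _sample_pairs(pairs, n_runs, rng, pair_jitter_sd):
        icon_a, icon_b = number_to_icon(a), number_to_icon(b)
        conj_icon, strategy = _conjoin(icon_a, icon_b, params, rng)

        def report(icon):
            if integer_scale:
                return icon_to_number(icon, params.noise_sd, rng)
            m = icon.magnitude
            if params.noise_sd > 0:
                m += rng.normal(0.0, params.noise_sd)
            return float(np.clip(m, 0.0, 1.0)) * 100.0

        rows.append(
            {
                "participant_id": "sim",
                "content_id": content_id,
                "form": "AB",
                "scale": "numeric",
                "order": "conjunction_last",
                "dependence": dependence,
                "pA": report(icon_a),
                "pB": report(icon_b),
                "pConj": report(conj_icon),
                "truth_strategy": strategy,
                "truth_pA": a,
                "truth_pB": b,
            }
        )
    return pd.DataFrame(rows)
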