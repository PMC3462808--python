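"""The intuitive (pre-numerical) system and its deliberative mappings.

Degrees of belief are represented as analog magnitudes — "belief icons", the
length of a line between impossibility and certainty — sampled from small
mental models of quantified evidence ("Most incumbent US Presidents are
re-elected").  The intuitive system can combine two icons only in primitive
ways: splitting the difference between them, or taking a coarsely quantized
proportion of one by the other.  A separate deliberative system maps icons
onto a 0–100 numerical scale (with conversion error) or onto a seven-point
verbal scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateModelError,
    LimitedRepetitionError,
    UnsupportedQuantifierError,
)

__all__ = [
    "MentalModel",
    "BeliefIcon",
    "VerbalScale",
    "DEFAULT_VERBAL_SCALE",
    "QUANTIFIER_BANDS",
    "CANONICAL_PROPORTIONS",
    "build_model",
    "sample_icon",
    "split_difference",
    "primitive_multiply",
    "quantize",
    "icon_to_number",
    "number_to_icon",
    "icon_to_verbal",
    "verbal_to_icon",
]

#: Admissible proportion band per quantifier: (low, high, low_open, high_open).
QUANTIFIER_BANDS: dict[str, tuple[float, float, bool, bool]] = {
    "all": (1.0, 1.0, False, False),
    "most": (0.5, 1.0, True, True),
    "many": (0.5, 1.0, True, True),
    "some": (0.0, 1.0, True, True),
    "few": (0.0, 0.5, True, True),
    "none": (0.0, 0.0, False, False),
}

#: Canonical point value used when constructing a model of a given size.
#: "most" maps to 3/4 and "few" to 1/4, mirroring the canonical 4-individual
#: model in which three of four incumbents are re-elected.
CANONICAL_PROPORTIONS: dict[str, float] = {
    "all": 1.0,
    "most": 0.75,
    "many": 0.75,
    "some": 0.5,
    "few": 0.25,
    "none": 0.0,
}

#: Default number of individuals in a mental model.
CANONICAL_MODEL_SIZE = 4

#: Default repetition cap on primitive multiplication.
MAX_GRANULARITY = 16

#: Default standard deviation (proportion units) of icon->number conversion error.
DEFAULT_NOISE_SD = 0.05


@dataclass(frozen=True)
class MentalModel:
    """A small set of individuals whose proportion with a property encodes a quantifier.

    Each entry of ``individuals`` is True when that individual has the
    property (e.g. "is re-elected").
    """

    individuals: tuple[bool, ...]
    quantifier: str

    def __post_init__(self) -> None:
        if self.quantifier not in QUANTIFIER_BANDS:
            raise UnsupportedQuantifierError(f"unknown quantifier: {self.quantifier!r}")
        if self.size < 2:
            raise DegenerateModelError(f"a mental model needs at least 2 individuals, got {self.size}")
        if not _in_band(self.proportion, self.quantifier):
            raise DegenerateModelError(
                f"proportion {self.proportion} outside the admissible band for {self.quantifier!r}"
            )

    @property
    def size(self) -> int:
        return len(self.individuals)

    @property
    def proportion(self) -> float:
        return sum(self.individuals) / len(self.individuals)


@dataclass(frozen=True)
class BeliefIcon:
    """An analog magnitude in [0, 1] representing strength of belief."""

    magnitude: float
    provenance: str = "sampled"  # sampled | numeric | combined

    def __post_init__(self) -> None:
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError(f"icon magnitude must lie in [0, 1], got {self.magnitude}")
        if self.provenance not in ("sampled", "numeric", "combined"):
            raise ValueError(f"unknown provenance: {self.provenance!r}")


@dataclass(frozen=True)
class VerbalScale:
    """A seven-category ordinal probability scale with numeric anchors."""

    labels: tuple[str, ...]
    anchors: tuple[float, ...] = field(default=tuple(i / 6 for i in range(7)))

    def __post_init__(self) -> None:
        if len(self.labels) != 7 or len(self.anchors) != 7:
            raise ValueError("a verbal scale has exactly 7 labels and 7 anchors")
        a = self.anchors
        if a[0] != 0.0 or a[-1] != 1.0 or any(x >= y for x, y in zip(a, a[1:])):
            raise ValueError("anchors must be strictly increasing from 0 to 1")

    def to_json(self) -> str:
        return json.dumps({"labels": list(self.labels), "anchors": list(self.anchors)})

    @classmethod
    def from_json(cls, s: str) -> "VerbalScale":
        d = json.loads(s)
        return cls(labels=tuple(d["labels"]), anchors=tuple(d["anchors"]))


DEFAULT_VERBAL_SCALE = VerbalScale(
    labels=(
        "Impossible",
        "Highly improbable",
        "Improbable",
        "As likely as not",
        "Probable",
        "Highly probable",
        "Certain",
    )
)


def _in_band(p: float, quantifier: str) -> bool:
    lo, hi, lo_open, hi_open = QUANTIFIER_BANDS[quantifier]
    above = p > lo if lo_open else p >= lo
    below = p < hi if hi_open else p <= hi
    return above and below


def build_model(quantifier: str, size: int = CANONICAL_MODEL_SIZE, seed: int | None = None) -> MentalModel:
    """Build a mental model of ``size`` individuals encoding ``quantifier``.

    The count of property-bearing individuals is the admissible count closest
    to the quantifier's canonical proportion (ties broken downward).  The seed
    only permutes the order of individuals, so the proportion is deterministic
    regardless of seed.

    Raises
    ------
    UnsupportedQuantifierError
        For a quantifier outside the supported six.
    DegenerateModelError
        If ``size`` < 2 or no count of ``size`` individuals falls inside the
        quantifier's band (e.g. "most" with only 2 individuals).
    """
    if quantifier not in QUANTIFIER_BANDS:
        raise UnsupportedQuantifierError(f"unknown quantifier: {quantifier!r}")
    if size < 2:
        raise DegenerateModelError(f"a mental model needs at least 2 individuals, got {size}")
    admissible = [k for k in range(size + 1) if _in_band(k / size, quantifier)]
    if not admissible:
        raise DegenerateModelError(
            f"no model of size {size} can represent {quantifier!r}; use a larger model"
        )
    target = CANONICAL_PROPORTIONS[quantifier] * size
    count = min(admissible, key=lambda k: (abs(k - target), k))
    flags = np.zeros(size, dtype=bool)
    flags[:count] = True
    rng = np.random.default_rng(seed)
    rng.shuffle(flags)
    return MentalModel(individuals=tuple(bool(b) for b in flags), quantifier=quantifier)


def sample_icon(model: MentalModel) -> BeliefIcon:
    """Sample a model into an iconic magnitude: the proportion of individuals with the property."""
    return BeliefIcon(magnitude=model.proportion, provenance="sampled")


def split_difference(
    a: BeliefIcon,
    b: BeliefIcon,
    weight: float = 0.5,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BeliefIcon:
    """Compromise between two icons by splitting the distance between them.

    With the default weight 0.5 this is the midpoint ("splitting the distance
    roughly halves it"); ``jitter_sd`` adds Gaussian jitter for the "roughly",
    after which the result is clamped to [0, 1].
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must lie in [0, 1], got {weight}")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    m = (1.0 - weight) * a.magnitude + weight * b.magnitude
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        m += rng.normal(0.0, jitter_sd)
    return BeliefIcon(magnitude=float(np.clip(m, 0.0, 1.0)), provenance="combined")


def quantize(x: float, granularity: int) -> float:
    """Round ``x`` to the nearest multiple of 1/granularity."""
    return round(x * granularity) / granularity


def primitive_multiply(
    a: BeliefIcon,
    b: BeliefIcon,
    granularity: int = 7,
    max_granularity: int | None = MAX_GRANULARITY,
) -> BeliefIcon:
    """Primitive finite multiplication: use one icon to take a proportion of another.

    The first operand is quantized to ``granularity`` steps (the intuitive
    system can repeat an operation only a small finite number of times) and the
    quantized proportion of ``b`` is taken.  ``max_granularity`` enforces the
    repetition cap; pass None to lift it (e.g. for convergence checks).

    Raises
    ------
    LimitedRepetitionError
        If granularity < 2 or exceeds the repetition cap.
    """
    if granularity < 2 or (max_granularity is not None and granularity > max_granularity):
        hi = max_granularity if max_granularity is not None else "inf"
        raise LimitedRepetitionError(
            f"granularity {granularity} outside the allowed band [2, {hi}]"
        )
    m = quantize(a.magnitude, granularity) * b.magnitude
    return BeliefIcon(magnitude=float(np.clip(m, 0.0, 1.0)), provenance="combined")


def icon_to_number(
    icon: BeliefIcon,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Deliberative mapping of an icon onto the 0–100 integer percentage scale.

    Conversion error is additive Gaussian with sd ``noise_sd`` (proportion
    units; 0.05 corresponds to about 5 percentage points), applied before
    rounding to the nearest integer and clamping to [0, 100].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    m = icon.magnitude
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        m += rng.normal(0.0, noise_sd)
    # round half away from zero for scale-symmetry; inputs are nonnegative here
    return int(np.clip(np.floor(m * 100.0 + 0.5), 0.0, 100.0))


def number_to_icon(percentage: float) -> BeliefIcon:
    """Represent a 0–100 percentage as a belief icon (numeric provenance)."""
    if not 0.0 <= percentage <= 100.0:
        raise ValueError(f"percentage must lie in [0, 100], got {percentage}")
    return BeliefIcon(magnitude=percentage / 100.0, provenance="numeric")


def icon_to_verbal(icon: BeliefIcon, scale: VerbalScale = DEFAULT_VERBAL_SCALE) -> str:
    """Map an icon to the verbal category with the nearest anchor.

    Exact midpoints between two anchors resolve to the lower category.
    """
    m = icon.magnitude
    best = 0
    best_d = abs(m - scale.anchors[0])
    for i in range(1, 7):
        d = abs(m - scale.anchors[i])
        if d < best_d:  # strict: ties keep the lower category
            best, best_d = i, d
    return scale.labels[best]


def verbal_to_icon(label: str, scale: VerbalScale = DEFAULT_VERBAL_SCALE) -> BeliefIcon:
    """Map a verbal category back to the icon at its anchor."""
    try:
        i = scale.labels.index(label)
    except ValueError:
        raise ValueError(f"label {label!r} not on the scale") from None
    return BeliefIcon(magnitude=scale.anchors[i], provenance="sampled")
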