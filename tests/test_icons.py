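"""The intuitive system's representations and the deliberative mappings."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probjudge import (
    DEFAULT_VERBAL_SCALE,
    BeliefIcon,
    DegenerateModelError,
    LimitedRepetitionError,
    UnsupportedQuantifierError,
    VerbalScale,
    build_model,
    icon_to_number,
    icon_to_verbal,
    number_to_icon,
    primitive_multiply,
    sample_icon,
    split_difference,
    verbal_to_icon,
)

unit = st.floats(min_value=0.0, max_value=1.0)


class TestMentalModels:
    @pytest.mark.parametrize(
        "quantifier,size,proportion",
        [
            ("most", 4, 0.75),  # the canonical 3-of-4 model
            ("all", 5, 1.0),
            ("none", 3, 0.0),
            ("few", 4, 0.25),  # complement of 'most' under the symmetric bands
            ("some", 4, 0.5),
            ("many", 8, 0.75),
        ],
    )
    def test_build_model_proportions(self, quantifier, size, proportion):
        model = build_model(quantifier, size, seed=0)
        assert model.size == size
        assert model.proportion == pytest.approx(proportion)

    def test_proportion_is_seed_invariant(self):
        assert build_model("most", 4, seed=1).proportion == build_model("most", 4, seed=99).proportion

    def test_unknown_quantifier(self):
        with pytest.raises(UnsupportedQuantifierError):
            build_model("several", 4)

    def test_too_small_model(self):
        with pytest.raises(DegenerateModelError):
            build_model("most", 1)

    def test_unrepresentable_band(self):
        # only proportions 0, 1/2, 1 exist at size 2; none lies strictly in (0.5, 1)
        with pytest.raises(DegenerateModelError):
            build_model("most", 2)

    @pytest.mark.parametrize("k,n", [(0, 4), (1, 3), (2, 5), (3, 4), (5, 5)])
    def test_sample_icon_counts_individuals(self, k, n):
        # oracle: brute-force count over the enumerated individuals
        from probjudge import MentalModel

        quantifier = "all" if k == n else ("none" if k == 0 else "some")
        model = MentalModel(individuals=tuple(i < k for i in range(n)), quantifier=quantifier)
        icon = sample_icon(model)
        assert icon.magnitude == pytest.approx(k / n)
        assert icon.provenance == "sampled"


class TestSplitDifference:
    def test_midpoint_of_worked_evidence(self):
        # combining strong (0.75) and weak (0.33) evidence halves the distance
        out = split_difference(BeliefIcon(0.75), BeliefIcon(0.33))
        assert out.magnitude == pytest.approx(0.54)
        assert out.provenance == "combined"

    @given(x=unit, w=unit)
    @settings(derandomize=True)
    def test_idempotent_on_equal_operands(self, x, w):
        assert split_difference(BeliefIcon(x), BeliefIcon(x), w).magnitude == pytest.approx(x)

    @given(a=unit, b=unit)
    @settings(derandomize=True)
    def test_commutative_at_half_weight(self, a, b):
        lhs = split_difference(BeliefIcon(a), BeliefIcon(b), 0.5).magnitude
        rhs = split_difference(BeliefIcon(b), BeliefIcon(a), 0.5).magnitude
        assert lhs == pytest.approx(rhs)

    def test_endpoints(self):
        assert split_difference(BeliefIcon(0.0), BeliefIcon(1.0)).magnitude == 0.5

    @given(a=unit, b=unit, w=unit, jit=st.floats(min_value=0, max_value=0.5))
    @settings(derandomize=True)
    def test_jittered_result_stays_in_unit_interval(self, a, b, w, jit):
        rng = np.random.default_rng(0)
        out = split_difference(BeliefIcon(a), BeliefIcon(b), w, jitter_sd=jit, rng=rng)
        assert 0.0 <= out.magnitude <= 1.0


class TestPrimitiveMultiply:
    def test_identity_and_annihilator(self):
        for g in (2, 7, 16):
            assert primitive_multiply(BeliefIcon(1.0), BeliefIcon(0.37), g).magnitude == pytest.approx(0.37)
            assert primitive_multiply(BeliefIcon(0.0), BeliefIcon(0.37), g).magnitude == 0.0

    def test_converges_to_exact_product(self):
        # oracle: exact multiplication; fine granularity approximates it
        out = primitive_multiply(BeliefIcon(0.6), BeliefIcon(0.4), 1000, max_granularity=None)
        assert out.magnitude == pytest.approx(0.24, abs=1e-3)

    @given(a=unit, b=unit, g=st.integers(min_value=2, max_value=64))
    @settings(derandomize=True)
    def test_quantization_error_bound(self, a, b, g):
        out = primitive_multiply(BeliefIcon(a), BeliefIcon(b), g, max_granularity=None)
        assert abs(out.magnitude - a * b) <= b / (2 * g) + 1e-12

    @pytest.mark.parametrize("g", [0, 1, 17, 1000])
    def test_repetition_cap(self, g):
        with pytest.raises(LimitedRepetitionError):
            primitive_multiply(BeliefIcon(0.5), BeliefIcon(0.5), g)


class TestNumericMapping:
    def test_noiseless_scaling(self):
        assert icon_to_number(BeliefIcon(0.54)) == 54

    @given(m=unit)
    @settings(derandomize=True)
    def test_noisy_output_clamped(self, m):
        rng = np.random.default_rng(7)
        for _ in range(5):
            assert 0 <= icon_to_number(BeliefIcon(m), noise_sd=0.5, rng=rng) <= 100

    def test_empirical_noise_sd(self, rng):
        # Monte Carlo against the stated additive-Gaussian noise model
        draws = [icon_to_number(BeliefIcon(0.5), noise_sd=0.05, rng=rng) for _ in range(10_000)]
        assert np.std(draws) == pytest.approx(5.0, rel=0.05)

    @given(m=unit)
    @settings(derandomize=True)
    def test_round_trip_within_integer_rounding(self, m):
        back = number_to_icon(icon_to_number(BeliefIcon(m)))
        assert abs(back.magnitude - m) <= 0.005 + 1e-12


class TestVerbalScale:
    def test_endpoint_labels(self):
        assert icon_to_verbal(BeliefIcon(0.0)) == "Impossible"
        assert icon_to_verbal(BeliefIcon(1.0)) == "Certain"
        assert icon_to_verbal(BeliefIcon(0.5)) == "As likely as not"

    def test_anchor_values_recover_every_label(self):
        for label, anchor in zip(DEFAULT_VERBAL_SCALE.labels, DEFAULT_VERBAL_SCALE.anchors):
            assert icon_to_verbal(BeliefIcon(anchor)) == label

    def test_midpoint_tie_resolves_downward(self):
        midpoint = (DEFAULT_VERBAL_SCALE.anchors[0] + DEFAULT_VERBAL_SCALE.anchors[1]) / 2
        assert icon_to_verbal(BeliefIcon(midpoint)) == "Impossible"

    def test_verbal_round_trip(self):
        for label in DEFAULT_VERBAL_SCALE.labels:
            assert icon_to_verbal(verbal_to_icon(label)) == label

    def test_json_round_trip(self):
        s = DEFAULT_VERBAL_SCALE.to_json()
        payload = json.loads(s)
        assert len(payload["labels"]) == 7
        assert VerbalScale.from_json(s) == DEFAULT_VERBAL_SCALE

    def test_rejects_bad_anchors(self):
        with pytest.raises(ValueError):
            VerbalScale(labels=DEFAULT_VERBAL_SCALE.labels, anchors=(0, 0.1, 0.1, 0.3, 0.5, 0.7, 1.0))
        with pytest.raises(ValueError):
            VerbalScale(labels=("a", "b"), anchors=(0.0, 1.0))
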