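"""Closed-form model: Bayes posteriors, fertility bias, flip condition."""

import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fertbias import (
    REGIME_NEGATIVE,
    REGIME_NEUTRAL,
    REGIME_POSITIVE,
    SSMParams,
    analyze,
    classify_regime,
    estimated_fertility,
    fertility_bias,
    flip_condition,
    posterior_high_given_diagnosis,
    posterior_low_given_diagnosis,
    true_fertility,
)


def enumerated_posterior_low(r, p_low, p_base):
    """Independent oracle: build the four-cell joint (class x diagnosis)
    distribution explicitly and condition on diagnosis by counting."""
    cells = {
        ("L", "D"): p_low * (r * p_base),
        ("L", "~D"): p_low * (1.0 - r * p_base),
        ("H", "D"): (1.0 - p_low) * p_base,
        ("H", "~D"): (1.0 - p_low) * (1.0 - p_base),
    }
    diagnosed = cells[("L", "D")] + cells[("H", "D")]
    return cells[("L", "D")] / diagnosed


@st.composite
def ssm_params(draw, min_r=1.0, min_d=0.0):
    p_low = draw(st.floats(0.05, 0.95))
    r = draw(st.floats(min_r, 20.0))
    d = draw(st.floats(min_d, 3.0))
    w_min = (1.0 - p_low) * d
    W = draw(st.floats(w_min + 1e-6, w_min + 3.0))
    return SSMParams(r=r, d=d, W=W, p_low=p_low)


class TestPosteriors:
    @pytest.mark.parametrize(
        "r, p_low, expected",
        [
            (3.0, 0.5, 0.75),  # over-represented low-fitness families
            (1.0, 0.5, 0.5),  # no signal leaves the prior unchanged
            (1.0, 0.3, 0.3),
            (9.0, 0.5, 0.9),
        ],
    )
    def test_posterior_low_examples(self, r, p_low, expected):
        assert posterior_low_given_diagnosis(r, p_low) == pytest.approx(expected, abs=1e-15)
        assert posterior_high_given_diagnosis(r, p_low) == pytest.approx(
            1.0 - expected, abs=1e-15
        )

    @pytest.mark.parametrize("r, p_low", [(0.5, 0.5), (3.0, 0.0), (3.0, 1.0), (3.0, -0.1)])
    def test_domain_errors(self, r, p_low):
        with pytest.raises(ValueError):
            posterior_low_given_diagnosis(r, p_low)

    @given(r=st.floats(1.0, 100.0), p_low=st.floats(0.01, 0.99))
    @settings(derandomize=True)
    def test_normalization_and_over_representation(self, r, p_low):
        low = posterior_low_given_diagnosis(r, p_low)
        high = posterior_high_given_diagnosis(r, p_low)
        assert low + high == pytest.approx(1.0, abs=1e-15)
        assert low >= p_low - 1e-15
        assert 0.0 <= low <= 1.0

    def test_matches_joint_table_enumeration(self):
        # the baseline diagnosis probability must cancel out exactly
        for p_base in (0.001, 0.01, 0.05):
            for i in range(10):
                for j in range(10):
                    r = 1.0 + 0.9 * i
                    p_low = 0.08 + 0.09 * j
                    assert posterior_low_given_diagnosis(r, p_low) == pytest.approx(
                        enumerated_posterior_low(r, p_low, p_base), abs=1e-12
                    )

    def test_posterior_high_monotone_decreasing_in_r(self):
        values = [posterior_high_given_diagnosis(r, 0.5) for r in (1, 2, 5, 20, 1000)]
        assert all(b < a for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-3


class TestFertility:
    @pytest.mark.parametrize(
        "kwargs, w_high, w_low",
        [
            (dict(r=3, d=1, W=1), 1.5, 0.5),
            (dict(r=3, d=0, W=1), 1.0, 1.0),
            (dict(r=3, d=0.4, W=0.9), 1.1, 0.7),
        ],
    )
    def test_class_means_and_round_trip(self, kwargs, w_high, w_low):
        params = SSMParams(**kwargs)
        assert params.w_high == pytest.approx(w_high)
        assert params.w_low == pytest.approx(w_low)
        assert true_fertility(params) == pytest.approx(kwargs["W"], abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(W=1, r=3, d=1), 0.75),  # the headline worked example
            (dict(W=1, r=1, d=1), 1.0),
            (dict(W=1.2, r=3, d=0), 1.2),
        ],
    )
    def test_estimated_fertility_examples(self, kwargs, expected):
        assert estimated_fertility(SSMParams(**kwargs)) == expected

    @given(ssm_params())
    @settings(derandomize=True)
    def test_estimated_equals_posterior_weighted_mixture(self, params):
        post_low = posterior_low_given_diagnosis(params.r, params.p_low)
        mixture = (1.0 - post_low) * params.w_high + post_low * params.w_low
        assert estimated_fertility(params) == pytest.approx(mixture, abs=1e-12)

    @given(ssm_params())
    @settings(derandomize=True)
    def test_estimate_never_exceeds_truth(self, params):
        assert estimated_fertility(params) <= true_fertility(params) + 1e-12


class TestBias:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(r=3, d=1, W=1), 0.25),
            (dict(r=1, d=5, W=5), 0.0),
            (dict(r=3, d=2, W=2), 0.5),  # linear in d
        ],
    )
    def test_bias_examples(self, kwargs, expected):
        assert fertility_bias(SSMParams(**kwargs)) == expected

    def test_bias_recomputed_via_estimated_fertility(self):
        params = SSMParams(r=3, d=2, W=2)
        assert fertility_bias(params) == params.W - estimated_fertility(params)

    @given(ssm_params(min_r=1.0 + 1e-9, min_d=1e-9))
    @settings(derandomize=True)
    def test_bias_strictly_positive_when_signal_exists(self, params):
        assert fertility_bias(params) > 0.0

    @given(ssm_params())
    @settings(derandomize=True)
    def test_bias_zero_iff_degenerate(self, params):
        bias = fertility_bias(params)
        if params.r == 1.0 or params.d == 0.0:
            assert bias == 0.0
        else:
            assert bias > 0.0

    @given(ssm_params(), st.floats(0.0, 5.0))
    @settings(derandomize=True)
    def test_bias_nondecreasing_in_r(self, params, dr):
        bigger = SSMParams(r=params.r + dr, d=params.d, W=params.W, p_low=params.p_low)
        assert fertility_bias(bigger) >= fertility_bias(params) - 1e-12

    @given(st.floats(1.0, 20.0), st.floats(0.0, 2.0))
    @settings(derandomize=True)
    def test_symmetric_prior_reduction(self, r, d):
        # with p_low = 0.5 the bias is d*(r-1)/(2*(r+1)), linear in d
        params = SSMParams(r=r, d=d, W=d, p_low=0.5)
        assert fertility_bias(params) == pytest.approx(
            d * (r - 1.0) / (2.0 * (r + 1.0)), abs=1e-12
        )

    @given(ssm_params())
    @settings(derandomize=True)
    def test_consistency_identity_exact(self, params):
        assert estimated_fertility(params) == params.W - fertility_bias(params)


class TestRegimes:
    @pytest.mark.parametrize(
        "w, expected",
        [(0.75, REGIME_NEGATIVE), (1.0, REGIME_NEUTRAL), (1.005, REGIME_NEUTRAL), (1.25, REGIME_POSITIVE)],
    )
    def test_classify_regime(self, w, expected):
        assert classify_regime(w, tol=0.01) == expected

    def test_classify_regime_rejects_negative_fertility(self):
        with pytest.raises(ValueError):
            classify_regime(-0.1)
        with pytest.raises(ValueError):
            classify_regime(1.0, tol=-1e-3)

    @pytest.mark.parametrize(
        "W, expected_flip",
        [(1.0, True), (1.2, True), (1.5, False), (0.9, False)],
    )
    def test_flip_condition_at_worked_example(self, W, expected_flip):
        params = SSMParams(r=3, d=1, W=W)
        flipped, threshold = flip_condition(params)
        assert threshold == pytest.approx(1.25)
        assert flipped is expected_flip

    def test_analyze_worked_example(self, worked_example_params):
        res = analyze(worked_example_params)
        assert res.w_true == 1.0
        assert res.w_hat == 0.75
        assert res.bias == 0.25
        assert res.flip_threshold == 1.25
        assert res.regime_true == REGIME_NEUTRAL
        assert res.regime_estimated == REGIME_NEGATIVE
        assert res.misclassified is True

    def test_analyze_not_misclassified_when_truly_negative(self):
        res = analyze(SSMParams(r=3, d=1, W=0.9))
        assert res.regime_true == REGIME_NEGATIVE
        assert res.misclassified is False

    def test_result_serializes_to_json(self, worked_example_params):
        payload = json.loads(analyze(worked_example_params).to_json())
        assert set(payload) == {
            "r", "d", "W", "p_low", "posterior_low", "posterior_high",
            "w_hat", "bias", "flip_threshold", "regime_true",
            "regime_estimated", "misclassified",
        }
        assert payload["bias"] == 0.25
        assert payload["misclassified"] is True


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r=0.5, d=1, W=1),  # risk signal must not be inverted
            dict(r=3, d=-0.1, W=1),
            dict(r=3, d=1, W=-0.5),
            dict(r=3, d=1, W=1, p_low=0.0),
            dict(r=3, d=1, W=1, p_low=1.0),
            dict(r=3, d=1, W=0.4),  # derived W_L = -0.1 < 0
            dict(r=math.nan, d=1, W=1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SSMParams(**kwargs)

    def test_dict_round_trip(self, worked_example_params):
        assert SSMParams.from_dict(worked_example_params.to_dict()) == worked_example_params
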