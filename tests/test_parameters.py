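"""Parameter container invariants and moment-matching transformations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvc_cea.parameters import (
    OTHER_COMPLICATIONS,
    BudgetContext,
    CostParam,
    ProbabilityParam,
    StrategyParams,
    apply_odds_ratio,
    beta_from_moments,
    ci_to_se,
    default_parameters,
    gamma_from_moments,
    load_parameters,
    rate_to_probability,
)


class TestDefaults:
    """The embedded base-case inputs carry the published values exactly."""

    EXPECTED_PROBS = {
        "UG": {
            "f1": (0.164, 0.143, 0.183),
            "f2": (0.049, 0.031, 0.067),
            "c1": (0.029, 0.019, 0.040),
            "c2": (0.041, 0.029, 0.053),
            "c3": (0.047, 0.034, 0.059),
            "arterial": (0.015, 0.010, 0.021),
        },
        "LM": {
            "f1": (0.376, 0.356, 0.395),
            "f2": (0.166, 0.138, 0.193),
            "c1": (0.114, 0.096, 0.132),
            "c2": (0.156, 0.136, 0.176),
            "c3": (0.177, 0.156, 0.197),
            "arterial": (0.081, 0.069, 0.093),
        },
    }
    EXPECTED_COSTS = {
        "arterial puncture": 94,
        "thrombosis": 131,
        "embolism": 131,
        "hydromediastinum": 133,
        "hematomediastinum": 94,
        "hematothorax": 177,
        "hydrothorax": 217,
        "pneumothorax": 178,
        "nerve injury": 347,
        "subcutaneous emphysema": 16,
    }

    def test_clinical_probabilities_exact(self, ug, lm):
        for arm in (ug, lm):
            for key, (mean, lo, hi) in self.EXPECTED_PROBS[arm.strategy].items():
                p = arm.probabilities[key]
                assert (p.mean, p.ci_low, p.ci_high) == (mean, lo, hi)

    def test_complication_costs_exact(self, ug):
        assert {k: v.mean_cost for k, v in ug.cost_map.items()} == self.EXPECTED_COSTS

    def test_budget_constants(self, budget_ctx):
        assert budget_ctx.annual_catheters == 568_000
        assert (budget_ctx.adoption_low, budget_ctx.adoption_high) == (0.10, 0.20)
        assert budget_ctx.incremental_cost == -179.0

    def test_derived_beta_parameters_match_mean(self, lm):
        for p in lm.probabilities.values():
            assert p.alpha > 0 and p.beta > 0
            assert math.isclose(p.alpha / (p.alpha + p.beta), p.mean, abs_tol=1e-9)

    def test_equal_other_complication_weights(self, ug):
        assert set(ug.other_complication_weights) == set(OTHER_COMPLICATIONS)
        assert all(
            math.isclose(w, 1 / 9) for w in ug.other_complication_weights.values()
        )


class TestCiToSe:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.096, 0.132, 0.036 / 3.92),
            (0.031, 0.067, 0.036 / 3.92),
            (0.5, 0.5, 0.0),
        ],
    )
    def test_normal_approximation_width(self, lo, hi, expected):
        assert ci_to_se(lo, hi) == pytest.approx(expected, abs=1e-12)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            ci_to_se(0.2, 0.1)


class TestBetaFromMoments:
    def test_symmetric_case(self):
        alpha, beta = beta_from_moments(0.5, 0.05)
        assert alpha == pytest.approx(49.5, abs=1e-9)
        assert beta == pytest.approx(49.5, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        mean=st.floats(0.01, 0.99),
        frac=st.floats(0.01, 0.9),
    )
    def test_roundtrip_mean_and_variance(self, mean, frac):
        # se chosen strictly inside the feasible range
        se = frac * math.sqrt(mean * (1 - mean))
        alpha, beta = beta_from_moments(mean, se)
        nu = alpha + beta
        assert alpha / nu == pytest.approx(mean, abs=1e-9)
        var = alpha * beta / (nu**2 * (nu + 1))
        assert var == pytest.approx(se**2, rel=1e-9)

    def test_variance_bound_rejected(self):
        with pytest.raises(ValueError):
            beta_from_moments(0.9, 0.4)

    def test_degenerate_mean_rejected(self):
        with pytest.raises(ValueError):
            beta_from_moments(0.0, 0.1)


class TestGammaFromMoments:
    def test_round_numbers(self):
        assert gamma_from_moments(100, 10) == pytest.approx((100.0, 1.0))

    def test_shape_from_cv(self):
        shape, scale = gamma_from_moments(94, 23.98)
        assert shape == pytest.approx((94 / 23.98) ** 2, rel=1e-12)
        assert shape * scale == pytest.approx(94, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(mean=st.floats(1.0, 1e4), se=st.floats(0.1, 1e3))
    def test_mean_variance_identity(self, mean, se):
        shape, scale = gamma_from_moments(mean, se)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert shape * scale**2 == pytest.approx(se**2, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_moments(0.0, 1.0)


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate, horizon, expected",
        [(0.0, 1.0, 0.0), (math.log(2), 1.0, 0.5), (0.1, 1.0, 1 - math.exp(-0.1))],
    )
    def test_closed_form(self, rate, horizon, expected):
        assert rate_to_probability(rate, horizon) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(rate=st.floats(0.0, 5.0), horizon=st.floats(0.01, 10.0))
    def test_bounded_and_small_rate_limit(self, rate, horizon):
        p = rate_to_probability(rate, horizon)
        assert 0.0 <= p <= 1.0
        if rate * horizon < 30:  # beyond this 1 - exp(-x) saturates in floats
            assert p < 1.0
        if rate * horizon < 1e-4:
            assert p == pytest.approx(rate * horizon, rel=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1, 1.0)


class TestApplyOddsRatio:
    @pytest.mark.parametrize(
        "p, odds_ratio, expected",
        [
            (0.5, 1.0, 0.5),
            (0.029, 8.4, 0.2006),
            (0.1, 35.6, 0.7983),
        ],
    )
    def test_examples(self, p, odds_ratio, expected):
        assert apply_odds_ratio(p, odds_ratio) == pytest.approx(expected, abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.001, 0.99), odds_ratio=st.floats(0.1, 50.0))
    def test_identity_and_monotonicity(self, p, odds_ratio):
        assert apply_odds_ratio(p, 1.0) == pytest.approx(p, rel=1e-12)
        bumped = apply_odds_ratio(min(p * 1.01, 0.995), odds_ratio)
        assert bumped >= apply_odds_ratio(p, odds_ratio) - 1e-12
        assert apply_odds_ratio(p, odds_ratio * 1.01) > apply_odds_ratio(p, odds_ratio)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            apply_odds_ratio(1.0, 2.0)


class TestContainers:
    def test_probability_ordering_enforced(self):
        with pytest.raises(ValueError):
            ProbabilityParam("bad", 0.5, 0.6, 0.7)

    def test_cost_range_enforced(self):
        with pytest.raises(ValueError):
            CostParam("bad", 100.0, low=120.0, high=150.0)

    def test_cost_default_dsa_range_is_half_to_one_and_a_half(self):
        cp = CostParam("x", 100.0)
        assert (cp.low, cp.high) == (50.0, 150.0)
        assert cp.shape * cp.scale == pytest.approx(100.0, abs=1e-9)

    def test_weights_must_sum_to_one(self, ug):
        bad = {name: 0.2 for name in OTHER_COMPLICATIONS}
        with pytest.raises(ValueError):
            StrategyParams(
                strategy="UG",
                cost_map=ug.cost_map,
                other_complication_weights=bad,
                **{k: v for k, v in ug.probabilities.items()},
            )

    def test_budget_context_validation(self):
        with pytest.raises(ValueError):
            BudgetContext(0, 0.1, 0.2, -179.0, 0.138)
        with pytest.raises(ValueError):
            BudgetContext(1000, 0.3, 0.2, -179.0, 0.138)


class TestConfigLoading:
    def test_override_roundtrip(self, tmp_path, lm):
        cfg = tmp_path / "params.yaml"
        cfg.write_text(
            "strategies:\n"
            "  lm:\n"
            "    c1: {mean: 0.2, ci_low: 0.15, ci_high: 0.25}\n"
            "costs:\n"
            "  pneumothorax: {mean: 500}\n"
            "budget:\n"
            "  annual_catheters: 100000\n"
        )
        ug2, lm2, ctx2 = load_parameters(cfg)
        assert lm2.c1.mean == 0.2
        assert lm2.c1.ci_low == 0.15
        # untouched values fall back to defaults
        assert lm2.f1.mean == lm.f1.mean
        assert ug2.cost_map["pneumothorax"].mean_cost == 500
        assert ctx2.annual_catheters == 100_000
        assert ctx2.adoption_high == 0.20

    def test_empty_file_gives_defaults(self, tmp_path, lm):
        cfg = tmp_path / "empty.yaml"
        cfg.write_text("")
        _, lm2, _ = load_parameters(cfg)
        assert lm2.c1.mean == lm.c1.mean
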