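import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialrisk.choice_models import (
    MODELS,
    AgentParameters,
    TrialArrays,
    gamble_utility,
    get_model,
    neg_log_likelihood,
    normalized_ocu,
    p_safe_hybrid,
    p_safe_ocu,
    p_safe_solo,
    p_safe_table,
)
from socialrisk.task_design import GamblePair, Trial

PAIR = GamblePair(0, 0.6, 2.00, 1.60, 3.85, 0.10)


def _params(**kw):
    base = dict(beta=1.0, alpha=1.0)
    base.update(kw)
    return AgentParameters(**base)


class TestGambleUtility:
    @pytest.mark.parametrize(
        "p,vh,vl,alpha,expected",
        [
            (0.6, 2.0, 1.6, 1.0, 1.84),                 # expected value
            (1.0, 2.0, 0.5, 0.8, 2.0**0.8),             # certain high payoff
            (0.5, 1.7, 1.7, 0.73, 1.7**0.73),           # degenerate lottery
            (0.3, 3.0, 0.2, 1.0, 0.3 * 3.0 + 0.7 * 0.2),
        ],
    )
    def test_matches_direct_power_evaluation(self, p, vh, vl, alpha, expected):
        assert gamble_utility(p, vh, vl, alpha) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_payoff_rejected(self):
        with pytest.raises(ValueError):
            gamble_utility(0.5, 2.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            gamble_utility(0.5, 2.0, 1.0, -0.2)


class TestSafeProbabilities:
    def test_solo_hand_arithmetic(self):
        # U_safe = 1.84, U_risky = 0.6*3.85 + 0.4*0.10 = 2.35
        assert p_safe_solo(PAIR, _params()) == pytest.approx(1 / (1 + math.exp(0.51)), abs=1e-10)

    def test_solo_indifference_at_equal_utilities(self):
        pair = GamblePair(0, 0.5, 2.0, 1.0, 2.5, 0.5)  # both EV = 1.5
        assert p_safe_solo(pair, _params()) == pytest.approx(0.5)

    def test_solo_beta_to_zero_limit(self):
        assert p_safe_solo(PAIR, _params(beta=1e-12)) == pytest.approx(0.5, abs=1e-9)

    def test_ocu_hand_arithmetic_on_info_safe(self):
        trial = Trial(0, PAIR, "info_safe")
        p = p_safe_ocu(trial, _params(ocu=0.5))
        assert p == pytest.approx(1 / (1 + math.exp(0.01)), abs=1e-10)

    @pytest.mark.parametrize("trial_type", ["solo", "info_mix"])
    def test_ocu_reduces_to_solo_when_delta_zero(self, trial_type):
        trial = Trial(0, PAIR, trial_type)
        assert p_safe_ocu(trial, _params(ocu=3.0)) == pytest.approx(p_safe_solo(PAIR, _params()))

    def test_ocu_zero_reduces_to_solo_on_info_trials(self):
        trial = Trial(0, PAIR, "info_risky")
        assert p_safe_ocu(trial, _params(ocu=0.0)) == pytest.approx(p_safe_solo(PAIR, _params()))

    def test_hybrid_hand_arithmetic(self):
        trial = Trial(0, PAIR, "info_safe")
        params = _params(ocu=0.5, w_follow=0.3, w_oppose=0.1, w_utility=0.6)
        p_ocu = p_safe_ocu(trial, params)
        assert p_safe_hybrid(trial, params) == pytest.approx(0.3 + 0.6 * p_ocu, abs=1e-12)

    def test_hybrid_pure_follow_ignores_gambles(self):
        trial = Trial(0, PAIR, "info_safe")
        params = _params(ocu=-2.0, w_follow=1.0, w_oppose=0.0, w_utility=0.0)
        assert p_safe_hybrid(trial, params) == pytest.approx(1.0)

    def test_ocu_strictly_increasing_in_ocu_on_info_safe(self):
        trial = Trial(0, PAIR, "info_safe")
        ps = [p_safe_ocu(trial, _params(ocu=o)) for o in np.linspace(-1, 1, 9)]
        assert all(b > a for a, b in zip(ps, ps[1:]))


class TestNormalizedOcu:
    def test_values(self):
        assert normalized_ocu(2.0, 0.0) == pytest.approx(0.5)
        assert normalized_ocu(1.0, 0.5) == pytest.approx(1 / (1 + math.exp(-0.5)), abs=1e-12)
        assert normalized_ocu(1.0, 50.0) == pytest.approx(1.0)

    def test_requires_positive_beta(self):
        with pytest.raises(ValueError):
            normalized_ocu(0.0, 1.0)


class TestParameterValidation:
    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError):
            AgentParameters(beta=1, alpha=1, w_follow=0.5, w_oppose=0.5, w_utility=0.5)

    @pytest.mark.parametrize("kw", [dict(beta=0.0), dict(alpha=-1.0)])
    def test_nonpositive_beta_alpha_rejected(self, kw):
        with pytest.raises(ValueError):
            _params(**kw)


class TestNesting:
    """The models form a nested family; restrictions must agree exactly."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        beta=st.floats(0.05, 10), alpha=st.floats(0.2, 1.8), ocu=st.floats(-2, 2),
        ttype=st.sampled_from(["solo", "info_safe", "info_risky", "info_mix"]),
        p=st.sampled_from([0.4, 0.5, 0.6, 0.7, 0.8, 0.9]),
    )
    def test_hybrid_with_unit_utility_weight_is_ocu_model(self, beta, alpha, ocu, ttype, p):
        pair = GamblePair(0, p, 2.0, 1.6, 3.85, 0.10)
        trial = Trial(0, pair, ttype)
        full = AgentParameters(beta=beta, alpha=alpha, ocu=ocu,
                               w_follow=0.0, w_oppose=0.0, w_utility=1.0)
        assert p_safe_hybrid(trial, full) == pytest.approx(p_safe_ocu(trial, full), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(beta=st.floats(0.05, 10), alpha=st.floats(0.2, 1.8),
           ttype=st.sampled_from(["solo", "info_safe", "info_risky", "info_mix"]))
    def test_ocu_model_with_zero_ocu_is_solo_model(self, beta, alpha, ttype):
        trial = Trial(0, PAIR, ttype)
        params = AgentParameters(beta=beta, alpha=alpha, ocu=0.0)
        assert p_safe_ocu(trial, params) == pytest.approx(p_safe_solo(PAIR, params), abs=1e-12)


class TestMixtureBounds:
    def test_heuristic_weights_bound_hybrid_probability(self, rng):
        """On unanimous trials the weights cap the reachable probability band."""
        for _ in range(500):
            w = rng.dirichlet(np.ones(3))
            params = AgentParameters(
                beta=float(rng.uniform(0.05, 10)), alpha=float(rng.uniform(0.2, 1.8)),
                ocu=float(rng.normal(0, 1.5)),
                w_follow=w[0], w_oppose=w[1], w_utility=w[2],
            )
            p_safe_trial = Trial(0, PAIR, "info_safe")
            p = p_safe_hybrid(p_safe_trial, params)
            assert w[0] - 1e-12 <= p <= 1 - w[1] + 1e-12
            p_risky_trial = Trial(0, PAIR, "info_risky")
            p = p_safe_hybrid(p_risky_trial, params)
            assert w[1] - 1e-12 <= p <= 1 - w[0] + 1e-12


class TestNegLogLikelihood:
    def test_random_chooser_closed_form(self, session_frame):
        # beta ~ 0 predicts 0.5 everywhere: -LL = 96 ln 2
        choices = np.zeros(96)
        nll = neg_log_likelihood("solo_rp", session_frame, choices, _params(beta=1e-12))
        assert nll == pytest.approx(96 * math.log(2), rel=1e-6)

    def test_perfect_prediction_gives_zero(self, toy_frame):
        params = _params(w_follow=1.0, w_oppose=0.0, w_utility=0.0)
        sub = toy_frame[toy_frame["trial_type"] == "info_safe"]
        nll = neg_log_likelihood("hybrid", sub, np.ones(len(sub)), params)
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_bernoulli_product(self, toy_frame, rng):
        """Independent oracle: per-trial scalar probabilities multiplied by hand."""
        params = _params(beta=1.7, alpha=0.8, ocu=0.4,
                         w_follow=0.25, w_oppose=0.15, w_utility=0.6)
        choices = rng.integers(0, 2, len(toy_frame))
        expected = 0.0
        for (_, row), c in zip(toy_frame.iterrows(), choices):
            pair = GamblePair(int(row.menu_id), row.p_high, row.v_high_safe,
                              row.v_low_safe, row.v_high_risky, row.v_low_risky)
            p = p_safe_hybrid(Trial(int(row.trial_index), pair, row.trial_type), params)
            expected -= math.log(p if c == 1 else 1 - p)
        got = neg_log_likelihood("hybrid", toy_frame, choices, params)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_length_mismatch_rejected(self, toy_frame):
        with pytest.raises(ValueError):
            neg_log_likelihood("hybrid", toy_frame, [1, 0], _params())

    def test_trial_filter_restricts_scoring(self, toy_frame):
        choices = np.ones(len(toy_frame))
        full = neg_log_likelihood("solo_rp", toy_frame, choices, _params())
        solo = neg_log_likelihood("solo_rp", toy_frame, choices, _params(), trial_filter="solo")
        assert 0 < solo < full


class TestModelRegistry:
    def test_hybrid_group_parameter_count(self):
        # 2 hyperparameters x 3 pooled parameters + (3 weights - 1)
        assert get_model("hybrid").n_group_params == 8

    @pytest.mark.parametrize("name,count", [("solo_rp", 4), ("ocu", 6), ("ocu_free", 5)])
    def test_nested_model_parameter_counts(self, name, count):
        assert get_model(name).n_group_params == count

    def test_aliases_and_unknown(self):
        assert get_model("ocu_based").name == "ocu"
        with pytest.raises(ValueError):
            get_model("prospect")

    def test_table_interface_agrees_with_scalar_functions(self, session_frame):
        arrays = TrialArrays.from_frame(session_frame)
        params = _params(beta=2.0, alpha=0.7, ocu=0.3,
                         w_follow=0.2, w_oppose=0.1, w_utility=0.7)
        p_vec = p_safe_table(arrays, *(
            MODELS["hybrid"].constrain(params.beta, params.alpha, params.ocu,
                                       params.w_follow, params.w_oppose, params.w_utility)
        ))
        for i, (_, row) in enumerate(session_frame.iterrows()):
            pair = GamblePair(int(row.menu_id), row.p_high, row.v_high_safe,
                              row.v_low_safe, row.v_high_risky, row.v_low_risky)
            p_scalar = p_safe_hybrid(Trial(i, pair, row.trial_type), params)
            assert p_vec[i] == pytest.approx(p_scalar, abs=1e-12)
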