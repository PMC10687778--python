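"""Unit and property tests for the decision-model likelihood layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batbandit import (
    AgentState,
    ChoiceTrial,
    ModelSpec,
    Session,
    WSLSParams,
    apply_night_carryover,
    choice_prob_perseveration,
    negative_log_likelihood,
    perseveration_update,
    q_update,
    softmax_choice_prob,
    wsls_choice_prob,
)

E_RATIO = math.e / (math.e + 1.0)  # softmax prob at unit exponent gap


class TestSoftmax:
    @pytest.mark.parametrize("q, beta, action, expected", [
        ((0.4, 0.4), 3.0, 0, 0.5),          # equal values: indifference
        ((0.9, 0.1), 0.0, 1, 0.5),          # beta=0: value-blind choice
        ((1.0, 0.0), 1.0, 0, E_RATIO),      # direct evaluation
        ((1.0, 0.0), 1.0, 1, 1.0 - E_RATIO),
    ])
    def test_values(self, q, beta, action, expected):
        assert softmax_choice_prob(q, beta, action) == pytest.approx(expected)

    def test_large_exponent_is_stable(self):
        p = softmax_choice_prob((1e4, 0.0), 20.0, 0)
        assert p == pytest.approx(1.0)
        assert math.isfinite(softmax_choice_prob((1e4, 0.0), 20.0, 1))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            softmax_choice_prob((np.nan, 0.0), 1.0, 0)
        with pytest.raises(ValueError):
            softmax_choice_prob((0.0, 0.0), -1.0, 0)

    @settings(derandomize=True, deadline=None)
    @given(q0=st.floats(-5, 5), q1=st.floats(-5, 5), beta=st.floats(0, 20),
           shift=st.floats(-3, 3))
    def test_sums_to_one_and_translation_invariant(self, q0, q1, beta, shift):
        p0 = softmax_choice_prob((q0, q1), beta, 0)
        p1 = softmax_choice_prob((q0, q1), beta, 1)
        assert p0 + p1 == pytest.approx(1.0)
        # only the value difference matters
        assert softmax_choice_prob((q0 + shift, q1 + shift), beta, 0) == pytest.approx(p0)


class TestQUpdate:
    def test_zero_learning_rate_freezes_values(self):
        s = AgentState(q=[0.3, 0.7])
        out = q_update(s, 0, 1, alpha=0.0)
        assert np.allclose(out.q, [0.3, 0.7])

    @pytest.mark.parametrize("reward", [0, 1])
    def test_full_learning_rate_replaces_value(self, reward):
        out = q_update(AgentState(q=[0.42, 0.1]), 0, reward, alpha=1.0)
        assert out.q[0] == reward

    def test_prediction_error_step_and_unchosen_untouched(self):
        out = q_update(AgentState(q=[0.5, 0.9]), 0, 1, alpha=0.2)
        assert out.q[0] == pytest.approx(0.6)
        assert out.q[1] == 0.9

    def test_rejects_non_binary_reward(self):
        with pytest.raises(ValueError):
            q_update(AgentState(), 0, 2, alpha=0.5)

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1),
                              st.floats(0, 1)), max_size=50))
    def test_values_stay_in_unit_interval(self, steps):
        s = AgentState(q=[0.5, 0.5])
        for action, reward, alpha in steps:
            s = q_update(s, action, reward, alpha)
        assert (0.0 <= s.q).all() and (s.q <= 1.0).all()


class TestPerseveration:
    def test_zero_rate_is_identity(self):
        s = AgentState(p_val=[0.2, 0.8])
        assert np.allclose(perseveration_update(s, 1, 0.0).p_val, [0.2, 0.8])

    def test_single_step(self):
        out = perseveration_update(AgentState(), 0, 0.2)
        assert np.allclose(out.p_val, [0.6, 0.4])

    def test_repeated_choice_drives_trace_to_one(self):
        s = AgentState()
        prev = 0.5
        for _ in range(40):
            s = perseveration_update(s, 0, 0.3)
            assert s.p_val[0] > prev
            prev = s.p_val[0]
        assert s.p_val[0] == pytest.approx(1.0, abs=1e-4)
        assert s.p_val.sum() == pytest.approx(1.0)

    def test_choice_prob_reduces_to_softmax_at_zero_exponent(self):
        state = AgentState(q=[0.3, 0.8], p_val=[0.9, 0.1])
        assert choice_prob_perseveration(state, 2.5, 0.0, 0) == \
            softmax_choice_prob(state.q, 2.5, 0)

    def test_choice_prob_direct_value(self):
        state = AgentState(q=[0.0, 0.0], p_val=[1.0, 0.0])
        assert choice_prob_perseveration(state, 2.0, 1.0, 0) == pytest.approx(E_RATIO)


class TestWSLSChoiceProb:
    def test_pure_strategy_is_deterministic(self):
        params = WSLSParams(p_stay=1.0, p_shift=1.0)
        won = ChoiceTrial(index=1, action=0, reward=1)
        lost = ChoiceTrial(index=1, action=0, reward=0)
        assert wsls_choice_prob(won, 0, params) == 1.0
        assert wsls_choice_prob(lost, 0, params) == 0.0

    def test_stay_after_win_and_shift_complement(self):
        params = WSLSParams(p_stay=0.8, p_shift=0.7)
        won = ChoiceTrial(index=1, action=0, reward=1)
        lost = ChoiceTrial(index=1, action=0, reward=0)
        assert wsls_choice_prob(won, 0, params) == pytest.approx(0.8)
        assert wsls_choice_prob(lost, 0, params) == pytest.approx(0.3)
        assert wsls_choice_prob(lost, 1, params) == pytest.approx(0.7)


class TestCarryover:
    def test_reset_zeroes_values(self):
        out = apply_night_carryover(AgentState(q=[0.7, 0.3]), "reset")
        assert np.allclose(out.q, 0.0)

    @pytest.mark.parametrize("decay, expected", [
        (0.0, [0.7, 0.3]),   # no forgetting
        (1.0, [0.0, 0.0]),   # complete forgetting
        (0.25, [0.525, 0.225]),
    ])
    def test_decay_forget_convention(self, decay, expected):
        out = apply_night_carryover(AgentState(q=[0.7, 0.3]), "decay", decay)
        assert np.allclose(out.q, expected)

    def test_retain_convention_flips_direction(self):
        out = apply_night_carryover(AgentState(q=[0.8, 0.4]), "decay", 0.25,
                                    convention="retain")
        assert np.allclose(out.q, [0.2, 0.1])

    def test_full_keeps_values(self):
        out = apply_night_carryover(AgentState(q=[0.7, 0.3]), "full")
        assert np.allclose(out.q, [0.7, 0.3])

    def test_decay_requires_value(self):
        with pytest.raises(ValueError):
            apply_night_carryover(AgentState(), "decay")


class TestNegativeLogLikelihood:
    def test_wsls_first_trial_convention(self):
        s = Session("b", 1, "stable", [1], [0])
        nll = negative_log_likelihood([s], ModelSpec("wsls"),
                                      {"p_stay": 0.9, "p_shift": 0.9})
        assert nll == pytest.approx(math.log(2))

    def test_wsls_three_trial_product(self, tiny_session):
        nll = negative_log_likelihood([tiny_session], ModelSpec("wsls"),
                                      {"p_stay": 0.8, "p_shift": 0.6})
        expected = math.log(2) - math.log(0.8) - math.log(0.6)
        assert nll == pytest.approx(expected)

    def test_beta_zero_gives_coin_flip_likelihood(self, rng):
        from conftest import random_sessions
        sessions = random_sessions(rng, n_nights=3, n_trials=25)
        nll = negative_log_likelihood(sessions, ModelSpec("rl", "reset"),
                                      {"alpha": 0.4, "beta": 0.0})
        assert nll == pytest.approx(75 * math.log(2))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood([], ModelSpec("rl"), {"alpha": 0.1, "beta": 1.0})

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(alpha=st.floats(0, 1), beta=st.floats(0, 10), decay=st.floats(0, 1),
           p_rate=st.floats(0, 1), seed=st.integers(0, 10_000))
    def test_perseveration_nests_plain_model_at_zero_exponent(
            self, alpha, beta, decay, p_rate, seed):
        from conftest import random_sessions
        sessions = random_sessions(np.random.default_rng(seed), 2, 30)
        plain = negative_log_likelihood(
            sessions, ModelSpec("rl", "decay"),
            {"alpha": alpha, "beta": beta, "decay": decay})
        nested = negative_log_likelihood(
            sessions, ModelSpec("rl_perseveration", "decay"),
            {"alpha": alpha, "beta": beta, "decay": decay,
             "p_rate": p_rate, "p_exp": 0.0})
        assert nested == pytest.approx(plain, abs=1e-12)

    @pytest.mark.parametrize("family, carryover, params", [
        ("rl", "decay", {"alpha": 0.35, "beta": 3.0, "decay": 0.4}),
        ("rl_perseveration", "full",
         {"alpha": 0.35, "beta": 3.0, "p_rate": 0.2, "p_exp": 1.5}),
        ("wsls", "reset", {"p_stay": 0.8, "p_shift": 0.55}),
    ])
    def test_invariant_under_feeder_relabeling(self, rng, family, carryover, params):
        from conftest import random_sessions
        sessions = random_sessions(rng, 3, 40)
        flipped = [Session(s.bat_id, s.night, s.environment,
                           1 - s.actions, s.rewards) for s in sessions]
        spec = ModelSpec(family, carryover)
        assert negative_log_likelihood(sessions, spec, params) == pytest.approx(
            negative_log_likelihood(flipped, spec, params), rel=1e-12)

    def test_per_trial_probabilities_sum_to_one(self, rng):
        state = AgentState(q=rng.random(2), p_val=rng.random(2))
        for beta in (0.0, 1.7, 12.0):
            assert softmax_choice_prob(state.q, beta, 0) + \
                softmax_choice_prob(state.q, beta, 1) == pytest.approx(1.0)
            assert choice_prob_perseveration(state, beta, 2.0, 0) + \
                choice_prob_perseveration(state, beta, 2.0, 1) == pytest.approx(1.0)
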