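"""Hybrid learner: value updates, choice rule, likelihood, oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacontrol import (
    ChoiceDataset,
    ModelParams,
    OMEGA_KEYS,
    TaskConfig,
    TrialObservation,
    choice_prob,
    generate_trial_sequence,
    init_state,
    mb_values,
    mf_update,
    replay,
    sequence_loglik,
    simulate_agent,
    transition_update,
)
from metacontrol.task import TrialSpec

from conftest import make_params, random_params, random_short_dataset
from oracle import oracle_loglik, pure_mb_loglik, pure_mf_loglik


def _trial(**overrides) -> TrialSpec:
    base = dict(trial_index=0, block_index=0, block_condition="variable",
                start_state=0, stakes="low", left_action=0)
    base.update(overrides)
    return TrialSpec(**base)


def _obs(trial=None, action1=0, planet=0, reward=5, **kw) -> TrialObservation:
    trial = trial or _trial()
    return TrialObservation(
        trial, action1, trial.key_of(action1), planet, True, reward, **kw
    )


class TestInitState:
    def test_values_start_at_reward_midpoint(self, default_config):
        state = init_state(default_config)
        assert np.all(state.q_mf_stage1 == 4.5)
        assert np.all(state.q_mf_stage2 == 4.5)

    def test_transitions_start_uninformed(self, default_config):
        state = init_state(default_config)
        assert np.all(state.transition == 0.5)
        assert state.prev_action == -1 and state.prev_key == -1

    def test_midpoint_follows_asymmetric_bounds(self):
        state = init_state(TaskConfig(reward_bounds=(2, 5)))
        assert np.all(state.q_mf_stage1 == 3.5)


class TestModelBasedValues:
    def test_deterministic_transition_passes_planet_value_through(self, default_config):
        state = init_state(default_config)
        state.transition[0] = [[1.0, 0.0], [0.0, 1.0]]
        state.q_mf_stage2[:] = [8.0, 2.0]
        np.testing.assert_allclose(mb_values(state, 0), [8.0, 2.0])

    def test_uninformed_transition_averages_planets(self, default_config):
        state = init_state(default_config)
        state.q_mf_stage2[:] = [8.0, 2.0]
        np.testing.assert_allclose(mb_values(state, 0), [5.0, 5.0])

    def test_equal_planet_values_give_equal_action_values(self, default_config):
        state = init_state(default_config)
        state.transition[1] = [[0.9, 0.1], [0.3, 0.7]]
        state.q_mf_stage2[:] = [6.0, 6.0]
        np.testing.assert_allclose(mb_values(state, 1), [6.0, 6.0])


class TestChoiceRule:
    def test_uniform_when_all_coefficients_zero(self, default_config):
        state = init_state(default_config)
        state.q_mf_stage1[0] = [9.0, 1.0]
        params = make_params(beta=0.0, pi=0.0, rho=0.0)
        p = choice_prob(state, 0, params, ("low", "stable"), (0, 1))
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_choice_stickiness_closed_form(self, default_config):
        state = init_state(default_config)
        state.prev_action = 0
        state.prev_key = -1
        params = make_params(beta=0.0, pi=1.0, rho=0.0)
        p = choice_prob(state, 0, params, ("low", "stable"), (0, 1))
        expected = math.e / (math.e + 1.0)
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_pure_model_based_is_indifferent_on_symmetric_beliefs(self, default_config):
        state = init_state(default_config)
        state.q_mf_stage1[0] = [9.0, 0.0]  # stage-1 cache should be ignored
        params = make_params(beta=5.0, pi=0.0, rho=0.0, omega=1.0)
        p = choice_prob(state, 0, params, ("low", "stable"), (0, 1))
        np.testing.assert_allclose(p, [0.5, 0.5])

    @given(
        beta=st.floats(0, 50), pi=st.floats(-5, 5), rho=st.floats(-5, 5),
        q=st.lists(st.floats(0, 9), min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_probabilities_normalize(self, beta, pi, rho, q):
        state = init_state(TaskConfig())
        state.q_mf_stage1[0] = q
        state.prev_action, state.prev_key = 0, 1
        params = make_params(beta=beta, pi=pi, rho=rho)
        p = choice_prob(state, 0, params, ("high", "variable"), (1, 0))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_stickiness_monotonically_favors_repeats(self, default_config):
        state = init_state(default_config)
        state.prev_action = 0
        prev = -1.0
        for pi in (-1.0, 0.0, 0.5, 1.0, 2.0):
            params = make_params(beta=2.0, pi=pi, rho=0.0)
            p = choice_prob(state, 0, params, ("low", "stable"), (0, 1))[0]
            assert p > prev
            prev = p


class TestModelFreeUpdate:
    def test_zero_learning_rate_is_identity(self, default_config):
        state = init_state(default_config)
        out = mf_update(state, _obs(reward=9), make_params(alpha=0.0))
        np.testing.assert_array_equal(out.q_mf_stage1, state.q_mf_stage1)
        np.testing.assert_array_equal(out.q_mf_stage2, state.q_mf_stage2)

    def test_hand_computed_sarsa_lambda_update(self, default_config):
        # Q1 = 4.5, Q2 = 6, r = 9, alpha = .5, lambda = 1:
        # d1 = 1.5, d2 = 3 -> Q1' = 4.5 + .75 + 1.5 = 6.75, Q2' = 7.5
        state = init_state(default_config)
        state.q_mf_stage2[0] = 6.0
        out = mf_update(
            state, _obs(reward=9), make_params(alpha=0.5, lam=1.0)
        )
        assert out.q_mf_stage1[0, 0] == pytest.approx(6.75)
        assert out.q_mf_stage2[0] == pytest.approx(7.5)

    def test_unvisited_entries_unchanged(self, default_config):
        state = init_state(default_config)
        out = mf_update(state, _obs(action1=0, planet=1, reward=0),
                        make_params(alpha=0.9))
        assert out.q_mf_stage1[0, 1] == 4.5
        assert np.all(out.q_mf_stage1[1] == 4.5)
        assert out.q_mf_stage2[0] == 4.5

    def test_missing_reward_rejected(self, default_config):
        state = init_state(default_config)
        obs = TrialObservation(_trial(), 0, 0, 0, False, None)
        with pytest.raises(ValueError):
            mf_update(state, obs, make_params())

    @given(
        alpha=st.floats(0, 1), lam=st.floats(0, 1),
        rewards=st.lists(st.integers(0, 9), min_size=1, max_size=30),
        planets=st.lists(st.integers(0, 1), min_size=30, max_size=30),
        actions=st.lists(st.integers(0, 3), min_size=30, max_size=30),
    )
    @settings(max_examples=40, deadline=None)
    def test_values_stay_within_reward_bounds(
        self, alpha, lam, rewards, planets, actions
    ):
        """Each update is a convex combination of quantities in [0, 9]."""
        state = init_state(TaskConfig())
        params = make_params(alpha=alpha, lam=lam)
        for i, r in enumerate(rewards):
            a = actions[i]
            trial = _trial(start_state=a // 2, left_action=2 * (a // 2))
            state = mf_update(
                state, _obs(trial=trial, action1=a, planet=planets[i], reward=r),
                params,
            )
            assert np.all((state.q_mf_stage1 >= 0) & (state.q_mf_stage1 <= 9))
            assert np.all((state.q_mf_stage2 >= 0) & (state.q_mf_stage2 <= 9))


class TestTransitionUpdate:
    def test_unit_rates_jump_to_certainty(self, default_config):
        state = init_state(default_config)
        out = transition_update(state, _obs(action1=0, planet=0), 1.0, 1.0)
        assert out.transition[0, 0, 0] == 1.0  # taken action -> observed planet
        assert out.transition[0, 1, 1] == 1.0  # other action -> other planet

    def test_zero_rates_are_identity(self, default_config):
        state = init_state(default_config)
        state.transition[0, 0] = [0.8, 0.2]
        out = transition_update(state, _obs(action1=0, planet=1), 0.0, 0.0)
        np.testing.assert_array_equal(out.transition, state.transition)

    @given(
        rates=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1,
            max_size=40,
        ),
        outcomes=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 1)), min_size=40,
            max_size=40,
        ),
    )
    @settings(max_examples=40, deadline=None)
    def test_rows_remain_normalized(self, rates, outcomes):
        state = init_state(TaskConfig())
        for (eta, eta_cf), (a, p) in zip(rates, outcomes):
            trial = _trial(start_state=a // 2, left_action=2 * (a // 2))
            state = transition_update(
                state, _obs(trial=trial, action1=a, planet=p), eta, eta_cf
            )
            sums = state.transition.sum(axis=2)
            np.testing.assert_allclose(sums, 1.0, atol=1e-12)
            assert np.all((state.transition >= 0) & (state.transition <= 1))


class TestSequenceLoglik:
    def test_uniform_policy_likelihood(self, simulated_dataset):
        params = make_params(beta=0.0, pi=0.0, rho=0.0)
        n_valid = sum(1 for o in simulated_dataset.observations if not o.miss1)
        for engine in ("python", "numba"):
            ll = sequence_loglik(simulated_dataset, params, engine=engine)
            assert ll == pytest.approx(n_valid * math.log(0.5), rel=1e-12)

    def test_all_first_stage_misses_contribute_nothing(self, small_config):
        seq = generate_trial_sequence(small_config)
        obs = tuple(
            TrialObservation(t, None, None, None, False, None)
            for t in seq.trials
        )
        ds = ChoiceDataset("p", "g", seq, obs)
        assert sequence_loglik(ds, make_params(), engine="python") == 0.0

    def test_engines_agree_on_full_session(self, simulated_dataset):
        params = make_params()
        ll_py = sequence_loglik(simulated_dataset, params, engine="python")
        ll_nb = sequence_loglik(simulated_dataset, params, engine="numba")
        assert ll_nb == pytest.approx(ll_py, abs=1e-10)

    def test_matches_brute_force_oracle_on_many_short_datasets(self):
        """Both engines agree with a from-scratch per-trial re-derivation,
        including first- and second-stage misses, to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            ds = random_short_dataset(rng)
            params = random_params(rng)
            expected = oracle_loglik(ds, params)
            assert sequence_loglik(ds, params, engine="python") == pytest.approx(
                expected, abs=1e-10
            )
            assert sequence_loglik(ds, params, engine="numba") == pytest.approx(
                expected, abs=1e-10
            )

    @pytest.mark.parametrize("omega,oracle", [(0.0, pure_mf_loglik),
                                              (1.0, pure_mb_loglik)])
    def test_reduces_to_single_strategy_learners(self, omega, oracle):
        rng = np.random.default_rng(321)
        for _ in range(25):
            ds = random_short_dataset(rng)
            params = random_params(rng)
            params = ModelParams(
                alpha=params.alpha, lam=params.lam, eta=params.eta,
                beta=params.beta, pi=params.pi, rho=params.rho,
                omega={k: omega for k in OMEGA_KEYS}, eta_cf=params.eta_cf,
            )
            assert sequence_loglik(ds, params, engine="numba") == pytest.approx(
                oracle(ds, params), abs=1e-10
            )

    def test_out_of_bounds_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_params(alpha=1.2)
        with pytest.raises(ValueError):
            make_params(beta=-0.1)
        with pytest.raises(ValueError):
            make_params(omega=1.5)


class TestReplay:
    def test_first_trial_expectation_is_midpoint(self, simulated_dataset):
        trace = replay(simulated_dataset, make_params())
        first_valid = next(
            i for i, o in enumerate(simulated_dataset.observations)
            if not o.miss1
        )
        assert trace["q2_visited"][first_valid] == 4.5

    def test_full_learning_rate_carries_last_reward(self, small_config):
        """With alpha = 1 the expectation on a revisit equals the reward
        obtained on the previous visit to that planet."""
        seq = generate_trial_sequence(small_config)
        params = make_params(alpha=1.0)
        ds = simulate_agent(params, seq, np.random.default_rng(0))
        trace = replay(ds, params)
        last_reward = {}
        for i, obs in enumerate(ds.observations):
            if obs.miss1:
                continue
            if obs.planet in last_reward:
                assert trace["q2_visited"][i] == last_reward[obs.planet]
            if obs.reward is not None:
                last_reward[obs.planet] = obs.reward

    def test_replay_matches_generation_trace(self, default_config):
        seq = generate_trial_sequence(default_config)
        params = make_params()
        ds, trace = simulate_agent(
            params, seq, np.random.default_rng(11), return_trace=True
        )
        replayed = replay(ds, params)
        np.testing.assert_allclose(
            replayed["q2_visited"], trace["q2_visited"], equal_nan=True
        )
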