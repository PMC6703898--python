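"""Behavioral analyses: baseline correction, revaluation, matching, RTs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metacontrol import (
    ChoiceDataset,
    TaskConfig,
    TrialObservation,
    baseline_corrected_reward,
    expectation_covariate,
    generate_trial_sequence,
    identify_revaluation_trials,
    omega_long_table,
    participant_summaries,
    performance_match,
    rt_preprocess,
    simulate_agent,
)
from metacontrol.task import (
    ReversalSchedule,
    RewardWalks,
    TransitionStructure,
    TrialSequence,
    TrialSpec,
)

from conftest import make_params


def _toy_sequence(
    n=12, block_condition="variable", start_states=None, events=(),
    walks=None, config=None,
):
    """Hand-built single-block sequence for enumeration tests."""
    config = config or TaskConfig(
        n_blocks=1, trials_per_block=n, block_order=(block_condition,),
    )
    start_states = start_states or [0] * n
    trials = tuple(
        TrialSpec(i, 0, block_condition, start_states[i],
                  "low" if i % 2 else "high", left_action=2 * start_states[i])
        for i in range(n)
    )
    if walks is None:
        walks = np.tile(np.array([[6], [2]]), (1, n))
    return TrialSequence(
        config=config,
        trials=trials,
        reversal_schedule=ReversalSchedule(tuple(events)),
        reward_walks=RewardWalks(walks),
        initial_transitions=TransitionStructure(np.array([[0, 1], [0, 1]])),
    )


def _respond(seq, choices):
    """Observations responding per `choices` (None = first-stage miss,
    "m2" suffix = second-stage miss)."""
    mapping = seq.mapping_per_trial()
    obs = []
    for trial, choice in zip(seq.trials, choices):
        if choice is None:
            obs.append(TrialObservation(trial, None, None, None, False, None))
            continue
        a_loc, miss2 = (choice, False) if isinstance(choice, int) else choice
        a = 2 * trial.start_state + a_loc
        planet = int(mapping[trial.trial_index, trial.start_state, a_loc])
        if miss2:
            obs.append(
                TrialObservation(trial, a, trial.key_of(a), planet, False, None)
            )
        else:
            reward = int(seq.reward_walks.values[planet, trial.trial_index])
            obs.append(
                TrialObservation(trial, a, trial.key_of(a), planet, True, reward)
            )
    return ChoiceDataset("toy", "younger", seq, tuple(obs))


class TestBaselineCorrectedReward:
    def test_definition_arithmetic(self):
        seq = _toy_sequence(n=2, walks=np.array([[6, 6], [2, 2]]))
        ds = _respond(seq, [0, 1])
        per_trial, _ = baseline_corrected_reward(ds)
        # planet 0 pays 6, planet 1 pays 2; baseline (6+2)/2 = 4
        assert per_trial[0] == pytest.approx(2.0)
        assert per_trial[1] == pytest.approx(-2.0)

    def test_misses_excluded_from_mean(self):
        seq = _toy_sequence(n=4, walks=np.array([[6] * 4, [2] * 4]))
        ds = _respond(seq, [0, None, (0, True), 1])
        per_trial, mean = baseline_corrected_reward(ds)
        assert np.isnan(per_trial[1]) and np.isnan(per_trial[2])
        assert mean == pytest.approx((2.0 - 2.0) / 2)

    def test_uniform_chooser_has_near_zero_mean(self, default_config):
        seq = generate_trial_sequence(default_config)
        means = []
        for seed in range(40):
            ds = simulate_agent(
                make_params(beta=0.0, pi=0.0, rho=0.0), seq,
                np.random.default_rng(seed),
            )
            means.append(baseline_corrected_reward(ds)[1])
        assert np.mean(means) == pytest.approx(0.0, abs=0.1)

    def test_perfect_chooser_earns_half_absolute_walk_gap(self, default_config):
        seq = generate_trial_sequence(default_config)
        walks = seq.reward_walks.values
        mapping = seq.mapping_per_trial()
        choices = []
        for t, trial in enumerate(seq.trials):
            better = int(np.argmax(walks[:, t]))
            a_loc = int(
                np.where(mapping[t, trial.start_state] == better)[0][0]
            )
            choices.append(a_loc)
        ds = _respond(seq, choices)
        _, mean = baseline_corrected_reward(ds)
        expected = np.mean(np.abs(walks[0] - walks[1]) / 2.0)
        assert mean == pytest.approx(expected, abs=1e-12)


class TestRevaluationTrials:
    def test_first_valid_visit_after_event_is_flagged(self):
        # reversal at trial 5 affecting state 0; trial 6 starts in state 1,
        # trial 7 in state 0 -> trial 7 carries the flag
        states = [0, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1]
        seq = _toy_sequence(start_states=states, events=[(5, 0)])
        ds = _respond(seq, [0] * 12)
        flags = identify_revaluation_trials(ds)
        assert list(np.where(flags)[0]) == [7]

    def test_stable_blocks_never_flagged(self, default_config):
        seq = generate_trial_sequence(default_config)
        ds = simulate_agent(make_params(), seq, np.random.default_rng(0))
        flags = identify_revaluation_trials(ds)
        stable = [
            o.trial.block_condition == "stable"
            for o in np.array(ds.observations, dtype=object)[flags]
        ]
        assert not any(stable)

    def test_no_events_no_flags(self):
        seq = _toy_sequence(block_condition="stable")
        ds = _respond(seq, [0] * 12)
        assert not identify_revaluation_trials(ds).any()

    def test_double_reversal_before_visit_collapses_to_one_flag(self):
        states = [1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1]
        seq = _toy_sequence(start_states=states, events=[(2, 0), (6, 0)])
        ds = _respond(seq, [0] * 12)
        flags = identify_revaluation_trials(ds)
        assert list(np.where(flags)[0]) == [8]

    def test_first_stage_miss_defers_flag_to_next_visit(self):
        states = [1, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        seq = _toy_sequence(start_states=states, events=[(1, 0)])
        ds = _respond(seq, [0, None, 0] + [0] * 9)
        flags = identify_revaluation_trials(ds)
        assert list(np.where(flags)[0]) == [2]

    def test_second_stage_miss_does_not_block_flag(self):
        states = [1, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        seq = _toy_sequence(start_states=states, events=[(1, 0)])
        ds = _respond(seq, [0, (0, True), 0] + [0] * 9)
        flags = identify_revaluation_trials(ds)
        assert list(np.where(flags)[0]) == [1]

    def test_matches_enumeration_oracle(self):
        """Exhaustive check over event/visit interleavings on 8-trial
        sessions against a direct walk of the definition."""
        for states in itertools.product((0, 1), repeat=8):
            for event_t in (1, 3, 5):
                for event_s in (0, 1):
                    seq = _toy_sequence(
                        n=8, start_states=list(states),
                        events=[(event_t, event_s)],
                    )
                    ds = _respond(seq, [0] * 8)
                    flags = identify_revaluation_trials(ds)
                    expected = next(
                        (t for t in range(event_t, 8)
                         if states[t] == event_s),
                        None,
                    )
                    got = list(np.where(flags)[0])
                    assert got == ([expected] if expected is not None else [])


class TestPerformanceMatch:
    def test_two_vs_two_example(self):
        result = performance_match(
            {"a1": 1.0, "a2": 2.0}, {"b1": 1.1, "b2": 5.0}
        )
        assert result.pairs == (("a1", "b1"),)
        assert set(result.unmatched) == {"a2", "b2"}

    def test_identical_groups_fully_matched(self):
        scores = {f"p{i}": float(i) for i in range(5)}
        other = {f"q{i}": float(i) for i in range(5)}
        result = performance_match(scores, other)
        assert len(result.pairs) == 5
        assert result.unmatched == ()
        assert all(a[1:] == b[1:] for a, b in result.pairs)

    def test_singletons_always_pair(self):
        result = performance_match({"a": 0.0}, {"b": 99.0})
        assert result.pairs == (("a", "b"),)

    def test_symmetric_in_group_order_and_ids_unique(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = {f"a{i}": float(x) for i, x in
                 enumerate(rng.normal(size=rng.integers(1, 8)))}
            b = {f"b{i}": float(x) for i, x in
                 enumerate(rng.normal(size=rng.integers(1, 8)))}
            fwd = performance_match(a, b)
            rev = performance_match(b, a)
            assert {frozenset(p) for p in fwd.pairs} == {
                frozenset(p) for p in rev.pairs
            }
            flat = [p for pair in fwd.pairs for p in pair]
            assert len(flat) == len(set(flat))

    def test_matches_brute_force_mutual_nearest_neighbors(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = {f"a{i}": round(float(x), 2) for i, x in
                 enumerate(rng.normal(size=6))}
            b = {f"b{i}": round(float(x), 2) for i, x in
                 enumerate(rng.normal(size=6))}
            expected = set()
            for pa, va in a.items():
                for pb, vb in b.items():
                    best_for_a = min(
                        sorted(b), key=lambda q: (abs(b[q] - va), q)
                    )
                    best_for_b = min(
                        sorted(a), key=lambda q: (abs(a[q] - vb), q)
                    )
                    if best_for_a == pb and best_for_b == pa:
                        expected.add((pa, pb))
            assert set(performance_match(a, b).pairs) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            performance_match({}, {"b": 1.0})


class TestRtPreprocess:
    def _rt_dataset(self, rts):
        states = [0] * 12
        seq = _toy_sequence(start_states=states, events=[(5, 0)])
        ds = _respond(seq, [0] * 12)
        new = []
        for obs, rt in zip(ds.observations, rts):
            new.append(
                TrialObservation(
                    obs.trial, obs.action1, obs.key1, obs.planet,
                    obs.action2_made, obs.reward, rt1=500.0, rt2=rt,
                )
            )
        return ChoiceDataset("p1", "older", ds.sequence, tuple(new))

    def test_cutoff_is_strictly_below_200ms(self):
        ds = self._rt_dataset([199.0, 200.0] + [600.0] * 10)
        table = rt_preprocess([ds])
        assert len(table) == 11  # the 199 ms trial is dropped
        assert table["log_rt2"].min() == pytest.approx(np.log(200.0))

    def test_stable_block_trials_dropped(self):
        seq = _toy_sequence(block_condition="stable")
        ds = _respond(seq, [0] * 12)
        new = tuple(
            TrialObservation(o.trial, o.action1, o.key1, o.planet,
                             o.action2_made, o.reward, 500.0, 700.0)
            for o in ds.observations
        )
        table = rt_preprocess([ChoiceDataset("p", "younger", seq, new)])
        assert len(table) == 0

    def test_dummy_codes_and_revaluation_flag(self):
        ds = self._rt_dataset([600.0] * 12)
        table = rt_preprocess([ds])
        assert set(table["old"]) == {1}  # group "older"
        assert table["revaluation"].sum() == 1
        assert (
            table["old_x_revaluation"] == table["old"] * table["revaluation"]
        ).all()


class TestExpectationCovariate:
    def test_initial_expectation_is_midpoint(self):
        seq = _toy_sequence()
        ds = _respond(seq, [0] * 12)
        cov = expectation_covariate(ds, make_params())
        assert cov[0] == 4.5

    def test_full_learning_rate_tracks_previous_reward(self):
        walks = np.array([[6] * 12, [2] * 12])
        seq = _toy_sequence(walks=walks)
        ds = _respond(seq, [0] * 12)
        cov = expectation_covariate(ds, make_params(alpha=1.0))
        assert cov[0] == 4.5
        np.testing.assert_allclose(cov[1:], 6.0)


class TestOmegaTable:
    def test_effect_codes_exact(self):
        frame = pd.DataFrame(
            [
                {
                    "participant": "y0", "group": "younger",
                    "omega_low_stable": 0.1, "omega_high_stable": 0.2,
                    "omega_low_variable": 0.3, "omega_high_variable": 0.4,
                }
            ]
        )
        table = omega_long_table(frame)
        assert len(table) == 4
        assert set(table["age"]) == {0.5}
        assert set(table["stakes"]) == {-0.5, 0.5}
        assert set(table["transition"]) == {-0.5, 0.5}
        row = table.loc[
            (table["stakes"] == 0.5) & (table["transition"] == -0.5)
        ].iloc[0]
        assert row["omega"] == 0.4
        assert row["age_x_stakes"] == 0.25
        assert row["age_x_transition"] == -0.25

    def test_summaries_have_expected_columns(self, simulated_dataset):
        frame = participant_summaries([simulated_dataset])
        assert list(frame.columns) == ["participant", "group",
                                       "mean_bc_reward"]
        assert len(frame) == 1
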