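import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from metacontrol import (  # noqa: E402
    ChoiceDataset,
    ModelParams,
    OMEGA_KEYS,
    TaskConfig,
    TrialObservation,
    generate_trial_sequence,
    simulate_agent,
)


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig(seed=0)


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """A short two-block session (one stable, one variable block)."""
    return TaskConfig(
        n_blocks=2, trials_per_block=16, block_order=("stable", "variable"),
        seed=5,
    )


def make_params(**overrides) -> ModelParams:
    """ModelParams with distinct, mid-range defaults handy for tests."""
    base = dict(
        alpha=0.45, lam=0.6, eta=0.7, beta=1.3, pi=0.25, rho=-0.15,
        omega=dict(zip(OMEGA_KEYS, (0.25, 0.45, 0.6, 0.8))),
    )
    if "omega" in overrides and not isinstance(overrides["omega"], dict):
        overrides["omega"] = {k: overrides["omega"] for k in OMEGA_KEYS}
    base.update(overrides)
    return ModelParams(**base)


@pytest.fixture(scope="session")
def simulated_dataset(default_config) -> ChoiceDataset:
    seq = generate_trial_sequence(default_config)
    return simulate_agent(
        make_params(), seq, np.random.default_rng(7),
        participant_id="sim0", group="younger",
    )


def random_short_dataset(rng: np.random.Generator, config=None):
    """A hand-rolled dataset of <= 10 trials with random misses, for oracle
    comparisons. Built directly from dataclasses, not via the simulator."""
    if config is None:
        config = TaskConfig(
            n_blocks=2, trials_per_block=6,
            block_order=("stable", "variable"), seed=int(rng.integers(1 << 16)),
        )
    seq = generate_trial_sequence(config, rng)
    n = int(rng.integers(3, 11))
    mapping = seq.mapping_per_trial()
    observations = []
    for tr in seq.trials:
        i = tr.trial_index
        if i >= n:
            observations.append(
                TrialObservation(tr, None, None, None, False, None)
            )
            continue
        u = rng.random()
        if u < 0.15:  # first-stage miss
            observations.append(
                TrialObservation(tr, None, None, None, False, None)
            )
            continue
        a_loc = int(rng.integers(0, 2))
        a = 2 * tr.start_state + a_loc
        planet = int(mapping[i, tr.start_state, a_loc])
        if u < 0.3:  # second-stage miss
            observations.append(
                TrialObservation(tr, a, tr.key_of(a), planet, False, None)
            )
            continue
        reward = int(seq.reward_walks.values[planet, i])
        observations.append(
            TrialObservation(tr, a, tr.key_of(a), planet, True, reward)
        )
    return ChoiceDataset("rand", "synthetic", seq, tuple(observations))


def random_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        alpha=float(rng.uniform(0.01, 0.99)),
        lam=float(rng.uniform(0.01, 0.99)),
        eta=float(rng.uniform(0.01, 0.99)),
        beta=float(rng.uniform(0.0, 3.0)),
        pi=float(rng.normal(0, 1)),
        rho=float(rng.normal(0, 1)),
        omega={k: float(rng.uniform(0.0, 1.0)) for k in OMEGA_KEYS},
        eta_cf=float(rng.uniform(0.01, 0.99)) if rng.random() < 0.5 else None,
    )
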