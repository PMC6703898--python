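"""Array packing of sessions for the compiled likelihood/simulation kernels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ChoiceDataset, ModelParams
from .task import STABLE, TrialSequence


@dataclass(frozen=True)
class PackedDataset:
    """A session flattened to integer/flag arrays (one entry per trial).

    ``a_loc``/``key1``/``planet``/``reward`` are -1 on trials where they are
    undefined because of a miss. ``key0`` is the response key that selects
    local action 0 on each trial (side randomization).
    """

    s1: np.ndarray
    a_loc: np.ndarray
    key1: np.ndarray
    planet: np.ndarray
    reward: np.ndarray
    miss1: np.ndarray
    miss2: np.ndarray
    key0: np.ndarray
    cell: np.ndarray
    stable: np.ndarray
    q_init: float

    def arrays(self) -> tuple:
        """Positional arguments for the likelihood kernel."""
        return (
            self.s1, self.a_loc, self.key1, self.planet, self.reward,
            self.miss1, self.miss2, self.key0, self.q_init,
        )


def pack_sequence(sequence: TrialSequence) -> dict:
    """Static per-trial arrays of a sequence (used by the simulator)."""
    trials = sequence.trials
    n = len(trials)
    s1 = np.fromiter((t.start_state for t in trials), np.int64, n)
    key0 = np.fromiter(
        (0 if t.left_action == 2 * t.start_state else 1 for t in trials),
        np.int64, n,
    )
    cell = np.fromiter((t.cell for t in trials), np.int64, n)
    stable = np.fromiter(
        (t.block_condition == STABLE for t in trials), np.bool_, n
    )
    return {
        "s1": s1, "key0": key0, "cell": cell, "stable": stable,
        "mapping": sequence.mapping_per_trial(),
        "walks": sequence.reward_walks.values,
    }


def pack_dataset(dataset: ChoiceDataset) -> PackedDataset:
    seq = pack_sequence(dataset.sequence)
    n = len(dataset)
    a_loc = np.full(n, -1, np.int64)
    key1 = np.full(n, -1, np.int64)
    planet = np.full(n, -1, np.int64)
    reward = np.full(n, -1, np.int64)
    miss1 = np.zeros(n, np.bool_)
    miss2 = np.zeros(n, np.bool_)
    for i, obs in enumerate(dataset.observations):
        if obs.miss1:
            miss1[i] = True
            continue
        a_loc[i] = obs.action1 - 2 * obs.trial.start_state
        key1[i] = obs.key1 if obs.key1 is not None else obs.trial.key_of(obs.action1)
        planet[i] = obs.planet if obs.planet is not None else -1
        if obs.miss2 or obs.reward is None:
            miss2[i] = True
        else:
            reward[i] = obs.reward
    lo, hi = dataset.sequence.config.reward_bounds
    return PackedDataset(
        s1=seq["s1"], a_loc=a_loc, key1=key1, planet=planet, reward=reward,
        miss1=miss1, miss2=miss2, key0=seq["key0"], cell=seq["cell"],
        stable=seq["stable"], q_init=(lo + hi) / 2.0,
    )


def params_per_trial(
    cell: np.ndarray, stable: np.ndarray, params: ModelParams
) -> tuple:
    """Expand a ModelParams into per-trial parameter arrays.

    The kernel is condition-agnostic: all condition structure (omega per
    cell, eta pinned to 1 in stable blocks) is resolved here.
    """
    n = cell.shape[0]
    full = lambda v: np.full(n, float(v))
    omega_t = params.omega_vector()[cell]
    eta_t = np.where(stable, 1.0, params.eta)
    etacf_t = np.where(stable, 1.0, params.eta_cf_effective)
    return (
        full(params.alpha), full(params.lam), eta_t, etacf_t,
        omega_t, full(params.beta), full(params.pi), full(params.rho),
    )
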