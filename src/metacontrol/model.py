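"""Hybrid model-free/model-based reinforcement learner for the two-stage task.

The agent maintains (i) model-free reward expectations ``Q_MF`` for the four
first-stage spaceships and the two planets, updated by SARSA(lambda) temporal
difference learning, and (ii) a transition model ``T(planet | state, action)``
updated from state prediction errors, with a counterfactual update for the
unchosen action that exploits the task's anti-correlated structure. At choice
time the two valuations are mixed by a model-based weight ``omega`` fitted
separately for each (stakes, transition-condition) cell, and mapped to choice
probabilities by a softmax with inverse temperature ``beta`` plus choice- and
response-key-stickiness terms ``pi`` and ``rho``.

Value updates, with ``a`` the chosen first-stage action in state ``s1`` and
``p`` the planet reached with reward ``r``::

    d1 = Q_MF(p) - Q_MF(s1, a)           # first-stage prediction error
    d2 = r - Q_MF(p)                     # second-stage prediction error
    Q_MF(s1, a) += alpha * d1 + alpha * lam * d2
    Q_MF(p)     += alpha * d2

Transition updates push probability mass toward the observed planet for the
taken action (rate ``eta``; fixed at 1 in stable blocks) and toward the
complementary planet for the untaken action (rate ``eta_cf``), keeping each
row of ``T`` normalized.

:func:`sequence_loglik` evaluates the log-likelihood of a recorded session.
Two engines produce identical numbers: a pure-Python reference built from the
single-step operations in this module, and a compiled kernel
(:mod:`metacontrol._kernel`) used by the fitting routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import (
    CELL_ORDER,
    STABLE,
    TaskConfig,
    TrialSequence,
    TrialSpec,
)

OMEGA_KEYS = CELL_ORDER


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the hybrid learner.

    ``omega`` maps each (stakes, transition-condition) pair to a model-based
    weight in [0, 1]. ``eta_cf`` defaults to ``eta`` (single transition
    learning rate); pass it explicitly for the dual-rate model variant.
    """

    alpha: float = 0.5
    lam: float = 0.5
    eta: float = 0.5
    beta: float = 1.0
    pi: float = 0.0
    rho: float = 0.0
    omega: dict = field(
        default_factory=lambda: {k: 0.5 for k in OMEGA_KEYS}
    )
    eta_cf: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "eta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.eta_cf is not None and not 0.0 <= self.eta_cf <= 1.0:
            raise ValueError(f"eta_cf={self.eta_cf} outside [0, 1]")
        if self.beta < 0.0:
            raise ValueError(f"beta={self.beta} must be >= 0")
        if set(self.omega) != set(OMEGA_KEYS):
            raise ValueError(f"omega must have exactly the keys {OMEGA_KEYS}")
        for k, v in self.omega.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"omega[{k}]={v} outside [0, 1]")

    @property
    def eta_cf_effective(self) -> float:
        return self.eta if self.eta_cf is None else self.eta_cf

    def omega_vector(self) -> np.ndarray:
        """Weights in canonical cell order (low/stable, high/stable,
        low/variable, high/variable)."""
        return np.array([self.omega[k] for k in OMEGA_KEYS])


@dataclass
class LearnerState:
    """Mutable beliefs of the agent.

    ``q_mf_stage1[s, a_local]`` are first-stage values, ``q_mf_stage2[p]``
    planet values (treasure units), ``transition[s, a_local, p]`` the learned
    transition probabilities. ``prev_action`` is the previous trial's chosen
    spaceship (global id) and ``prev_key`` its response key; both are -1
    before any valid response and persist across missed trials.
    """

    q_mf_stage1: np.ndarray
    q_mf_stage2: np.ndarray
    transition: np.ndarray
    prev_action: int = -1
    prev_key: int = -1

    def copy(self) -> "LearnerState":
        return LearnerState(
            self.q_mf_stage1.copy(),
            self.q_mf_stage2.copy(),
            self.transition.copy(),
            self.prev_action,
            self.prev_key,
        )


@dataclass(frozen=True)
class TrialObservation:
    """One trial of a behavioral record. Missing entries are None / -1.

    A first-stage miss (``action1`` is None) implies no planet and no reward;
    a second-stage miss (``action2_made`` False) implies the planet was seen
    but no reward obtained.
    """

    trial: TrialSpec
    action1: int | None
    key1: int | None
    planet: int | None
    action2_made: bool
    reward: int | None
    rt1: float | None = None
    rt2: float | None = None

    def __post_init__(self) -> None:
        if self.action1 is None and (self.planet is not None or self.reward is not None):
            raise ValueError("first-stage miss cannot have planet or reward")
        if not self.action2_made and self.reward is not None:
            raise ValueError("second-stage miss cannot have reward")

    @property
    def miss1(self) -> bool:
        return self.action1 is None

    @property
    def miss2(self) -> bool:
        return not self.miss1 and not self.action2_made


@dataclass
class ChoiceDataset:
    """One participant's session: the generated sequence plus their record."""

    participant_id: str
    group: str
    sequence: TrialSequence
    observations: tuple[TrialObservation, ...]

    def __post_init__(self) -> None:
        if len(self.observations) != len(self.sequence):
            raise ValueError("observations must align with the trial sequence")

    def __len__(self) -> int:
        return len(self.observations)


# ---------------------------------------------------------------------------
# single-step operations (reference path)
# ---------------------------------------------------------------------------

def init_state(config: TaskConfig) -> LearnerState:
    """Agent beliefs before the first trial.

    All reward expectations start at the midpoint of the reward bounds (4.5
    for bounds 0 and 9) and all transition probabilities at 0.5: agents know
    the reward range but not the initial transition structure.
    """
    lo, hi = config.reward_bounds
    mid = (lo + hi) / 2.0
    return LearnerState(
        q_mf_stage1=np.full((2, 2), mid),
        q_mf_stage2=np.full(2, mid),
        transition=np.full((2, 2, 2), 0.5),
    )


def mb_values(state: LearnerState, s1: int) -> np.ndarray:
    """Model-based values of the two actions in first-stage state ``s1``:
    planet values weighted by the learned transition probabilities."""
    return state.transition[s1] @ state.q_mf_stage2


def choice_prob(
    state: LearnerState,
    s1: int,
    params: ModelParams,
    omega_key: tuple[str, str],
    layout: tuple[int, int],
) -> np.ndarray:
    """First-stage choice probabilities over the state's two local actions.

    ``layout[a_local]`` is the response key selecting local action ``a_local``
    on this trial. Uses pre-update beliefs; softmax computed with max
    subtraction for numerical stability.
    """
    omega = params.omega[omega_key]
    q_net = (1.0 - omega) * state.q_mf_stage1[s1] + omega * mb_values(state, s1)
    rep = np.array(
        [1.0 if state.prev_action == 2 * s1 + a else 0.0 for a in range(2)]
    )
    resp = np.array(
        [1.0 if state.prev_key == layout[a] else 0.0 for a in range(2)]
    )
    logits = params.beta * q_net + params.pi * rep + params.rho * resp
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def mf_update(
    state: LearnerState, obs: TrialObservation, params: ModelParams
) -> LearnerState:
    """SARSA(lambda) reward update for a completed trial (returns a new state)."""
    if obs.action1 is None or obs.planet is None or obs.reward is None:
        raise ValueError("mf_update requires action1, planet and reward")
    out = state.copy()
    s1 = obs.trial.start_state
    a = obs.action1 - 2 * s1
    d1 = state.q_mf_stage2[obs.planet] - state.q_mf_stage1[s1, a]
    d2 = obs.reward - state.q_mf_stage2[obs.planet]
    out.q_mf_stage1[s1, a] += params.alpha * d1 + params.alpha * params.lam * d2
    out.q_mf_stage2[obs.planet] += params.alpha * d2
    return out


def transition_update(
    state: LearnerState, obs: TrialObservation, eta: float, eta_cf: float
) -> LearnerState:
    """Update transition beliefs from an observed transition.

    The taken action's row moves toward the observed planet at rate ``eta``;
    the untaken action's row moves toward the complementary planet at rate
    ``eta_cf`` (counterfactual inference from the anti-correlated structure).
    Both rows remain normalized exactly.
    """
    if obs.action1 is None or obs.planet is None:
        raise ValueError("transition_update requires action1 and planet")
    out = state.copy()
    s1 = obs.trial.start_state
    a = obs.action1 - 2 * s1
    p = obs.planet
    T = out.transition
    # factual: push T(p | s1, a) toward 1
    spe = 1.0 - T[s1, a, p]
    T[s1, a, p] += eta * spe
    T[s1, a, 1 - p] *= 1.0 - eta
    # counterfactual: the other action should lead to the other planet
    cf = 1.0 - T[s1, 1 - a, 1 - p]
    T[s1, 1 - a, 1 - p] += eta_cf * cf
    T[s1, 1 - a, p] *= 1.0 - eta_cf
    return out


def _advance(
    state: LearnerState, obs: TrialObservation, params: ModelParams
) -> LearnerState:
    """Apply one trial's updates in canonical order (transition, then reward),
    maintaining the stickiness memory. No-op for first-stage misses."""
    if obs.miss1:
        return state
    cond = obs.trial.block_condition
    eta = 1.0 if cond == STABLE else params.eta
    eta_cf = 1.0 if cond == STABLE else params.eta_cf_effective
    state = transition_update(state, obs, eta, eta_cf)
    if obs.reward is not None:
        state = mf_update(state, obs, params)
    state.prev_action = obs.action1
    state.prev_key = obs.key1 if obs.key1 is not None else obs.trial.key_of(obs.action1)
    return state


def sequence_loglik(
    dataset: ChoiceDataset,
    params: ModelParams,
    engine: str = "numba",
) -> float:
    """Log-likelihood of the first-stage choices in a session.

    Trials with a missed first-stage response contribute no likelihood term
    and trigger no updates. Trials with a missed second-stage response
    contribute their first-stage term and the transition update (the planet
    was observed) but no reward update. ``eta`` (and ``eta_cf``) are fixed at
    1 in stable blocks.
    """
    if engine == "numba":
        from ._kernel import loglik_packed
        from ._pack import pack_dataset, params_per_trial

        packed = pack_dataset(dataset)
        ll = loglik_packed(
            *packed.arrays(),
            *params_per_trial(packed.cell, packed.stable, params),
        )
        if np.isnan(ll):
            raise FloatingPointError("log-likelihood accumulated NaN")
        return float(ll)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    state = init_state(dataset.sequence.config)
    total = 0.0
    for obs in dataset.observations:
        if obs.miss1:
            continue
        tr = obs.trial
        layout = tuple(tr.key_of(a) for a in tr.actions())
        probs = choice_prob(
            state, tr.start_state, params, (tr.stakes, tr.block_condition), layout
        )
        a_local = obs.action1 - 2 * tr.start_state
        total += float(np.log(probs[a_local]))
        state = _advance(state, obs, params)
    if np.isnan(total):
        raise FloatingPointError("log-likelihood accumulated NaN")
    return total


def replay(dataset: ChoiceDataset, params: ModelParams) -> dict:
    """Replay the learner over a recorded session at fixed parameters.

    Returns per-trial traces (NaN where undefined because of misses):

    - ``logp_choice``: log-probability of the observed first-stage choice
    - ``p_choice``: that probability
    - ``q2_visited``: pre-update Q_MF of the visited planet (the model's
      second-stage reward expectation at arrival, used as an RT covariate)
    """
    n = len(dataset)
    logp = np.full(n, np.nan)
    q2v = np.full(n, np.nan)
    state = init_state(dataset.sequence.config)
    for i, obs in enumerate(dataset.observations):
        if obs.miss1:
            continue
        tr = obs.trial
        layout = tuple(tr.key_of(a) for a in tr.actions())
        probs = choice_prob(
            state, tr.start_state, params, (tr.stakes, tr.block_condition), layout
        )
        a_local = obs.action1 - 2 * tr.start_state
        logp[i] = np.log(probs[a_local])
        if obs.planet is not None:
            q2v[i] = state.q_mf_stage2[obs.planet]
        state = _advance(state, obs, params)
    return {
        "logp_choice": logp,
        "p_choice": np.exp(logp),
        "q2_visited": q2v,
    }
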