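"""Two-stage sequential decision task: environment generation and stepping.

The task runs in alternating *stable* and *variable* transition blocks. Every
trial starts in one of two first-stage states, each offering two actions
(spaceships) that lead deterministically to one of two second-stage states
(planets). Planet rewards drift as reflected, integer-rounded Gaussian random
walks. In variable blocks the action->planet mapping of one first-stage state
reverses every 6-14 trials. A per-trial stakes cue multiplies the obtained
reward into points (low x1, high x5).

Conventions: trials, blocks, states, planets are 0-based. Actions carry a
global spaceship identity 0..3; state ``s`` owns actions ``2s`` and ``2s+1``.
Response keys are 0 (left) and 1 (right); the screen side of each action is
randomized per trial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STABLE = "stable"
VARIABLE = "variable"
LOW = "low"
HIGH = "high"

#: condition-cell index used throughout: (stakes, transition-condition)
CELL_ORDER = ((LOW, STABLE), (HIGH, STABLE), (LOW, VARIABLE), (HIGH, VARIABLE))
CELL_INDEX = {key: i for i, key in enumerate(CELL_ORDER)}


def cell_of(stakes: str, block_condition: str) -> int:
    """Index of the (stakes, transition-condition) cell in :data:`CELL_ORDER`."""
    return CELL_INDEX[(stakes, block_condition)]


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the two-stage task.

    Defaults reproduce the published design: 320 trials in four alternating
    80-trial blocks, reversals every 6-14 trials in variable blocks, reward
    walks with sd 2 reflected at 0 and 9, stakes multipliers 1 and 5, and
    response deadlines of 3 s (first stage) and 2 s (second stage).
    """

    n_blocks: int = 4
    trials_per_block: int = 80
    block_order: tuple[str, ...] = (STABLE, VARIABLE, STABLE, VARIABLE)
    reversal_interval: tuple[int, int] = (6, 14)
    reward_walk_sd: float = 2.0
    reward_bounds: tuple[int, int] = (0, 9)
    stakes_multipliers: dict = field(
        default_factory=lambda: {LOW: 1, HIGH: 5}
    )
    stage1_deadline: float = 3.0
    stage2_deadline: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if len(self.block_order) != self.n_blocks:
            raise ValueError("block_order length must equal n_blocks")
        if any(b not in (STABLE, VARIABLE) for b in self.block_order):
            raise ValueError(f"block conditions must be '{STABLE}' or '{VARIABLE}'")
        lo, hi = self.reversal_interval
        if lo > hi:
            raise ValueError("reversal_interval must satisfy min <= max")
        if lo < 1:
            raise ValueError("reversal_interval.min must be >= 1")
        if self.reward_bounds[0] >= self.reward_bounds[1]:
            raise ValueError("reward_bounds must satisfy lo < hi")
        if self.reward_walk_sd < 0:
            raise ValueError("reward_walk_sd must be non-negative")
        if any(m < 1 for m in self.stakes_multipliers.values()):
            raise ValueError("stakes multipliers must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class TrialSpec:
    """Static description of one trial, fixed before the agent responds."""

    trial_index: int
    block_index: int
    block_condition: str
    start_state: int
    stakes: str
    left_action: int  # global id of the spaceship displayed on the left

    @property
    def cell(self) -> int:
        return cell_of(self.stakes, self.block_condition)

    def key_of(self, action: int) -> int:
        """Response key (0 left / 1 right) that selects a global action id."""
        return 0 if action == self.left_action else 1

    def actions(self) -> tuple[int, int]:
        s = self.start_state
        return (2 * s, 2 * s + 1)


@dataclass(frozen=True)
class TransitionStructure:
    """Deterministic action->planet assignment, anti-correlated within state.

    ``mapping[s, a_local]`` is the planet reached from first-stage state ``s``
    by its local action ``a_local``; the two actions of a state always lead to
    distinct planets.
    """

    mapping: np.ndarray  # shape (2, 2), entries in {0, 1}

    def __post_init__(self) -> None:
        m = np.asarray(self.mapping, dtype=np.int64)
        object.__setattr__(self, "mapping", m)
        if m.shape != (2, 2) or not np.isin(m, (0, 1)).all():
            raise ValueError("mapping must be (2, 2) with planet entries 0/1")
        if (m[:, 0] == m[:, 1]).any():
            raise ValueError("actions within a state must lead to distinct planets")

    def planet(self, start_state: int, action: int) -> int:
        return int(self.mapping[start_state, action - 2 * start_state])


@dataclass(frozen=True)
class ReversalSchedule:
    """Trials at which one first-stage state's spaceships swap destinations."""

    events: tuple[tuple[int, int], ...]  # (trial_index, affected_start_state)

    def affected_at(self, trial_index: int) -> int:
        """Affected state if a reversal takes effect at this trial, else -1."""
        for t, s in self.events:
            if t == trial_index:
                return s
        return -1


@dataclass(frozen=True)
class RewardWalks:
    """Per-planet integer reward trajectories, shape (2, n_trials)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))


@dataclass(frozen=True)
class TrialSequence:
    """A complete generated session: trials, reversals, walks, initial mapping."""

    config: TaskConfig
    trials: tuple[TrialSpec, ...]
    reversal_schedule: ReversalSchedule
    reward_walks: RewardWalks
    initial_transitions: TransitionStructure

    def __len__(self) -> int:
        return len(self.trials)

    def mapping_per_trial(self) -> np.ndarray:
        """Action->planet mapping in effect at every trial, shape (n, 2, 2).

        A reversal event at trial ``t`` takes effect from trial ``t`` onward.
        """
        n = len(self.trials)
        out = np.empty((n, 2, 2), dtype=np.int64)
        current = self.initial_transitions
        for t in range(n):
            s = self.reversal_schedule.affected_at(t)
            if s >= 0:
                current = apply_reversal(current, s)
            out[t] = current.mapping
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format export, one row per trial.

        ``map_s0``/``map_s1`` record the planet reached by local action 0 of
        each start state on that trial, making the export lossless.
        """
        events = dict(self.reversal_schedule.events)
        mapping = self.mapping_per_trial()
        rows = []
        for tr in self.trials:
            t = tr.trial_index
            rows.append(
                {
                    "trial": t,
                    "block": tr.block_index,
                    "block_condition": tr.block_condition,
                    "start_state": tr.start_state,
                    "stakes": tr.stakes,
                    "left_action": tr.left_action,
                    "reward_red": int(self.reward_walks.values[0, t]),
                    "reward_purple": int(self.reward_walks.values[1, t]),
                    "reversal_event": int(t in events),
                    "affected_state": events.get(t, -1),
                    "map_s0": int(mapping[t, 0, 0]),
                    "map_s1": int(mapping[t, 1, 0]),
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: TaskConfig) -> "TrialSequence":
        frame = frame.sort_values("trial")
        trials = tuple(
            TrialSpec(
                trial_index=int(r.trial),
                block_index=int(r.block),
                block_condition=str(r.block_condition),
                start_state=int(r.start_state),
                stakes=str(r.stakes),
                left_action=int(r.left_action),
            )
            for r in frame.itertuples()
        )
        events = tuple(
            (int(r.trial), int(r.affected_state))
            for r in frame.itertuples()
            if int(r.reversal_event) == 1
        )
        walks = RewardWalks(
            np.stack([frame["reward_red"].to_numpy(np.int64),
                      frame["reward_purple"].to_numpy(np.int64)])
        )
        first = frame.iloc[0]
        initial = TransitionStructure(
            np.array(
                [[int(first.map_s0), 1 - int(first.map_s0)],
                 [int(first.map_s1), 1 - int(first.map_s1)]]
            )
        )
        return cls(config, trials, ReversalSchedule(events), walks, initial)


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold excursions past either bound back symmetrically until inside
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
    return x


def generate_reward_walks(
    config: TaskConfig, n_trials: int, rng: np.random.Generator
) -> RewardWalks:
    """Generate the two planets' reward trajectories.

    Each planet follows an independent Gaussian random walk (zero-mean
    increments with sd ``reward_walk_sd``) reflected at the reward bounds. The
    latent walk is continuous; the emitted reward is the latent value rounded
    to the nearest integer. Initial values are drawn uniformly over the
    integer bounds.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = config.reward_bounds
    out = np.empty((2, n_trials), dtype=np.int64)
    for p in range(2):
        x = float(rng.integers(lo, hi + 1))
        out[p, 0] = round(x)
        for t in range(1, n_trials):
            x = _reflect(x + rng.normal(0.0, config.reward_walk_sd), lo, hi)
            out[p, t] = round(x)
    return RewardWalks(out)


def _balanced_block_cells(n: int, rng: np.random.Generator) -> list[tuple[int, str]]:
    """(start_state, stakes) assignments for one block.

    Exactly half the trials get each stakes level and, within each stakes
    level, the two start states appear as evenly as possible (exactly evenly
    when n is divisible by 4). Order is randomized.
    """
    if n % 2:
        raise ValueError("trials_per_block must be even to balance stakes")
    cells: list[tuple[int, str]] = []
    for stakes in (LOW, HIGH):
        half = n // 2
        n0 = half // 2
        n1 = half - n0
        cells += [(0, stakes)] * n0 + [(1, stakes)] * n1
    perm = rng.permutation(len(cells))
    return [cells[i] for i in perm]


def _block_reversals(
    block_start: int, block_len: int, interval: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    lo, hi = interval
    events = []
    pos = block_start + int(rng.integers(lo, hi + 1))
    while pos < block_start + block_len:
        events.append((pos, int(rng.integers(0, 2))))
        pos += int(rng.integers(lo, hi + 1))
    return events


def generate_trial_sequence(
    config: TaskConfig, rng: np.random.Generator | None = None
) -> TrialSequence:
    """Generate a full session from a config (seeded by ``config.seed`` if no
    generator is supplied)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    walks = generate_reward_walks(config, n, rng)

    trials: list[TrialSpec] = []
    events: list[tuple[int, int]] = []
    for b, cond in enumerate(config.block_order):
        start = b * config.trials_per_block
        for i, (state, stakes) in enumerate(
            _balanced_block_cells(config.trials_per_block, rng)
        ):
            left = 2 * state + int(rng.integers(0, 2))
            trials.append(
                TrialSpec(start + i, b, cond, state, stakes, left_action=left)
            )
        if cond == VARIABLE:
            events += _block_reversals(
                start, config.trials_per_block, config.reversal_interval, rng
            )

    # randomize the initial assignment of both states independently
    m = np.empty((2, 2), dtype=np.int64)
    for s in range(2):
        first = int(rng.integers(0, 2))
        m[s] = (first, 1 - first)
    initial = TransitionStructure(m)

    return TrialSequence(
        config=config,
        trials=tuple(trials),
        reversal_schedule=ReversalSchedule(tuple(events)),
        reward_walks=walks,
        initial_transitions=initial,
    )


def apply_reversal(structure: TransitionStructure, state: int) -> TransitionStructure:
    """Swap the destination planets of one first-stage state's two actions."""
    if state not in (0, 1):
        raise ValueError("state must be 0 or 1")
    m = structure.mapping.copy()
    m[state] = m[state, ::-1]
    return TransitionStructure(m)


def step(
    structure: TransitionStructure,
    trial: TrialSpec,
    action: int,
    walks: RewardWalks,
    config: TaskConfig,
) -> tuple[int, int, int]:
    """Resolve one trial: returns (planet, reward in treasure, points).

    ``action`` is the global spaceship id and must belong to the trial's
    start state. Points are the reward multiplied by the stakes factor.
    """
    if action not in trial.actions():
        raise ValueError(
            f"action {action} not available in start state {trial.start_state}"
        )
    planet = structure.planet(trial.start_state, action)
    reward = int(walks.values[planet, trial.trial_index])
    points = reward * int(config.stakes_multipliers[trial.stakes])
    return planet, reward, points
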