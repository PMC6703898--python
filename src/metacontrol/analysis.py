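"""Downstream behavioral analyses: performance, revaluation, matching, RTs.

- *Baseline-corrected reward*: obtained reward minus the mean reward
  currently available on the two planets, before stakes multiplication.
  Removes the common drift of the reward walks from performance measures.
- *Revaluation trials*: the first trial on which a changed action->planet
  mapping is observed, i.e. the first valid visit to the affected first-stage
  state after a reversal event.
- *Performance matching*: mutual-nearest-neighbor pairing of participants
  across groups on mean baseline-corrected reward.
- *RT preprocessing* and the construction of regression tables (effect-coded
  model-based weights; dummy-coded revaluation RT analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ChoiceDataset, ModelParams, OMEGA_KEYS, replay
from .task import VARIABLE

#: effect codes used for the model-based-weight regressions
EFFECT_CODES = {
    "group": {"younger": 0.5, "older": -0.5},
    "stakes": {"low": -0.5, "high": 0.5},
    "transition": {"stable": 0.5, "variable": -0.5},
}
#: dummy codes used for the revaluation RT regression
DUMMY_CODES = {"group": {"younger": 0, "older": 1}}

RT_CUTOFF_MS = 200.0


def baseline_corrected_reward(
    dataset: ChoiceDataset,
) -> tuple[np.ndarray, float]:
    """Per-trial baseline-corrected reward and its session mean.

    Each valid trial contributes ``r - (walk_red + walk_purple) / 2`` in
    unmultiplied treasure units; trials without an obtained reward are NaN
    and excluded from the mean.
    """
    walks = dataset.sequence.reward_walks.values
    n = len(dataset)
    out = np.full(n, np.nan)
    for i, obs in enumerate(dataset.observations):
        if obs.reward is None:
            continue
        out[i] = obs.reward - (walks[0, i] + walks[1, i]) / 2.0
    mean = float(np.nanmean(out)) if np.any(~np.isnan(out)) else float("nan")
    return out, mean


def identify_revaluation_trials(dataset: ChoiceDataset) -> np.ndarray:
    """Boolean flag per trial marking first observations of a changed mapping.

    After a reversal event affecting state ``s``, the first subsequent trial
    that starts in ``s`` with a valid first-stage response is flagged (a
    second-stage miss does not block the flag: the planet is displayed on
    arrival). Multiple reversals of the same state before it is revisited
    collapse into a single flag at that first visit.
    """
    n = len(dataset)
    flags = np.zeros(n, dtype=bool)
    pending = [False, False]
    events = dict(dataset.sequence.reversal_schedule.events)
    for i, obs in enumerate(dataset.observations):
        s_affected = events.get(i)
        if s_affected is not None:
            pending[s_affected] = True
        s = obs.trial.start_state
        if pending[s] and not obs.miss1:
            flags[i] = True
            pending[s] = False
    return flags


@dataclass(frozen=True)
class MatchedSample:
    """Mutual-nearest-neighbor pairs plus the participants left unmatched."""

    pairs: tuple[tuple[str, str], ...]
    unmatched: tuple[str, ...]


def performance_match(group_a: dict, group_b: dict) -> MatchedSample:
    """Match participants across two groups on a scalar performance score.

    ``group_a`` and ``group_b`` map participant id -> mean baseline-corrected
    reward. Each participant's candidate partner is the other group's member
    with the smallest absolute score difference (ties broken by the
    lexicographically smaller id); a pair enters the matched sample only if
    the assignment is mutual. The result is symmetric in group order.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    def nearest(pid: str, score: float, other: dict) -> str:
        return min(
            sorted(other), key=lambda q: (abs(other[q] - score), q)
        )

    pairs = []
    for pid in sorted(group_a):
        partner = nearest(pid, group_a[pid], group_b)
        if nearest(partner, group_b[partner], group_a) == pid:
            pairs.append((pid, partner))
    matched = {p for pair in pairs for p in pair}
    unmatched = tuple(sorted((set(group_a) | set(group_b)) - matched))
    return MatchedSample(pairs=tuple(pairs), unmatched=unmatched)


def participant_summaries(datasets) -> pd.DataFrame:
    """Per-participant session summaries (id, group, mean baseline-corrected
    reward)."""
    rows = []
    for ds in datasets:
        _, mean = baseline_corrected_reward(ds)
        rows.append(
            {
                "participant": ds.participant_id,
                "group": ds.group,
                "mean_bc_reward": mean,
            }
        )
    return pd.DataFrame(rows)


def omega_long_table(fit_frame: pd.DataFrame) -> pd.DataFrame:
    """Long-format model-based-weight table for the effect-coded regression.

    Input: one row per participant with the four ``omega_*`` columns (plus
    ``participant`` and ``group``). Output: four rows per participant with
    effect-coded predictors and their interactions.
    """
    rows = []
    for r in fit_frame.itertuples():
        for (stakes, trans) in OMEGA_KEYS:
            age = EFFECT_CODES["group"][r.group]
            s = EFFECT_CODES["stakes"][stakes]
            t = EFFECT_CODES["transition"][trans]
            rows.append(
                {
                    "participant": r.participant,
                    "omega": getattr(r, f"omega_{stakes}_{trans}"),
                    "age": age,
                    "stakes": s,
                    "transition": t,
                    "age_x_stakes": age * s,
                    "age_x_transition": age * t,
                    "stakes_x_transition": s * t,
                }
            )
    return pd.DataFrame(rows)


def rt_preprocess(
    datasets,
    expectation_fits: dict | None = None,
) -> pd.DataFrame:
    """Analysis table for the revaluation reaction-time regression.

    Keeps variable-block trials with a valid second-stage response and
    ``rt2 >= 200`` ms (strictly-below-cutoff trials dropped). The outcome is
    the natural log of rt2 in ms; ``revaluation`` and ``old`` are dummy-coded
    (0/1). If ``expectation_fits`` maps participant id -> FitResult, the
    model-derived second-stage reward expectation is attached as an
    ``expectation`` column.
    """
    rows = []
    for ds in datasets:
        reval = identify_revaluation_trials(ds)
        expect = None
        if expectation_fits is not None:
            expect = expectation_covariate(ds, expectation_fits[ds.participant_id])
        for i, obs in enumerate(ds.observations):
            if obs.trial.block_condition != VARIABLE:
                continue
            if obs.miss1 or obs.miss2 or obs.rt2 is None:
                continue
            if obs.rt2 < RT_CUTOFF_MS:
                continue
            row = {
                "participant": ds.participant_id,
                "log_rt2": float(np.log(obs.rt2)),
                "revaluation": int(reval[i]),
                "old": DUMMY_CODES["group"][ds.group],
            }
            row["old_x_revaluation"] = row["old"] * row["revaluation"]
            if expect is not None:
                row["expectation"] = float(expect[i])
            rows.append(row)
    return pd.DataFrame(rows)


def expectation_covariate(dataset: ChoiceDataset, fit) -> np.ndarray:
    """Trial-wise second-stage reward expectation under a fitted model.

    Replays the learner at the fitted parameters and returns the model-free
    value of the visited planet immediately before its reward update (NaN on
    first-stage misses). ``fit`` may be a FitResult or a ModelParams.
    """
    params = fit if isinstance(fit, ModelParams) else fit.params_hat
    if params is None:
        raise ValueError("expectation covariate needs a standard-layout fit")
    return replay(dataset, params)["q2_visited"]
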