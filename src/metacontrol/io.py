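"""Configuration, CSV/JSON serialization and pipeline orchestration.

Data files are plain CSV: one sequence file (one row per trial per sequence)
and one behavioral file (one row per trial per participant). Missing values
are empty fields, miss flags 0/1 integers, floats written at full precision
so that a write/read round trip is lossless. Run configuration is YAML (JSON
is a subset); the pipeline writes a JSON manifest listing every produced
artifact with its stage seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as _analysis
from . import fitting as _fitting
from . import regression as _regression
from .cohorts import CohortSpec, RTGenSpec, effect_coded_shifts, simulate_cohort
from .model import ChoiceDataset, TrialObservation
from .task import TaskConfig, TrialSequence

CHOICE_COLUMNS = [
    "participant", "group", "trial", "block", "block_condition", "stakes",
    "start_state", "left_action", "action1", "key1", "planet", "reward",
    "points", "rt1_ms", "rt2_ms", "miss1", "miss2",
]


class SchemaError(ValueError):
    """A CSV file does not match the documented schema."""


def write_sequence_csv(sequences: dict[str, TrialSequence], path) -> None:
    """Write named trial sequences to one CSV (column ``sequence_id``)."""
    frames = []
    for sid, seq in sequences.items():
        frame = seq.to_frame()
        frame.insert(0, "sequence_id", sid)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sequence_csv(path, config: TaskConfig) -> dict[str, TrialSequence]:
    frame = pd.read_csv(path)
    return {
        str(sid): TrialSequence.from_frame(sub, config)
        for sid, sub in frame.groupby("sequence_id", sort=True)
    }


def choice_frame(dataset: ChoiceDataset) -> pd.DataFrame:
    """One participant's record as a long-format table."""
    mult = dataset.sequence.config.stakes_multipliers
    rows = []
    for obs in dataset.observations:
        tr = obs.trial
        reward = obs.reward
        rows.append(
            {
                "participant": dataset.participant_id,
                "group": dataset.group,
                "trial": tr.trial_index,
                "block": tr.block_index,
                "block_condition": tr.block_condition,
                "stakes": tr.stakes,
                "start_state": tr.start_state,
                "left_action": tr.left_action,
                "action1": obs.action1,
                "key1": obs.key1,
                "planet": obs.planet,
                "reward": reward,
                "points": None if reward is None else reward * mult[tr.stakes],
                "rt1_ms": obs.rt1,
                "rt2_ms": obs.rt2,
                "miss1": int(obs.miss1),
                "miss2": int(obs.miss2),
            }
        )
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


def write_choice_csv(datasets, path) -> None:
    pd.concat(
        [choice_frame(ds) for ds in datasets], ignore_index=True
    ).to_csv(path, index=False, float_format=None)


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def read_choice_csv(path, sequences) -> list[ChoiceDataset]:
    """Read a behavioral CSV back into datasets.

    ``sequences`` maps participant id -> TrialSequence (or is a single
    sequence shared by everyone). Validates the schema, trial contiguity and
    miss-flag consistency.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(CHOICE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    out = []
    for pid, sub in frame.groupby("participant", sort=False):
        sub = sub.sort_values("trial")
        trials = sub["trial"].to_numpy()
        if len(trials) and not np.array_equal(
            trials, np.arange(trials[0], trials[0] + len(trials))
        ):
            raise SchemaError(f"non-contiguous trial indices for {pid}")
        seq = sequences[str(pid)] if isinstance(sequences, dict) else sequences
        observations = []
        for r, spec_trial in zip(sub.itertuples(), seq.trials):
            miss1, miss2 = bool(r.miss1), bool(r.miss2)
            rt2 = _opt_float(r.rt2_ms)
            if miss2 and rt2 is not None:
                raise SchemaError(
                    f"participant {pid} trial {r.trial}: rt2_ms present "
                    "but miss2 = 1"
                )
            if miss1:
                observations.append(
                    TrialObservation(spec_trial, None, None, None, False, None)
                )
                continue
            observations.append(
                TrialObservation(
                    trial=spec_trial,
                    action1=_opt_int(r.action1),
                    key1=_opt_int(r.key1),
                    planet=_opt_int(r.planet),
                    action2_made=not miss2,
                    reward=_opt_int(r.reward),
                    rt1=_opt_float(r.rt1_ms),
                    rt2=rt2,
                )
            )
        out.append(
            ChoiceDataset(str(pid), str(sub["group"].iloc[0]), seq,
                          tuple(observations))
        )
    return out


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    variant: str = "standard"
    n_restarts: int = 100
    priors: _fitting.PriorSpec = field(default_factory=_fitting.PriorSpec)
    regression_iterations: int = 2000
    regression_warmup: int = 1000
    regression_chains: int = 4
    n_ppc_participants: int = 3
    n_ppc_sims: int = 50
    output_dir: str = "metacontrol_run"
    global_seed: int = 0


def _build_cohort_spec(d: dict, global_seed: int) -> CohortSpec:
    kwargs = dict(d)
    if "omega_effects" in kwargs:
        kwargs["planted_omega_effects"] = effect_coded_shifts(
            **kwargs.pop("omega_effects")
        )
    if "rt_model" in kwargs and isinstance(kwargs["rt_model"], dict):
        kwargs["rt_model"] = RTGenSpec(**kwargs["rt_model"])
    kwargs.setdefault("seed", global_seed)
    return CohortSpec(**kwargs)


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from YAML (JSON accepted)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return run_config_from_dict(raw)


def run_config_from_dict(raw: dict) -> RunConfig:
    seed = int(raw.get("global_seed", 0))
    task_kwargs = dict(raw.get("task", {}))
    if "block_order" in task_kwargs:
        task_kwargs["block_order"] = tuple(task_kwargs["block_order"])
    if "reversal_interval" in task_kwargs:
        task_kwargs["reversal_interval"] = tuple(task_kwargs["reversal_interval"])
    if "reward_bounds" in task_kwargs:
        task_kwargs["reward_bounds"] = tuple(task_kwargs["reward_bounds"])
    fitting_kwargs = dict(raw.get("fitting", {}))
    priors = _fitting.PriorSpec(**fitting_kwargs.pop("priors", {}))
    analysis_kwargs = dict(raw.get("analysis", {}))
    return RunConfig(
        task=TaskConfig(**task_kwargs),
        cohort=_build_cohort_spec(dict(raw.get("cohort", {})), seed),
        variant=fitting_kwargs.get("variant", "standard"),
        n_restarts=int(fitting_kwargs.get("n_restarts", 100)),
        priors=priors,
        regression_iterations=int(analysis_kwargs.get("iterations", 2000)),
        regression_warmup=int(analysis_kwargs.get("warmup", 1000)),
        regression_chains=int(analysis_kwargs.get("chains", 4)),
        n_ppc_participants=int(raw.get("n_ppc_participants", 3)),
        n_ppc_sims=int(raw.get("n_ppc_sims", 50)),
        output_dir=str(raw.get("output_dir", "metacontrol_run")),
        global_seed=seed,
    )


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        _stringify_keys(dataclasses.asdict(config)), sort_keys=True,
        default=str,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records completed stages."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.manifest = manifest


STAGES = ("simulate", "fit", "recover", "ppc", "analyze")


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute pipeline stages and write a manifest.

    Stages consume the files earlier stages wrote to ``output_dir``, so a
    later stage can be rerun alone as long as its inputs exist. Rerunning
    with the same config reproduces identical numeric outputs: all
    randomness derives from ``global_seed`` through fixed, named substreams.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.global_seed)
    stage_seeds = {
        name: seq for name, seq in zip(STAGES, root.spawn(len(STAGES)))
    }
    manifest = {
        "config_hash": _config_hash(config),
        "global_seed": config.global_seed,
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, files: list[str], t0: float) -> None:
        manifest["stages"][stage] = {
            "files": files,
            "seed_entropy": int(stage_seeds[stage].entropy),
            "spawn_key": [int(k) for k in stage_seeds[stage].spawn_key],
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    current = None
    try:
        if "simulate" in stages:
            current = "simulate"
            t0 = time.perf_counter()
            spec = dataclasses.replace(config.cohort, seed=config.cohort.seed)
            datasets, truth = simulate_cohort(spec, config.task)
            seqs = {}
            seq_ids = {}
            for ds in datasets:
                key = next(
                    (k for k, v in seqs.items() if v is ds.sequence), None
                )
                if key is None:
                    key = f"seq{len(seqs)}"
                    seqs[key] = ds.sequence
                seq_ids[ds.participant_id] = key
            write_sequence_csv(seqs, out / "sequences.csv")
            write_choice_csv(datasets, out / "choices.csv")
            truth.to_csv(out / "truth.csv", index=False)
            (out / "sequence_assignment.json").write_text(json.dumps(seq_ids))
            record("simulate", ["sequences.csv", "choices.csv", "truth.csv",
                                "sequence_assignment.json"], t0)

        if "fit" in stages:
            current = "fit"
            t0 = time.perf_counter()
            datasets = _load_datasets(out, config)
            rng = np.random.default_rng(stage_seeds["fit"])
            _, fit_frame = _fitting.fit_cohort(
                datasets, config.variant, config.priors,
                config.n_restarts, rng,
            )
            fit_frame.to_csv(out / "fits.csv", index=False)
            record("fit", ["fits.csv"], t0)

        if "recover" in stages:
            current = "recover"
            t0 = time.perf_counter()
            truth = pd.read_csv(out / "truth.csv")
            fit_frame = pd.read_csv(out / "fits.csv")
            report = _fitting.recovery_from_fits(
                truth, fit_frame, config.variant
            )
            report.table.to_csv(out / "recovery.csv", index=False)
            (out / "recovery.json").write_text(
                json.dumps(
                    {
                        "n_agents": report.n_agents,
                        **report.config_summary,
                        "parameters": report.table.to_dict("records"),
                    },
                    indent=2,
                )
            )
            record("recover", ["recovery.csv", "recovery.json"], t0)

        if "ppc" in stages:
            current = "ppc"
            t0 = time.perf_counter()
            datasets = _load_datasets(out, config)
            fit_frame = pd.read_csv(out / "fits.csv")
            rng = np.random.default_rng(stage_seeds["ppc"])
            frames = []
            for ds in datasets[: config.n_ppc_participants]:
                row = fit_frame.loc[
                    fit_frame["participant"] == ds.participant_id
                ].iloc[0]
                variant = _fitting.get_variant(config.variant)
                fit = _fitting.FitResult(
                    variant=variant,
                    values={n: float(row[n]) for n in variant.names},
                    log_posterior=float(row["log_posterior"]),
                    log_likelihood=float(row["log_likelihood"]),
                    n_restarts=config.n_restarts,
                    best_restart_index=-1,
                    converged_flags=np.array([]),
                    participant_id=ds.participant_id,
                )
                frame = _fitting.posterior_predictive(
                    fit, ds, config.n_ppc_sims, rng
                )
                frame.insert(0, "participant", ds.participant_id)
                frames.append(frame)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "ppc.csv", index=False
            )
            record("ppc", ["ppc.csv"], t0)

        if "analyze" in stages:
            current = "analyze"
            t0 = time.perf_counter()
            rng = np.random.default_rng(stage_seeds["analyze"])
            fit_frame = pd.read_csv(out / "fits.csv")
            files = []

            omega_table = _analysis.omega_long_table(fit_frame)
            spec = _regression.RegressionSpec(
                outcome="omega",
                predictors=("age", "stakes", "transition", "age_x_stakes",
                            "age_x_transition"),
                chains=config.regression_chains,
                iterations=config.regression_iterations,
                warmup=config.regression_warmup,
            )
            res = _regression.fit_hierarchical_lm(omega_table, spec, rng)
            _write_regression(res, out, "omega_regression")
            files += ["omega_regression.csv", "omega_regression.json"]

            datasets = _load_datasets(out, config)
            rt_table = _analysis.rt_preprocess(datasets)
            if len(rt_table):
                rt_spec = _regression.RegressionSpec(
                    outcome="log_rt2",
                    predictors=("old", "revaluation", "old_x_revaluation"),
                    random_slopes=("revaluation",),
                    chains=config.regression_chains,
                    iterations=config.regression_iterations,
                    warmup=config.regression_warmup,
                )
                res = _regression.fit_hierarchical_lm(rt_table, rt_spec, rng)
                _write_regression(res, out, "rt_regression")
                files += ["rt_regression.csv", "rt_regression.json"]

            mean_rewards = _analysis.participant_summaries(datasets)
            groups = sorted(mean_rewards["group"].unique())
            if len(groups) == 2:
                scores = {
                    g: dict(
                        zip(sub["participant"], sub["mean_bc_reward"])
                    )
                    for g, sub in mean_rewards.groupby("group")
                }
                matched = _analysis.performance_match(
                    scores[groups[0]], scores[groups[1]]
                )
                pd.DataFrame(
                    matched.pairs, columns=[groups[0], groups[1]]
                ).to_csv(out / "matched_pairs.csv", index=False)
                files.append("matched_pairs.csv")
            record("analyze", files, t0)
    except Exception as exc:
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise PipelineError(current or "unknown", manifest, exc) from exc
    return manifest


def _write_regression(res, out: Path, stem: str) -> None:
    res.table.to_csv(out / f"{stem}.csv", index=False)
    (out / f"{stem}.json").write_text(
        json.dumps(
            {
                "converged": res.converged,
                "iterations_used": res.iterations_used,
                "sigma_mean": res.sigma_mean,
                "tau_mean": res.tau_mean,
                "coefficients": res.table.to_dict("records"),
            },
            indent=2,
        )
    )


def _load_datasets(out: Path, config: RunConfig) -> list[ChoiceDataset]:
    sequences = read_sequence_csv(out / "sequences.csv", config.task)
    assignment = json.loads((out / "sequence_assignment.json").read_text())
    per_participant = {pid: sequences[sid] for pid, sid in assignment.items()}
    return read_choice_csv(out / "choices.csv", per_participant)
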