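"""Full in-silico study: simulate trials, compute metrics, run TE tests.

Mirrors the experimental design: three conditions (control, open-loop,
closed-loop) with 16 trials each, per-trial metric tables binned into
three 2-min windows, per-condition mean +- standard error summaries, and
transfer-entropy surrogate tests from the replica's state to the fish's
vertical and horizontal position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .arena import ArenaGeometry, FishBehaviorParams, RobotKinematicsParams, TrialRecord
from .metrics import compute_metric_table
from .simulate import run_trial
from .te import SurrogateTest, SymbolicSeries, bin_position, downsample, surrogate_test, symbolize_states

__all__ = ["StudyConfig", "StudyReport", "run_study", "summarize", "trial_te_series"]

logger = logging.getLogger("robopred")

_AXIS_TO_BINNING = {"vertical": "depth", "horizontal": "length"}

METRIC_COLUMNS = [
    "avg_distance_to_replica_cm",
    "pct_time_opposite_half",
    "avg_height_cm",
    "pct_time_bottom_third",
    "n_entries_bottom",
    "avg_speed_cm_s",
    "avg_accel_mag_cm_s2",
    "avg_turn_rate_rad_s",
    "pct_robot_lower_half",
    "pct_robot_attacking",
]


@dataclass
class StudyConfig:
    """Configuration of a simulated study (defaults mirror the experiment)."""

    n_trials_per_condition: int = 16
    seed: int = 0
    seeds: Optional[Dict[str, List[int]]] = None
    conditions: Tuple[str, ...] = ("control", "open_loop", "closed_loop")
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    kinematics: RobotKinematicsParams = field(default_factory=RobotKinematicsParams)
    fish_params: FishBehaviorParams = field(
        default_factory=lambda: FishBehaviorParams(horizontal_coupling=0.0)
    )
    habituation_s: int = 600
    observation_s: int = 360
    te_axes: Tuple[str, ...] = ("vertical", "horizontal")
    te_conditions: Tuple[str, ...] = ("open_loop", "closed_loop")
    n_perm: int = 1000

    def __post_init__(self):
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least two trials per condition")

    def trial_seeds(self, condition: str) -> List[int]:
        """Per-trial seeds; unique, reproducible from the master seed."""
        if self.seeds and condition in self.seeds:
            s = list(self.seeds[condition])
            if len(set(s)) != len(s):
                raise ValueError("per-trial seeds must be unique")
            return s
        ss = np.random.SeedSequence(
            [self.seed, self.conditions.index(condition)]
        )
        return [int(v) for v in ss.generate_state(self.n_trials_per_condition) % (2**31)]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "arena" in kwargs:
            kwargs["arena"] = ArenaGeometry(**kwargs["arena"])
        if "kinematics" in kwargs:
            kwargs["kinematics"] = RobotKinematicsParams(**kwargs["kinematics"])
        if "fish_params" in kwargs:
            kwargs["fish_params"] = FishBehaviorParams(**kwargs["fish_params"])
        for key in ("conditions", "te_axes", "te_conditions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class StudyReport:
    """Everything the study computes, ready for external statistics."""

    metrics: pd.DataFrame
    summary: pd.DataFrame
    te_tests: Dict[Tuple[str, str], SurrogateTest]
    trials: List[TrialRecord] = field(default_factory=list)

    def write(self, out_dir: Union[str, Path], write_trials: bool = True) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        te_json = {
            f"{cond}/{axis}": {
                "observed_mean_te_bits": t.observed_mean_te,
                "per_trial_te_bits": [float(v) for v in t.per_trial_te],
                "null_q05": t.q05,
                "null_q95": t.q95,
                "significant": t.significant,
                "n_perm": t.n_perm,
            }
            for (cond, axis), t in self.te_tests.items()
        }
        (out / "te.json").write_text(json.dumps(te_json, indent=1))
        if write_trials:
            for trial in self.trials:
                trial.write(out / "trials" / trial.trial_id)
        return out


def trial_te_series(
    trial: TrialRecord, axis: str
) -> Tuple[SymbolicSeries, SymbolicSeries]:
    """(fish, robot) 1 Hz symbolic series over the observation window.

    Fish position along the chosen axis is down-sampled from 30 Hz to 1 Hz
    and binned at one body length (3 cm); the robot series is the 1 Hz
    behavior stream itself.
    """
    if axis not in _AXIS_TO_BINNING:
        raise ValueError("axis must be 'vertical' or 'horizontal'")
    fish = trial.fish_observation()
    pos = fish.z if axis == "vertical" else fish.x
    pos_1hz = downsample(pos, rate_hz=fish.rate_hz, out_hz=1.0)
    fish_sym = bin_position(pos_1hz, _AXIS_TO_BINNING[axis], trial.arena)
    robot_sym = symbolize_states(trial.observation_states())
    return fish_sym, robot_sym


def condition_surrogate_test(
    trials: Sequence[TrialRecord],
    axis: str,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> SurrogateTest:
    """Surrogate TE test over the trials of one condition, one axis."""
    pairs = [trial_te_series(t, axis) for t in trials]
    fish_series = [p[0] for p in pairs]
    robot_series = [p[1] for p in pairs]
    return surrogate_test(fish_series, robot_series, n_perm=n_perm, rng=rng)


def summarize(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-bin mean and standard error of each measure.

    SEM = sd / sqrt(n) with n the number of trials; it is NaN (flagged
    undefined) when a cell holds a single trial.
    """
    grouped = metric_table.groupby(["condition", "time_bin"], sort=False)
    mean = grouped[METRIC_COLUMNS].mean()
    sem = grouped[METRIC_COLUMNS].sem()
    out = mean.join(sem, lsuffix="_mean", rsuffix="_sem").reset_index()
    out["n_trials"] = grouped.size().to_numpy()
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Simulate the full study described by ``config``; deterministic."""
    trials: List[TrialRecord] = []
    tables = []
    for condition in config.conditions:
        for seed in config.trial_seeds(condition):
            trial = run_trial(
                condition,
                seed=seed,
                arena=config.arena,
                kinematics=config.kinematics,
                fish_params=config.fish_params,
                habituation_s=config.habituation_s,
                observation_s=config.observation_s,
            )
            logger.info(
                "trial %s: condition=%s seed=%d attack_fraction=%.3f",
                trial.trial_id, condition, seed,
                trial.meta.get("attack_fraction_observation", float("nan")),
            )
            trials.append(trial)
            tables.append(compute_metric_table(trial))
    metrics = pd.concat(tables, ignore_index=True)
    summary = summarize(metrics)

    te_tests: Dict[Tuple[str, str], SurrogateTest] = {}
    for condition in config.te_conditions:
        cond_trials = [t for t in trials if t.condition == condition]
        if not cond_trials:
            continue
        for axis in config.te_axes:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed, 7919, config.conditions.index(condition),
                     config.te_axes.index(axis)]
                )
            )
            te_tests[(condition, axis)] = condition_surrogate_test(
                cond_trials, axis, n_perm=config.n_perm, rng=rng
            )
    return StudyReport(metrics=metrics, summary=summary, te_tests=te_tests, trials=trials)
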