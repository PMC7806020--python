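"""Arena geometry, simulation parameters, and the trial record container.

Coordinate convention: origin at the bottom corner of the central tank on
the replica side; x runs along the tank length (x = 0 at the replica-side
wall, increasing away from the replica), y along the width, z upward from
the base.  All lengths in cm, time in seconds.  The replica's lateral tank
occupies x in [-lateral_length, 0].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .states import BehaviorState

__all__ = [
    "ArenaGeometry",
    "RobotKinematicsParams",
    "FishBehaviorParams",
    "Trajectory",
    "TrialRecord",
]

FRAME_RATE_HZ = 30


@dataclass(frozen=True)
class ArenaGeometry:
    """Binary-choice tank geometry: central arena flanked by a lateral tank.

    Defaults reproduce a 42 x 30 cm central tank with a 16 cm lateral tank
    and 15 cm of water (so the bottom third of the water column is 5 cm).
    """

    central_length_cm: float = 42.0
    central_width_cm: float = 30.0
    water_depth_cm: float = 15.0
    lateral_length_cm: float = 16.0
    replica_side: str = "left"

    def __post_init__(self):
        for name in ("central_length_cm", "central_width_cm", "water_depth_cm",
                     "lateral_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.replica_side not in ("left", "right"):
            raise ValueError("replica_side must be 'left' or 'right'")

    @property
    def lateral_center(self) -> Tuple[float, float, float]:
        """Geometric center of the water volume in the lateral tank."""
        return (
            -self.lateral_length_cm / 2.0,
            self.central_width_cm / 2.0,
            self.water_depth_cm / 2.0,
        )


@dataclass(frozen=True)
class RobotKinematicsParams:
    """Replica movement parameters for the three locomotory states.

    Swimming follows an elliptical horizontal orbit (axis lengths 2.35 cm
    along x and 10 cm along y) at nominal axis speeds 1.01 / 1.33 cm/s; each
    swim second the y-speed jitters by +-0.1 cm/s with probability 0.1 and
    the replica steps +-1 cm vertically with probability 0.2.  Stationary
    descends to the bottom and freezes; attacking sweeps back and forth
    along the wall adjacent to the central tank.
    """

    ellipse_axis_minor_cm: float = 2.35
    ellipse_axis_major_cm: float = 10.0
    speed_x_cm_s: float = 1.01
    speed_y_cm_s: float = 1.33
    speed_jitter_cm_s: float = 0.1
    speed_jitter_prob: float = 0.1
    vertical_step_cm: float = 1.0
    vertical_step_prob: float = 0.2
    attack_speed_cm_s: float = 3.0
    descent_speed_cm_s: float = 3.0
    attack_wall_offset_cm: float = 1.0
    frame_rate_hz: int = FRAME_RATE_HZ

    def __post_init__(self):
        for name in ("speed_jitter_prob", "vertical_step_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("speed_x_cm_s", "speed_y_cm_s", "attack_speed_cm_s",
                     "descent_speed_cm_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FishBehaviorParams:
    """Stochastic fish model: a bounded 3D correlated random walk.

    The horizontal heading diffuses with per-frame sd ``turning_noise_rad``;
    speed fluctuates about ``mean_speed_cm_s``; the vertical velocity is a
    noisy drift (negative baseline = bottom preference).  When
    ``attack_avoidance_gain`` (g) > 0 and the replica is attacking, the fish
    receives an escape drift of magnitude g * mean_speed: vertically away
    from the replica's half of the water column (weight
    ``vertical_coupling``) and longitudinally away from the replica-side
    third (weight ``horizontal_coupling``).  With g = 0 the trajectory law
    is independent of the replica's states.  ``habituation_bias`` is an
    extra downward drift (cm/s) applied during habituation only, emulating
    the initial bottom preference of fish in a novel tank.
    """

    mean_speed_cm_s: float = 7.0
    speed_sd: float = 2.0
    turning_noise_rad: float = 0.3
    vertical_speed_sd: float = 2.0
    vertical_drift_baseline: float = -0.3
    attack_avoidance_gain: float = 0.5
    vertical_coupling: float = 1.0
    horizontal_coupling: float = 1.0
    habituation_bias: float = 0.5

    def __post_init__(self):
        if self.mean_speed_cm_s <= 0:
            raise ValueError("mean_speed_cm_s must be positive")
        if self.attack_avoidance_gain < 0:
            raise ValueError("attack_avoidance_gain must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 3D position series (cm) for one agent."""

    t_s: np.ndarray
    xyz: np.ndarray
    rate_hz: float = FRAME_RATE_HZ

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if t.shape[0] != xyz.shape[0]:
            raise ValueError("time stamps and positions must align")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "xyz", xyz)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory with t0 <= t < t1."""
        mask = (self.t_s >= t0) & (self.t_s < t1)
        return Trajectory(self.t_s[mask], self.xyz[mask], self.rate_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t_s, "x_cm": self.x, "y_cm": self.y, "z_cm": self.z}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rate_hz: float = FRAME_RATE_HZ):
        return cls(
            t_s=frame["t_s"].to_numpy(),
            xyz=frame[["x_cm", "y_cm", "z_cm"]].to_numpy(),
            rate_hz=rate_hz,
        )


CONDITIONS = ("control", "open_loop", "closed_loop")


@dataclass
class TrialRecord:
    """One simulated trial: condition, trajectories, robot states, geometry.

    ``robot_states`` is the 1 Hz behavior stream covering the full trial
    (habituation + observation); in the control condition it is a constant
    placeholder.  Trajectories are sampled at 30 Hz.
    """

    condition: str
    arena: ArenaGeometry
    fish_traj: Trajectory
    robot_traj: Trajectory
    robot_states: Tuple[BehaviorState, ...]
    habituation_s: int = 600
    observation_s: int = 360
    seed: Optional[int] = None
    trial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        total = self.habituation_s + self.observation_s
        if len(self.robot_states) != total:
            raise ValueError(
                f"robot_states has {len(self.robot_states)} entries; "
                f"expected one per second of the {total}-s trial"
            )
        if not self.trial_id:
            self.trial_id = f"{self.condition}_seed{self.seed}"

    @property
    def duration_s(self) -> int:
        return self.habituation_s + self.observation_s

    def observation_window(self) -> Tuple[float, float]:
        return float(self.habituation_s), float(self.duration_s)

    def fish_observation(self) -> Trajectory:
        return self.fish_traj.window(*self.observation_window())

    def robot_observation(self) -> Trajectory:
        return self.robot_traj.window(*self.observation_window())

    def observation_states(self) -> Tuple[BehaviorState, ...]:
        return self.robot_states[self.habituation_s:]

    # -- serialization: a directory of plain-text tables plus JSON metadata --

    def write(self, out_dir: Union[str, Path]) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fish_traj.to_frame().to_csv(out / "fish.csv", index=False)
        self.robot_traj.to_frame().to_csv(out / "robot.csv", index=False)
        pd.DataFrame(
            {
                "t_s": np.arange(len(self.robot_states)),
                "state": [s.value for s in self.robot_states],
            }
        ).to_csv(out / "states.csv", index=False)
        meta = {
            "condition": self.condition,
            "arena": asdict(self.arena),
            "habituation_s": self.habituation_s,
            "observation_s": self.observation_s,
            "seed": self.seed,
            "trial_id": self.trial_id,
            **self.meta,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=1))
        return out

    @classmethod
    def read(cls, trial_dir: Union[str, Path]) -> "TrialRecord":
        d = Path(trial_dir)
        meta = json.loads((d / "meta.json").read_text())
        arena = ArenaGeometry(**meta.pop("arena"))
        states = tuple(
            BehaviorState(s) for s in pd.read_csv(d / "states.csv")["state"]
        )
        known = {"condition", "habituation_s", "observation_s", "seed", "trial_id"}
        # round_trip parsing keeps positions bit-identical across serialization
        read = lambda p: pd.read_csv(p, float_precision="round_trip")
        return cls(
            condition=meta["condition"],
            arena=arena,
            fish_traj=Trajectory.from_frame(read(d / "fish.csv")),
            robot_traj=Trajectory.from_frame(read(d / "robot.csv")),
            robot_states=states,
            habituation_s=meta["habituation_s"],
            observation_s=meta["observation_s"],
            seed=meta["seed"],
            trial_id=meta["trial_id"],
            meta={k: v for k, v in meta.items() if k not in known},
        )
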