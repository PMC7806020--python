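"""Virtual arena: replica kinematics, stochastic fish model, trial runner.

The simulator replaces the physical platform (robotic arm + replica), the
cameras, and the live fish.  It produces 30 Hz ground-truth trajectories
for both agents and the 1 Hz behavior-state stream of the replica, under
three conditions:

* ``control`` -- no replica; the robot stream is a constant placeholder and
  the fish is uncoupled.
* ``open_loop`` -- the replica follows a pre-generated schedule sampled from
  the three-state behavior chain, independent of the fish.
* ``closed_loop`` -- at every 1 Hz tick the fish's proximity is measured and
  the replica's next behavior is drawn from the joint six-state chain.

The fish is a bounded correlated random walk in 3D with an optional,
tunable escape response to the replica's attacks (active only during the
observation window, when the curtain separating the tanks is removed).
"""

from __future__ import annotations

import math
from dataclasses import asdict
from typing import Optional, Sequence, Tuple

import numpy as np

from .arena import (
    FRAME_RATE_HZ,
    ArenaGeometry,
    FishBehaviorParams,
    RobotKinematicsParams,
    Trajectory,
    TrialRecord,
)
from .markov import (
    CLOSED_LOOP_MATRIX,
    OPEN_LOOP_MATRIX,
    TransitionMatrix,
    classify_proximity,
    sample_next_state,
)
from .states import JOINT_LABELS, BehaviorState, ProximityState, joint_label, parse_behavior

__all__ = [
    "generate_open_loop_schedule",
    "step_closed_loop",
    "simulate_robot_motion",
    "simulate_fish",
    "run_trial",
]

_DT = 1.0 / FRAME_RATE_HZ


def generate_open_loop_schedule(
    M_OL: TransitionMatrix, duration_s: int, rng: np.random.Generator
) -> Tuple[BehaviorState, ...]:
    """Sample a 1 Hz behavior schedule of ``duration_s`` events.

    The schedule begins in the stationary state; each subsequent event is
    drawn from the behavior chain (a 20-min schedule has 1,200 events).
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    if M_OL.n_states != 3:
        raise ValueError("open-loop schedule requires the 3-state behavior chain")
    states = [BehaviorState.ST]
    current = BehaviorState.ST.value
    for _ in range(duration_s - 1):
        current = sample_next_state(M_OL, current, rng)
        states.append(parse_behavior(current))
    return tuple(states)


def step_closed_loop(
    M_CL: TransitionMatrix,
    current_behavior: BehaviorState,
    proximity: ProximityState,
    rng: np.random.Generator,
) -> BehaviorState:
    """One closed-loop tick: next behavior given current behavior + proximity.

    The joint state (behavior, proximity) selects a row of the six-state
    matrix; the sampled next joint state's behavior component is returned
    (the proximity component is overridden by the next live measurement).
    """
    if M_CL.n_states != 6:
        raise ValueError("closed-loop stepping requires the 6-state joint chain")
    nxt = sample_next_state(M_CL, joint_label(current_behavior, proximity), rng)
    b, _ = nxt.split("-")
    return parse_behavior(b)


def _fold(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect (billiard-fold) coordinates into [lo, hi]."""
    span = hi - lo
    q = np.mod(np.asarray(p) - lo, 2.0 * span)
    return lo + span - np.abs(q - span)


class _RobotSim:
    """Stateful replica kinematics, advanced one 1 Hz tick at a time.

    The replica lives in the lateral tank (x in [-lateral_length, 0]).
    Stationary: descend to the bottom, then freeze.  Swimming: track an
    elliptical horizontal orbit about the lateral-tank center (minor axis
    along x, major along y) with per-second stochastic speed and vertical
    perturbations.  Attacking: constant-speed back-and-forth sweep along
    the wall adjacent to the central tank.  Behavior changes take effect at
    the tick; an in-progress attack sweep is truncated.
    """

    def __init__(self, params: RobotKinematicsParams, arena: ArenaGeometry):
        self.p = params
        self.arena = arena
        self.cx = -arena.lateral_length_cm / 2.0
        self.cy = arena.central_width_cm / 2.0
        self.ax = params.ellipse_axis_minor_cm / 2.0  # semi-axis along x
        self.ay = params.ellipse_axis_major_cm / 2.0  # semi-axis along y
        self.phase = 0.0
        self.speed_y = params.speed_y_cm_s
        self.sweep_dir = 1.0
        self.y_margin = 2.0
        # start on the swim orbit at mid-depth
        self.pos = np.array([self.cx + self.ax, self.cy, arena.water_depth_cm / 2.0])

    def _omega(self) -> float:
        # phase rate blending the nominal axis speeds (peak-speed convention)
        return 0.5 * (self.p.speed_x_cm_s / self.ax + self.speed_y / self.ay)

    def step_second(self, state: BehaviorState, rng: np.random.Generator) -> np.ndarray:
        """Advance one second; return the 30 frame positions."""
        out = np.empty((FRAME_RATE_HZ, 3))
        x, y, z = self.pos
        if state is BehaviorState.ST:
            dz = self.p.descent_speed_cm_s * _DT
            for i in range(FRAME_RATE_HZ):
                z = max(0.0, z - dz)
                out[i] = (x, y, z)
        elif state is BehaviorState.SW:
            if rng.random() < self.p.speed_jitter_prob:
                self.speed_y = max(
                    0.1,
                    self.speed_y
                    + self.p.speed_jitter_cm_s * (1.0 if rng.random() < 0.5 else -1.0),
                )
            vz = 0.0
            if rng.random() < self.p.vertical_step_prob:
                step = self.p.vertical_step_cm * (1.0 if rng.random() < 0.5 else -1.0)
                # reflect the step at the water surface / tank base
                if z + step > self.arena.water_depth_cm or z + step < 0.0:
                    step = -step
                vz = step * _DT  # spread the 1 cm move over the second
            omega = self._omega()
            cap = 0.2  # cm per frame approach cap toward the orbit point
            for i in range(FRAME_RATE_HZ):
                self.phase += omega * _DT
                tx = self.cx + self.ax * math.cos(self.phase)
                ty = self.cy + self.ay * math.sin(self.phase)
                dx, dy = tx - x, ty - y
                dist = math.hypot(dx, dy)
                if dist > cap:
                    x += dx / dist * cap
                    y += dy / dist * cap
                else:
                    x, y = tx, ty
                z = min(self.arena.water_depth_cm, max(0.0, z + vz))
                out[i] = (x, y, z)
        else:  # attacking: thrash along the wall next to the central tank
            wall_x = -self.p.attack_wall_offset_cm
            ymin, ymax = self.y_margin, self.arena.central_width_cm - self.y_margin
            step = self.p.attack_speed_cm_s * _DT
            for i in range(FRAME_RATE_HZ):
                if abs(x - wall_x) > step:
                    x += step if wall_x > x else -step
                else:
                    x = wall_x
                    y += self.sweep_dir * step
                    if y >= ymax:
                        y, self.sweep_dir = ymax, -1.0
                    elif y <= ymin:
                        y, self.sweep_dir = ymin, 1.0
                out[i] = (x, y, z)
        self.pos = out[-1].copy()
        return out


class _FishSim:
    """Bounded 3D correlated random walk, advanced one second at a time."""

    def __init__(
        self,
        params: FishBehaviorParams,
        arena: ArenaGeometry,
        rng: np.random.Generator,
    ):
        self.p = params
        self.arena = arena
        L, W, D = arena.central_length_cm, arena.central_width_cm, arena.water_depth_cm
        self.pos = np.array(
            [
                rng.uniform(0.1 * L, 0.9 * L),
                rng.uniform(0.1 * W, 0.9 * W),
                rng.uniform(0.2 * D, 0.8 * D),
            ]
        )
        self.heading = rng.uniform(-math.pi, math.pi)

    def step_second(
        self,
        robot_state: BehaviorState,
        robot_z: float,
        rng: np.random.Generator,
        couple: bool,
        habituating: bool,
    ) -> np.ndarray:
        """Advance one second (30 frames); return the frame positions."""
        p, arena = self.p, self.arena
        n = FRAME_RATE_HZ
        dtheta = rng.normal(0.0, p.turning_noise_rad, n)
        speed = np.clip(rng.normal(p.mean_speed_cm_s, p.speed_sd, n), 0.0, None)
        # vertical velocity is bout-like: one draw held for the whole second,
        # so the fish makes cm-scale vertical excursions rather than jitter
        vz_noise = rng.normal(0.0, p.vertical_speed_sd)

        esc_vx = esc_vz = 0.0
        if couple and p.attack_avoidance_gain > 0 and robot_state is BehaviorState.A:
            mag = p.attack_avoidance_gain * p.mean_speed_cm_s
            away = 1.0 if robot_z <= arena.water_depth_cm / 2.0 else -1.0
            esc_vz = p.vertical_coupling * mag * away
            esc_vx = p.horizontal_coupling * mag  # away from the replica wall
        drift_z = p.vertical_drift_baseline + esc_vz
        if habituating:
            drift_z -= p.habituation_bias

        theta = self.heading + np.cumsum(dtheta)
        vx = speed * np.cos(theta) + esc_vx
        vy = speed * np.sin(theta)
        vz = drift_z + vz_noise
        x = _fold(self.pos[0] + np.cumsum(vx) * _DT, 0.0, arena.central_length_cm)
        y = _fold(self.pos[1] + np.cumsum(vy) * _DT, 0.0, arena.central_width_cm)
        z = _fold(
            self.pos[2] + vz * _DT * np.arange(1, n + 1), 0.0, arena.water_depth_cm
        )
        out = np.column_stack([x, y, z])
        self.pos = out[-1].copy()
        self.heading = float(theta[-1])
        return out


def simulate_robot_motion(
    states: Sequence[BehaviorState],
    params: Optional[RobotKinematicsParams] = None,
    arena: Optional[ArenaGeometry] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Render a 1 Hz behavior-state sequence into a 30 Hz replica trajectory."""
    params = params or RobotKinematicsParams()
    arena = arena or ArenaGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    sim = _RobotSim(params, arena)
    frames = [sim.step_second(s, rng) for s in states]
    xyz = np.concatenate(frames)
    t = np.arange(xyz.shape[0]) * _DT
    return Trajectory(t_s=t, xyz=xyz)


def simulate_fish(
    params: Optional[FishBehaviorParams] = None,
    robot_states: Sequence[BehaviorState] = (),
    arena: Optional[ArenaGeometry] = None,
    rng: Optional[np.random.Generator] = None,
    robot_z: Optional[Sequence[float]] = None,
    habituation_s: int = 0,
) -> Trajectory:
    """Simulate the fish alone against a known 1 Hz robot-state sequence.

    ``robot_z`` gives the replica's depth at each second (used only to
    orient the vertical escape during attacks); when omitted the replica is
    assumed at the bottom, so the escape drift points upward.  Coupling is
    disabled for the first ``habituation_s`` seconds (curtain in place).
    """
    params = params or FishBehaviorParams()
    arena = arena or ArenaGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    states = list(robot_states)
    if robot_z is None:
        robot_z = np.zeros(len(states))
    sim = _FishSim(params, arena, rng)
    frames = [
        sim.step_second(
            s, float(robot_z[t]), rng, couple=t >= habituation_s,
            habituating=t < habituation_s,
        )
        for t, s in enumerate(states)
    ]
    xyz = np.concatenate(frames) if frames else np.empty((0, 3))
    t = np.arange(xyz.shape[0]) * _DT
    return Trajectory(t_s=t, xyz=xyz)


def run_trial(
    condition: str,
    seed: int,
    arena: Optional[ArenaGeometry] = None,
    kinematics: Optional[RobotKinematicsParams] = None,
    fish_params: Optional[FishBehaviorParams] = None,
    m_cl: Optional[TransitionMatrix] = None,
    m_ol: Optional[TransitionMatrix] = None,
    habituation_s: int = 600,
    observation_s: int = 360,
) -> TrialRecord:
    """Run one full trial (default 16 min: 10 min habituation + 6 min test).

    Closed loop: at every 1 Hz tick the fish's proximity is classified from
    the current positions and the replica's next behavior is drawn from the
    joint chain.  Open loop: the replica follows a schedule sampled from
    the behavior chain.  Control: the replica is absent (constant
    placeholder stream; trajectory pinned at the lateral-tank center) and
    the fish is forced uncoupled.  The same seed reproduces the trial
    byte-for-byte.
    """
    arena = arena or ArenaGeometry()
    kinematics = kinematics or RobotKinematicsParams()
    fish_params = fish_params or FishBehaviorParams()
    total = habituation_s + observation_s
    rng = np.random.default_rng(seed)

    if condition == "control":
        fish_params = FishBehaviorParams(
            **{
                **{f: getattr(fish_params, f) for f in fish_params.__dataclass_fields__},
                "attack_avoidance_gain": 0.0,
            }
        )
        states = tuple([BehaviorState.ST] * total)
        center = np.array(arena.lateral_center)
        xyz = np.tile(center, (total * FRAME_RATE_HZ, 1))
        robot_traj = Trajectory(t_s=np.arange(total * FRAME_RATE_HZ) * _DT, xyz=xyz)
        fish_traj = simulate_fish(
            fish_params, states, arena, rng,
            robot_z=np.full(total, center[2]), habituation_s=habituation_s,
        )
        states_out = states
    elif condition == "open_loop":
        m = m_ol or OPEN_LOOP_MATRIX
        if m.n_states != 3:
            raise ValueError("open_loop requires a 3-state behavior matrix")
        states_out = generate_open_loop_schedule(m, total, rng)
        robot_sim = _RobotSim(kinematics, arena)
        fish_sim = _FishSim(fish_params, arena, rng)
        robot_frames, fish_frames = [], []
        for t, s in enumerate(states_out):
            rframes = robot_sim.step_second(s, rng)
            robot_frames.append(rframes)
            fish_frames.append(
                fish_sim.step_second(
                    s, float(rframes[0, 2]), rng,
                    couple=t >= habituation_s, habituating=t < habituation_s,
                )
            )
        robot_traj = _frames_to_traj(robot_frames)
        fish_traj = _frames_to_traj(fish_frames)
    elif condition == "closed_loop":
        m = m_cl or CLOSED_LOOP_MATRIX
        if tuple(m.states) != JOINT_LABELS:
            raise ValueError("closed_loop requires the 6-state joint matrix")
        robot_sim = _RobotSim(kinematics, arena)
        fish_sim = _FishSim(fish_params, arena, rng)
        behavior = BehaviorState.ST
        states_list = [behavior]
        robot_frames, fish_frames = [], []
        for t in range(total):
            if t > 0:
                prox = classify_proximity(fish_sim.pos, robot_sim.pos[2], arena)
                behavior = step_closed_loop(m, behavior, prox, rng)
                states_list.append(behavior)
            rframes = robot_sim.step_second(behavior, rng)
            robot_frames.append(rframes)
            fish_frames.append(
                fish_sim.step_second(
                    behavior, float(rframes[0, 2]), rng,
                    couple=t >= habituation_s, habituating=t < habituation_s,
                )
            )
        states_out = tuple(states_list)
        robot_traj = _frames_to_traj(robot_frames)
        fish_traj = _frames_to_traj(fish_frames)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    obs_states = states_out[habituation_s:]
    attack_fraction = sum(s is BehaviorState.A for s in obs_states) / max(
        1, len(obs_states)
    )
    return TrialRecord(
        condition=condition,
        arena=arena,
        fish_traj=fish_traj,
        robot_traj=robot_traj,
        robot_states=states_out,
        habituation_s=habituation_s,
        observation_s=observation_s,
        seed=seed,
        meta={
            "attack_fraction_observation": attack_fraction,
            "kinematics": asdict(kinematics),
            "fish_params": asdict(fish_params),
        },
    )


def _frames_to_traj(frames) -> Trajectory:
    xyz = np.concatenate(frames)
    return Trajectory(t_s=np.arange(xyz.shape[0]) * _DT, xyz=xyz)
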