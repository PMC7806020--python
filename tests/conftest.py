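import numpy as np
import pytest

from robopred.arena import ArenaGeometry, FishBehaviorParams, Trajectory, TrialRecord
from robopred.states import BehaviorState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def arena():
    return ArenaGeometry()


def make_trial(
    fish_xyz,
    robot_xyz=None,
    condition="closed_loop",
    observation_s=360,
    states=None,
    arena=None,
):
    """Assemble a TrialRecord from raw 30 Hz positions (no habituation)."""
    arena = arena or ArenaGeometry()
    fish_xyz = np.asarray(fish_xyz, dtype=float)
    n = fish_xyz.shape[0]
    t = np.arange(n) / 30.0
    if robot_xyz is None:
        robot_xyz = np.tile(np.array(arena.lateral_center), (n, 1))
    if states is None:
        states = tuple([BehaviorState.SW] * observation_s)
    return TrialRecord(
        condition=condition,
        arena=arena,
        fish_traj=Trajectory(t, fish_xyz),
        robot_traj=Trajectory(t, np.asarray(robot_xyz, dtype=float)),
        robot_states=tuple(states),
        habituation_s=0,
        observation_s=observation_s,
        seed=0,
    )


@pytest.fixture
def quiet_fish_params():
    return FishBehaviorParams(attack_avoidance_gain=0.0)
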