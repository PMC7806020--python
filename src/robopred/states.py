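"""Finite state spaces for the predator-replica controller.

The replica switches among three locomotory behaviors scored from live
predator ethograms -- stationary (St), swimming (Sw), attacking (A) -- and
the prey's position relative to the replica is discretized as close (C) or
far (F).  The joint behavior x proximity space has six states with a fixed
indexing order used for all transition matrices.
"""

from __future__ import annotations

import enum
from typing import Tuple


class BehaviorState(str, enum.Enum):
    """Replica locomotory behavior.  Ordered (St, Sw, A) for matrix indexing."""

    ST = "St"
    SW = "Sw"
    A = "A"

    @property
    def index(self) -> int:
        return BEHAVIOR_STATES.index(self)


class ProximityState(str, enum.Enum):
    """Fish position relative to the replica: close or far."""

    C = "C"
    F = "F"

    @property
    def index(self) -> int:
        return PROXIMITY_STATES.index(self)


BEHAVIOR_STATES: Tuple[BehaviorState, ...] = (
    BehaviorState.ST,
    BehaviorState.SW,
    BehaviorState.A,
)
PROXIMITY_STATES: Tuple[ProximityState, ...] = (ProximityState.C, ProximityState.F)

#: Fixed joint-state order: St-C, St-F, Sw-C, Sw-F, A-C, A-F.
JOINT_STATES: Tuple[Tuple[BehaviorState, ProximityState], ...] = tuple(
    (b, p) for b in BEHAVIOR_STATES for p in PROXIMITY_STATES
)

BEHAVIOR_LABELS: Tuple[str, ...] = tuple(b.value for b in BEHAVIOR_STATES)
JOINT_LABELS: Tuple[str, ...] = tuple(f"{b.value}-{p.value}" for b, p in JOINT_STATES)


def joint_index(behavior: BehaviorState, proximity: ProximityState) -> int:
    """Index of a (behavior, proximity) pair in the fixed six-state order."""
    return 2 * behavior.index + proximity.index


def joint_label(behavior: BehaviorState, proximity: ProximityState) -> str:
    return f"{behavior.value}-{proximity.value}"


def parse_behavior(label: str) -> BehaviorState:
    try:
        return BehaviorState(label)
    except ValueError:
        raise ValueError(f"unknown behavior state label: {label!r}") from None


def parse_joint(label: str) -> Tuple[BehaviorState, ProximityState]:
    """Parse a 'St-C'-style label into a (behavior, proximity) pair."""
    try:
        b, p = label.split("-")
        return BehaviorState(b), ProximityState(p)
    except ValueError:
        raise ValueError(f"unknown joint state label: {label!r}") from None
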