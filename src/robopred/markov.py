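"""Finite-state Markov-chain behavior policy for the robotic predator.

The controller is a discrete-time Markov chain on a 1 Hz clock.  In
closed-loop operation the chain lives on the six joint states
(behavior x prey proximity); the replica's next behavior is drawn from the
row of the joint transition matrix selected by its current behavior and the
live-measured proximity of the fish.  In open-loop operation the proximity
coordinate is marginalized out against the stationary distribution, leaving
a three-state behavior chain that evolves independently of the fish.

This module provides calibration from scored state sequences, stationary
analysis, the open-loop marginalization, state sampling, and the proximity
classifier used by the closed-loop feedback law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .states import (
    BEHAVIOR_LABELS,
    BEHAVIOR_STATES,
    JOINT_LABELS,
    JOINT_STATES,
    BehaviorState,
    ProximityState,
    joint_index,
)

__all__ = [
    "TransitionMatrix",
    "StationaryDistribution",
    "CLOSED_LOOP_MATRIX",
    "OPEN_LOOP_MATRIX",
    "select_max_attack_window",
    "build_transition_matrix",
    "stationary_distribution",
    "behavior_given_proximity",
    "marginalize_to_open_loop",
    "sample_next_state",
    "classify_proximity",
    "read_scored_sequence",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix over a named finite state space.

    Rows index the current state, columns the next state.  Every row must
    sum to 1 within 1e-9 and all entries must lie in [0, 1].
    """

    states: Tuple[str, ...]
    P: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "states", tuple(self.states))
        n = len(self.states)
        if P.shape != (n, n):
            raise ValueError(f"matrix shape {P.shape} does not match {n} states")
        if np.any(P < -_ROW_TOL) or np.any(P > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0):
            raise ValueError("every row of a transition matrix must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: Union[str, BehaviorState]) -> int:
        label = state.value if isinstance(state, BehaviorState) else str(state)
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"state {label!r} not in {self.states}") from None

    def row(self, state) -> np.ndarray:
        return self.P[self.index(state)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.states), columns=list(self.states))

    def write(self, path: Union[str, Path]) -> None:
        """Write as a labelled delimited table plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path)
        meta = {"states": list(self.states), **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "TransitionMatrix":
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        meta.pop("states", None)
        return cls(states=tuple(frame.index), P=frame.to_numpy(), meta=meta)


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run state-occupancy probabilities of an ergodic chain."""

    states: Tuple[str, ...]
    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "states", tuple(self.states))
        if pi.shape != (len(self.states),):
            raise ValueError("pi length must match number of states")
        if np.any(pi < -_ROW_TOL):
            raise ValueError("stationary probabilities must be nonnegative")
        if abs(pi.sum() - 1.0) > _ROW_TOL:
            raise ValueError("stationary probabilities must sum to 1")

    def __getitem__(self, state) -> float:
        label = state.value if isinstance(state, BehaviorState) else str(state)
        return float(self.pi[self.states.index(label)])


# Joint six-state transition matrix calibrated from scored videos of a live
# red tiger Oscar predator interacting with zebrafish (1 Hz scoring; the
# calibration segment is the 1-min window with the largest attack fraction).
# State order: St-C, St-F, Sw-C, Sw-F, A-C, A-F.
CLOSED_LOOP_MATRIX = TransitionMatrix(
    states=JOINT_LABELS,
    P=np.array(
        [
            [0.806, 0.194, 0.000, 0.000, 0.000, 0.000],
            [0.075, 0.891, 0.007, 0.027, 0.000, 0.000],
            [0.011, 0.023, 0.794, 0.138, 0.034, 0.000],
            [0.000, 0.016, 0.060, 0.891, 0.000, 0.033],
            [0.000, 0.000, 0.042, 0.000, 0.750, 0.208],
            [0.000, 0.000, 0.043, 0.043, 0.203, 0.711],
        ]
    ),
    meta={"calibration": "live-predator scored videos, max-attack 1-min window"},
)

# Three-state behavior chain obtained by marginalizing the joint chain over
# proximity against its stationary distribution (values as used on the
# physical platform, rounded to three decimals).
OPEN_LOOP_MATRIX = TransitionMatrix(
    states=BEHAVIOR_LABELS,
    P=np.array(
        [
            [0.976, 0.024, 0.000],
            [0.022, 0.945, 0.033],
            [0.000, 0.064, 0.936],
        ]
    ),
    meta={"calibration": "proximity-marginalized joint chain"},
)


def select_max_attack_window(
    attack_fractions: Sequence[float], window_s: int
) -> Tuple[int, float]:
    """Find the contiguous window with the largest total attack fraction.

    ``attack_fractions`` is a per-second series of values in [0, 1] (the
    fraction of scored videos reporting an attack at that second).  Returns
    ``(start_index, total_fraction)`` of the length-``window_s`` window that
    maximizes the sum; ties are broken by the earliest start.
    """
    x = np.asarray(attack_fractions, dtype=float)
    if window_s < 1:
        raise ValueError("window_s must be >= 1")
    if x.ndim != 1 or x.size < window_s:
        raise ValueError(
            f"series of length {x.size} is shorter than window {window_s}"
        )
    # sum each window independently (not via cumsum differences) so exact
    # ties between identical windows stay exact and the earliest start wins
    windows = np.lib.stride_tricks.sliding_window_view(x, window_s)
    totals = windows.sum(axis=1)
    start = int(np.argmax(totals))  # argmax returns the first maximizer
    return start, float(totals[start])


def build_transition_matrix(
    seq: Sequence[Union[str, Tuple[BehaviorState, ProximityState]]],
    states: Optional[Sequence[str]] = None,
    dt_s: float = 1.0,
) -> TransitionMatrix:
    """Calibrate a transition matrix from a 1 Hz scored state sequence.

    Entry (i, j) is the number of observed i->j transitions divided by the
    number of departures from i.  States never departed from get an identity
    row (absorbing); their labels are recorded in ``meta['absorbing_rows']``.
    """
    labels = [
        s if isinstance(s, str) else f"{s[0].value}-{s[1].value}" for s in seq
    ]
    if len(labels) < 2:
        raise ValueError("need at least two samples to count transitions")
    if states is None:
        states = JOINT_LABELS if set(labels) <= set(JOINT_LABELS) else sorted(set(labels))
    states = tuple(states)
    index = {s: i for i, s in enumerate(states)}
    unknown = set(labels) - set(states)
    if unknown:
        raise ValueError(f"sequence contains labels outside the state space: {unknown}")
    n = len(states)
    counts = np.zeros((n, n))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[index[a], index[b]] += 1
    departures = counts.sum(axis=1)
    P = np.eye(n)
    observed = departures > 0
    P[observed] = counts[observed] / departures[observed, None]
    absorbing = [states[i] for i in np.flatnonzero(~observed)]
    return TransitionMatrix(
        states=states,
        P=P,
        meta={"n_transitions": int(departures.sum()), "dt_s": dt_s,
              "absorbing_rows": absorbing},
    )


def stationary_distribution(M: TransitionMatrix) -> StationaryDistribution:
    """Stationary distribution pi with pi.P = pi, via the linear system.

    Solves pi(P - I) = 0 with the normalization sum(pi) = 1 appended, which
    yields a real nonnegative solution directly (the left eigenvector with
    unit eigenvalue).  Raises if the chain does not have a unique stationary
    distribution (rank of P^T - I below n-1, i.e. multiple closed classes).
    """
    P = M.P
    n = M.n_states
    A = P.T - np.eye(n)
    if np.linalg.matrix_rank(A) < n - 1:
        raise ValueError(
            "chain has no unique stationary distribution (reducible with "
            "multiple closed communicating classes)"
        )
    B = np.vstack([A, np.ones(n)])
    rhs = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(B, rhs, rcond=None)
    residual = np.abs(pi @ P - pi).max()
    if residual > 1e-9 or np.any(pi < -1e-9):
        raise ValueError(f"stationary solve failed (residual {residual:.2e})")
    pi = np.clip(pi, 0.0, None)
    return StationaryDistribution(states=M.states, pi=pi / pi.sum())


def behavior_given_proximity(
    pi: StationaryDistribution,
) -> Tuple[np.ndarray, np.ndarray]:
    """Conditional behavior distributions given proximity, from a joint pi.

    Returns ``(close, far)``: each a 3-vector over (St, Sw, A) obtained by
    normalizing the stationary mass over the three states sharing that
    proximity value, e.g. pi(St-C) / [pi(St-C) + pi(Sw-C) + pi(A-C)].
    """
    if tuple(pi.states) != JOINT_LABELS:
        raise ValueError("pi must be defined over the six joint states")
    out = []
    for prox in ProximityState:
        mass = np.array(
            [pi.pi[joint_index(b, prox)] for b in BEHAVIOR_STATES]
        )
        total = mass.sum()
        if total <= 0:
            raise ValueError(f"zero stationary mass for proximity {prox.value}")
        out.append(mass / total)
    return out[0], out[1]


def marginalize_to_open_loop(
    M_CL: TransitionMatrix,
    pi_CL: Optional[StationaryDistribution] = None,
) -> TransitionMatrix:
    """Marginalize the joint chain over proximity to a 3-state behavior chain.

    Entry (b, b') aggregates the joint transition mass from both proximity
    variants of b into any variant of b', weighted by the stationary
    probability of each source state:

        M_OL(b, b') = sum_p [sum_p' M_CL((b,p),(b',p'))] pi_CL(b,p) / pi_OL(b)

    where pi_OL(b) = sum_p pi_CL(b, p).
    """
    if tuple(M_CL.states) != JOINT_LABELS:
        raise ValueError("M_CL must be defined over the six joint states")
    if pi_CL is None:
        pi_CL = stationary_distribution(M_CL)
    elif np.abs(pi_CL.pi @ M_CL.P - pi_CL.pi).max() > 1e-6:
        raise ValueError("pi_CL is not stationary for M_CL")
    pi = pi_CL.pi
    # 6x6 -> (3 behaviors, 2 proximities, 3 behaviors, 2 proximities)
    blocks = M_CL.P.reshape(3, 2, 3, 2)
    pi_joint = pi.reshape(3, 2)
    pi_ol = pi_joint.sum(axis=1)
    if np.any(pi_ol <= 0):
        raise ValueError("a behavior state has zero stationary mass")
    # sum over destination proximity, weight source proximity by pi
    P_ol = np.einsum("ipj,ip->ij", blocks.sum(axis=3), pi_joint) / pi_ol[:, None]
    return TransitionMatrix(
        states=BEHAVIOR_LABELS,
        P=P_ol,
        meta={"derived_from": "proximity marginalization of joint chain"},
    )


def sample_next_state(
    M: TransitionMatrix, current, rng: np.random.Generator
) -> str:
    """Draw the next state label from the row of ``current``."""
    cum = np.cumsum(M.row(current))
    idx = min(int(np.searchsorted(cum, rng.random(), side="right")), M.n_states - 1)
    return M.states[idx]


def classify_proximity(fish_pos, robot_z: float, arena) -> ProximityState:
    """Closed-loop proximity classifier.

    The fish is *close* iff its longitudinal position lies in the third of
    the central tank adjacent to the replica's lateral tank (x in [0, L/3)
    with the origin on the replica-side wall) AND fish and replica occupy
    the same vertical half of the water column; otherwise *far*.  The
    midline itself belongs to the lower half.
    """
    x, _, z = np.asarray(fish_pos, dtype=float)
    L, depth = arena.central_length_cm, arena.water_depth_cm
    if not (0 <= x <= L) or not (0 <= z <= depth):
        raise ValueError(f"fish position ({x:.2f}, z={z:.2f}) outside the arena")
    if not (0 <= robot_z <= depth):
        raise ValueError(f"robot depth {robot_z:.2f} outside the water column")
    mid = depth / 2.0
    same_half = (z <= mid) == (robot_z <= mid)
    nearest_third = x < L / 3.0
    return ProximityState.C if (nearest_third and same_half) else ProximityState.F


def read_scored_sequence(path: Union[str, Path]) -> list:
    """Read a scored state sequence from two-column text (time_s, state)."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("scored sequence file needs (time_s, state) columns")
    return [str(s) for s in frame.iloc[:, 1]]
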