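"""Controllable effectors and their deterministic kinematics.

Two effector families are supported: a free-flying point cursor whose pose is
its position in the workspace, and an articulated serial kinematic chain whose
pose is a vector of joint angles.  In both cases the decoder commands a
*velocity* (per-timestep pose increment) and the pose is physically governed
by the velocity: ``p_{t+1} = p_t + dt * v_t``, with the velocity itself
replaced afterwards.  This one-step lag mirrors the block structure of the
steady-state velocity Kalman filter decoder (see :mod:`imitatebci.decoder`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KinematicState",
    "Joint",
    "ChainModel",
    "Goal",
    "integrate_state",
    "forward_kinematics",
    "chain_jacobian",
    "distance_to_goal",
    "arm_chain",
    "chain_from_json",
    "chain_to_json",
]


@dataclass(frozen=True)
class KinematicState:
    """Effector pose and velocity at a single timestep.

    ``pose`` is cursor position in task units or joint angles in radians;
    ``velocity`` is the per-timestep pose increment.
    """

    pose: np.ndarray
    velocity: np.ndarray
    t: int = 0

    def __post_init__(self):
        pose = np.asarray(self.pose, dtype=float)
        velocity = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "pose", pose)
        object.__setattr__(self, "velocity", velocity)
        if pose.shape != velocity.shape or pose.ndim != 1:
            raise ValueError(
                f"pose (length {pose.size}) and velocity (length {velocity.size}) "
                "must be 1-D vectors of identical length"
            )
        if not (np.all(np.isfinite(pose)) and np.all(np.isfinite(velocity))):
            raise ValueError("pose and velocity must be finite")
        if self.t < 0:
            raise ValueError("timestep t must be nonnegative")

    @property
    def ndim(self) -> int:
        return self.pose.size


def integrate_state(state: KinematicState, new_velocity: np.ndarray, dt: float = 1.0) -> KinematicState:
    """Advance the effector one timestep.

    The pose advances with the *current* velocity (``p + dt*v``) and the
    velocity is then replaced by ``new_velocity``; the commanded velocity thus
    moves the pose one step later, exactly as in the decoder's block update.
    """
    new_velocity = np.asarray(new_velocity, dtype=float)
    if new_velocity.shape != state.pose.shape:
        raise ValueError(
            f"new_velocity has length {new_velocity.size}, expected {state.pose.size}"
        )
    if not np.all(np.isfinite(new_velocity)):
        raise ValueError("new_velocity must be finite")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return KinematicState(
        pose=state.pose + dt * state.velocity,
        velocity=new_velocity,
        t=state.t + 1,
    )


@dataclass(frozen=True)
class Joint:
    """One revolute joint: rotation axis (unit 3-vector) and the length of the
    link extending from the joint along its local x-axis."""

    axis: np.ndarray
    length: float

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if axis.shape != (3,) or norm == 0:
            raise ValueError("joint axis must be a nonzero 3-vector")
        object.__setattr__(self, "axis", axis / norm)
        if self.length <= 0:
            raise ValueError(f"link length must be strictly positive, got {self.length}")


@dataclass(frozen=True)
class ChainModel:
    """Serial kinematic chain with named marker points.

    Markers are given as ``name -> (link_index, offset)`` where the marker sits
    ``offset`` task units from joint ``link_index`` along its link direction.
    """

    joints: tuple[Joint, ...]
    base_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    markers: dict[str, tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "joints", tuple(self.joints))
        object.__setattr__(self, "base_position", np.asarray(self.base_position, dtype=float))
        if len(self.joints) == 0:
            raise ValueError("chain must have at least one joint")
        for name, (idx, off) in self.markers.items():
            if not 0 <= idx < len(self.joints):
                raise ValueError(f"marker {name!r} references link {idx} outside the chain")

    @property
    def n_joints(self) -> int:
        return len(self.joints)


def _axis_angle_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis (hot path: no scipy)."""
    x, y, z = axis
    c, s = np.cos(theta), np.sin(theta)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _frames(chain: ChainModel, angles: np.ndarray):
    """Joint origins and world-frame rotations along the chain."""
    origins = np.empty((chain.n_joints + 1, 3))
    rots = []
    origins[0] = chain.base_position
    R = np.eye(3)
    for i, joint in enumerate(chain.joints):
        R = R @ _axis_angle_matrix(joint.axis, angles[i])
        rots.append(R)
        origins[i + 1] = origins[i] + R[:, 0] * joint.length
    return origins, rots


def forward_kinematics(chain: ChainModel, angles: np.ndarray) -> dict[str, np.ndarray]:
    """Marker world positions for the given joint angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (chain.n_joints,):
        raise ValueError(
            f"expected {chain.n_joints} joint angles, got {angles.size}"
        )
    origins, rots = _frames(chain, angles)
    out = {}
    for name, (idx, off) in chain.markers.items():
        out[name] = origins[idx] + rots[idx][:, 0] * off
    return out


def chain_jacobian(chain: ChainModel, angles: np.ndarray, marker_names) -> np.ndarray:
    """Analytic task Jacobian of the stacked markers: shape (3*M, n_joints).

    Column j of each marker block is ``axis_j x (m - p_j)`` for joints at or
    below the marker's link, zero for joints further down the chain.
    """
    angles = np.asarray(angles, dtype=float)
    origins, rots = _frames(chain, angles)
    J = np.zeros((3 * len(marker_names), chain.n_joints))
    Rprev = np.eye(3)
    world_axes = []
    for i, joint in enumerate(chain.joints):
        world_axes.append(Rprev @ joint.axis)
        Rprev = rots[i]
    for m, name in enumerate(marker_names):
        idx, off = chain.markers[name]
        pos = origins[idx] + rots[idx][:, 0] * off
        for j in range(idx + 1):
            J[3 * m : 3 * m + 3, j] = np.cross(world_axes[j], pos - origins[j])
    return J


@dataclass(frozen=True)
class Goal:
    """A reach target: a single point for the cursor, or a wand (wrist target
    plus up to two fingertip touch points) for the arm."""

    kind: str
    positions: np.ndarray

    def __post_init__(self):
        positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", positions)
        if not np.all(np.isfinite(positions)):
            raise ValueError("goal positions must be finite")
        if self.kind == "cursor_point":
            if positions.shape[0] != 1:
                raise ValueError("cursor_point goal carries exactly one position")
        elif self.kind == "wand":
            if not 1 <= positions.shape[0] <= 3:
                raise ValueError("wand goal carries between 1 and 3 points")
        else:
            raise ValueError(f"unknown goal kind {self.kind!r}")

    @property
    def point(self) -> np.ndarray:
        return self.positions[0]

    @property
    def touch_points(self) -> np.ndarray:
        """Fingertip touch points for a wand (falls back to the wrist target)."""
        if self.positions.shape[0] > 1:
            return self.positions[1:]
        return self.positions


# fingertip markers used during the grasp phase, in touch-point order
GRASP_MARKERS = ("thumb_tip", "mid_tip")


def distance_to_goal(state_or_markers, goal: Goal, phase: int = 1) -> float:
    """Distance of the effector from the goal.

    Cursor: Euclidean pose-goal distance.  Wand: phase 1 is wrist-to-wand
    distance; phase 2 is the worst fingertip-to-touch-point distance.
    """
    if goal.kind == "cursor_point":
        pose = state_or_markers.pose if isinstance(state_or_markers, KinematicState) else np.asarray(state_or_markers)
        return float(np.linalg.norm(pose - goal.point))
    if goal.kind == "wand":
        markers = state_or_markers
        if not isinstance(markers, dict):
            raise TypeError("wand goals require a marker-name -> position mapping")
        if phase == 1:
            return float(np.linalg.norm(markers["wrist"] - goal.point))
        touch = goal.touch_points
        dists = [
            np.linalg.norm(markers[name] - touch[i % len(touch)])
            for i, name in enumerate(GRASP_MARKERS)
            if name in markers
        ]
        return float(max(dists))
    raise ValueError(f"unknown goal kind {goal.kind!r}")  # pragma: no cover


def arm_chain() -> ChainModel:
    """Default 8-DOF stand-in for an arm effector.

    Two "shoulder" joints, one "elbow", two "wrist" joints, and three "finger"
    joints with progressively shorter distal links, so the degrees of freedom
    have deliberately non-uniform task relevance: the shoulder moves the wrist
    marker a lot, the distal finger joint barely moves anything.
    """
    z, y = np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])
    joints = (
        Joint(z, 0.25),   # shoulder yaw
        Joint(y, 1.50),   # shoulder pitch, upper arm
        Joint(y, 1.20),   # elbow, forearm
        Joint(z, 0.25),   # wrist yaw
        Joint(y, 0.25),   # wrist pitch
        Joint(y, 0.20),   # finger proximal
        Joint(y, 0.15),   # finger middle
        Joint(y, 0.04),   # finger distal (tiny link: short lever, rarely needed)
    )
    markers = {
        "wrist": (4, 0.25),
        "thumb_tip": (5, 0.20),
        "mid_tip": (7, 0.04),
    }
    return ChainModel(joints=joints, markers=markers)


def chain_to_json(chain: ChainModel) -> str:
    doc = {
        "base_position": chain.base_position.tolist(),
        "joints": [{"axis": j.axis.tolist(), "length": j.length} for j in chain.joints],
        "markers": {k: [int(i), float(o)] for k, (i, o) in chain.markers.items()},
    }
    return json.dumps(doc, indent=1)


def chain_from_json(doc: str) -> ChainModel:
    d = json.loads(doc)
    return ChainModel(
        joints=tuple(Joint(np.asarray(j["axis"]), j["length"]) for j in d["joints"]),
        base_position=np.asarray(d.get("base_position", [0, 0, 0])),
        markers={k: (int(v[0]), float(v[1])) for k, v in d.get("markers", {}).items()},
    )
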