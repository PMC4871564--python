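"""Intention oracles and intention-mismatch wrappers.

An intention oracle is a goal-aware model of the user's intended instantaneous
movement.  It supplies the per-timestep training labels o_t that the decoder
imitates; learnable decoders never see the goal, only the oracle does.

Two oracles are provided:

* ``cursor_oracle`` — the optimal-control solution for a point cursor under a
  quadratic velocity penalty: equal-length velocity vectors pointed straight
  at the target, capped near the goal to avoid overshoot.
* ``chain_oracle`` — a one-step damped-least-squares (resolved-rate) controller
  for an articulated chain: the closed-form incremental optimal step for a
  quadratic end-effector cost, with a two-phase wand task (reach with the
  wrist, then touch the wand with two fingertips).

Mismatch wrappers transform the oracle action into the signal that *actually*
drives the simulated neural activity, modelling discrepancies between the
assumed oracle and the user's true intention: isotropic intention noise, a
fixed linear operator, or a distance-dependent "arc" rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .effector import (
    GRASP_MARKERS,
    ChainModel,
    Goal,
    chain_jacobian,
    forward_kinematics,
)

__all__ = [
    "OracleAction",
    "MismatchSpec",
    "ChainOracleSpec",
    "cursor_oracle",
    "chain_oracle",
    "apply_intention_noise",
    "apply_linear_mismatch",
    "apply_arc_mismatch",
    "arc_rotation",
    "make_mismatch",
]


@dataclass(frozen=True)
class OracleAction:
    """An intended per-timestep velocity (pose units per timestep)."""

    velocity: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "velocity", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("oracle velocity must be finite")


@dataclass(frozen=True)
class MismatchSpec:
    """Which intention-mismatch transformation to apply, and its parameters.

    kind: 'none' | 'noise' | 'linear' | 'arc'.
    noise_pct: magnitude of the random intention relative to the oracle, in
        percent (100 adds a randomly directed vector of equal norm).
    M: the fixed linear operator (kind='linear').
    phi_max: maximal arc rotation angle in degrees (kind='arc').
    sigmoid_midpoint/sigmoid_slope: the logistic ramp of arc angle with
        distance to goal.
    """

    kind: str = "none"
    noise_pct: float = 0.0
    M: np.ndarray | None = None
    phi_max: float = 0.0
    sigmoid_midpoint: float = 3.0
    sigmoid_slope: float = 1.0

    def __post_init__(self):
        if self.kind not in ("none", "noise", "linear", "arc"):
            raise ValueError(f"unknown mismatch kind {self.kind!r}")
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be nonnegative")
        if not 0.0 <= self.phi_max <= 90.0:
            raise ValueError("phi_max must lie in [0, 90] degrees")
        if self.kind == "linear":
            if self.M is None:
                raise ValueError("linear mismatch requires a matrix M")
            M = np.asarray(self.M, dtype=float)
            object.__setattr__(self, "M", M)
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError("M must be square")
            if abs(np.linalg.det(M)) < 1e-12:
                raise ValueError("M must be invertible")


@dataclass(frozen=True)
class ChainOracleSpec:
    """Parameters of the damped-least-squares chain oracle.

    mu: damping of the pseudo-inversion (>0 keeps it well-posed at
        singular poses).
    omega_max: per-joint speed cap, rad/timestep (inf-norm bound).
    delta: wrist-to-wand radius at which the task switches from the reach
        phase to the fingertip-touch phase.
    goal_tol: fingertip tolerance at which the grasp counts as complete
        (the oracle returns zero once every fingertip is this close).
    """

    mu: float = 1e-3
    omega_max: float = 0.1
    delta: float = 0.5
    goal_tol: float = 0.2

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("damping mu must be positive (mu=0 makes the pseudo-inversion singular)")
        if self.omega_max <= 0 or self.delta <= 0 or self.goal_tol <= 0:
            raise ValueError("omega_max, delta and goal_tol must be positive")


def cursor_oracle(pose: np.ndarray, goal: Goal, speed: float, dt: float = 1.0, tol: float = 0.0) -> OracleAction:
    """Constant-speed goal-directed intention for the point cursor.

    Beyond one step of the goal the velocity has norm exactly ``speed``; within
    one step it is capped at the remaining distance (no overshoot); within
    ``tol`` of the goal it is zero.
    """
    if speed <= 0:
        raise ValueError("oracle speed must be positive")
    pose = np.asarray(pose, dtype=float)
    delta = goal.point - pose
    dist = np.linalg.norm(delta)
    if dist <= tol or dist == 0.0:
        return OracleAction(np.zeros_like(pose))
    if dist <= speed * dt:
        return OracleAction(delta / dt)
    return OracleAction(speed * delta / dist)


def chain_oracle(chain: ChainModel, angles: np.ndarray, goal: Goal, spec: ChainOracleSpec) -> OracleAction:
    """One damped-least-squares step toward the wand.

    Phase 1 drives the wrist marker to the wand; once the wrist is within
    ``spec.delta``, phase 2 drives both fingertips to their touch points.
    The joint step is Jt (J Jt + mu I)^-1 e, rescaled so no joint exceeds
    ``spec.omega_max``.
    """
    if goal.kind != "wand":
        raise ValueError("chain_oracle requires a wand goal")
    angles = np.asarray(angles, dtype=float)
    markers = forward_kinematics(chain, angles)
    wrist_err = goal.point - markers["wrist"]
    if np.linalg.norm(wrist_err) > spec.delta:
        names = ("wrist",)
        err = wrist_err
    else:
        names = GRASP_MARKERS
        touch = goal.touch_points
        errs = [touch[i % len(touch)] - markers[n] for i, n in enumerate(names)]
        if max(np.linalg.norm(e) for e in errs) <= spec.goal_tol:
            return OracleAction(np.zeros(chain.n_joints))
        err = np.concatenate(errs)
    J = chain_jacobian(chain, angles, names)
    JJt = J @ J.T
    dtheta = J.T @ np.linalg.solve(JJt + spec.mu * np.eye(JJt.shape[0]), err)
    peak = np.max(np.abs(dtheta))
    if peak > spec.omega_max:
        dtheta *= spec.omega_max / peak
    return OracleAction(dtheta)


def apply_intention_noise(o: OracleAction, noise_pct: float, rng: np.random.Generator) -> OracleAction:
    """Add a randomly directed vector of norm (noise_pct/100)*|o| to the
    intention.  The result is not renormalized."""
    if noise_pct < 0:
        raise ValueError("noise_pct must be nonnegative")
    v = o.velocity
    if noise_pct == 0:
        return o
    r = rng.standard_normal(v.size)
    norm = np.linalg.norm(r)
    while norm == 0.0:  # pragma: no cover - probability zero
        r = rng.standard_normal(v.size)
        norm = np.linalg.norm(r)
    return OracleAction(v + (noise_pct / 100.0) * np.linalg.norm(v) * r / norm)


def apply_linear_mismatch(o: OracleAction, M: np.ndarray) -> OracleAction:
    """Bias the intention by a fixed linear operator: u = M o."""
    M = np.asarray(M, dtype=float)
    v = o.velocity
    if M.ndim != 2 or M.shape != (v.size, v.size):
        raise ValueError(f"M has shape {M.shape}, expected ({v.size}, {v.size})")
    return OracleAction(M @ v)


def arc_rotation(theta: float) -> np.ndarray:
    """Rotation applying angle ``theta`` (radians) in the xy, yz and zx
    coordinate planes sequentially, in that fixed order."""
    c, s = np.cos(theta), np.sin(theta)
    rot_xy = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rot_yz = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    rot_zx = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return rot_zx @ rot_yz @ rot_xy


def apply_arc_mismatch(o: OracleAction, pose: np.ndarray, goal: Goal, spec: MismatchSpec) -> OracleAction:
    """Distance-dependent rotation of the intention, modelling a user whose
    intended trajectory arcs toward the goal.

    The rotation angle follows a logistic ramp of the cursor-goal distance d:
    theta(d) = phi_max * sigmoid((d - midpoint)/slope), so the discrepancy is
    maximal far from the goal and vanishes on approach.
    """
    if not 0.0 <= spec.phi_max <= 90.0:
        raise ValueError("phi_max must lie in [0, 90] degrees")
    if spec.phi_max == 0.0:
        return o
    d = float(np.linalg.norm(goal.point - np.asarray(pose, dtype=float)))
    theta = np.deg2rad(spec.phi_max) * expit((d - spec.sigmoid_midpoint) / spec.sigmoid_slope)
    return OracleAction(arc_rotation(theta) @ o.velocity)


def make_mismatch(spec: MismatchSpec, rng: np.random.Generator):
    """Bind a mismatch spec into a callable ``(o, pose, goal) -> user intention``."""
    if spec.kind == "none":
        return lambda o, pose, goal: o
    if spec.kind == "noise":
        return lambda o, pose, goal: apply_intention_noise(o, spec.noise_pct, rng)
    if spec.kind == "linear":
        return lambda o, pose, goal: apply_linear_mismatch(o, spec.M)
    if spec.kind == "arc":
        return lambda o, pose, goal: apply_arc_mismatch(o, pose, goal, spec)
    raise ValueError(f"unknown mismatch kind {spec.kind!r}")  # pragma: no cover
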