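"""Steady-state velocity Kalman filter (SSVKF) decoding and its fitting.

The decoder is the parameterized policy family

    v_{t+1} = F_v n_t + b_v + G_v v_t
    p_{t+1} = p_t + dt * v_t

i.e. neural activity relates only to velocity, and position is physically
governed by the velocity.  The steady-state gain is never derived from a
Kalman recursion; the family is treated directly as the policy class and fit
by (ridge) regression of the oracle actions on the regressors [n_t; 1; v_t],
where v_t is the realized closed-loop decoded velocity.  The bias b_v is
never penalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .effector import KinematicState

__all__ = [
    "DecoderParams",
    "FitReport",
    "decode_step",
    "fit_by_regression",
    "solve_readout",
    "ridge_mask",
    "init_decoder",
    "params_to_json",
    "params_from_json",
]


@dataclass(frozen=True)
class DecoderParams:
    """SSVKF parameters: neural read-out F_v (D x N), bias b_v (D), velocity
    prior dynamics G_v (D x D), and the integration step dt."""

    F_v: np.ndarray
    b_v: np.ndarray
    G_v: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        F = np.asarray(self.F_v, dtype=float)
        b = np.asarray(self.b_v, dtype=float)
        G = np.asarray(self.G_v, dtype=float)
        object.__setattr__(self, "F_v", F)
        object.__setattr__(self, "b_v", b)
        object.__setattr__(self, "G_v", G)
        D = F.shape[0]
        if b.shape != (D,) or G.shape != (D, D):
            raise ValueError(
                f"inconsistent shapes: F_v {F.shape}, b_v {b.shape}, G_v {G.shape}"
            )
        if not all(np.all(np.isfinite(m)) for m in (F, b, G)):
            raise ValueError("decoder parameters must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_neurons(self) -> int:
        return self.F_v.shape[1]

    @property
    def n_dof(self) -> int:
        return self.F_v.shape[0]

    def velocity(self, n: np.ndarray, v: np.ndarray) -> np.ndarray:
        """The policy output F_v n + b_v + G_v v."""
        return self.F_v @ n + self.b_v + self.G_v @ v

    def as_weights(self) -> np.ndarray:
        """Stacked weight matrix W = [F_v | b_v | G_v], shape D x (N+1+D)."""
        return np.hstack([self.F_v, self.b_v[:, None], self.G_v])

    @classmethod
    def from_weights(cls, W: np.ndarray, n_neurons: int, dt: float = 1.0) -> "DecoderParams":
        D = W.shape[0]
        return cls(
            F_v=W[:, :n_neurons],
            b_v=W[:, n_neurons],
            G_v=W[:, n_neurons + 1 : n_neurons + 1 + D],
            dt=dt,
        )


@dataclass(frozen=True)
class FitReport:
    """Regression diagnostics: per-DOF residual variance of the fit noise e_t,
    effective sample count, and the ridge coefficient used."""

    residual_var: np.ndarray
    n_samples: int
    ridge: float


def decode_step(n: np.ndarray, state: KinematicState, params: DecoderParams):
    """One decoder step: returns the commanded velocity and the next state.

    The pose advances with the current velocity; the commanded velocity takes
    effect on the pose one step later (the block structure of the SSVKF).
    """
    n = np.asarray(n, dtype=float)
    if n.shape != (params.n_neurons,):
        raise ValueError(f"neural sample has length {n.size}, expected {params.n_neurons}")
    if state.ndim != params.n_dof:
        raise ValueError(f"state dimension {state.ndim} != decoder DOF {params.n_dof}")
    action = params.velocity(n, state.velocity)
    next_state = KinematicState(
        pose=state.pose + params.dt * state.velocity,
        velocity=action,
        t=state.t + 1,
    )
    return action, next_state


def ridge_mask(n_neurons: int, n_dof: int) -> np.ndarray:
    """Diagonal of the penalty matrix: 1 on F_v and G_v entries, 0 on b_v."""
    d = np.ones(n_neurons + 1 + n_dof)
    d[n_neurons] = 0.0
    return d


def solve_readout(Z: np.ndarray, Y: np.ndarray, ridge: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Solve the shared-design ridge problem min |Z W^T - Y|^2 + ridge |W m|^2.

    With ridge=0 the minimum-norm least-squares solution is returned, so
    rank-deficient designs (unavoidable in noiseless closed-loop data, where
    the neural activity lives in the column space of A) are resolved by the
    standard tie-break rather than an error.
    Returns W of shape (Y.shape[1], Z.shape[1]).
    """
    if Z.shape[0] == 0:
        raise ValueError("cannot fit a decoder on an empty dataset")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if ridge == 0.0:
        W, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        return W.T
    if mask is None:
        mask = np.ones(Z.shape[1])
    gram = Z.T @ Z + ridge * np.diag(mask)
    return np.linalg.solve(gram, Z.T @ Y).T


def fit_by_regression(data, ridge: float = 1.0, dt: float = 1.0):
    """Fit {F_v, b_v, G_v} by ridge regression of the oracle actions on the
    regressors [n_t; 1; v_t].

    ``data`` is anything exposing ``regressors()`` and ``targets()`` (see
    :class:`imitatebci.updates.Dataset`) or a precomputed ``(Z, Y)`` pair.
    The penalty applies to the F_v and G_v blocks but not to the bias.
    """
    if isinstance(data, tuple):
        Z, Y = data
    else:
        Z, Y = data.regressors(), data.targets()
    D = Y.shape[1]
    n_neurons = Z.shape[1] - 1 - D
    W = solve_readout(Z, Y, ridge, ridge_mask(n_neurons, D))
    resid = Y - Z @ W.T
    report = FitReport(
        residual_var=np.mean(resid**2, axis=0),
        n_samples=Z.shape[0],
        ridge=ridge,
    )
    return DecoderParams.from_weights(W, n_neurons, dt=dt), report


def init_decoder(N: int, D: int, rng: np.random.Generator, scale: float = 0.01, dt: float = 1.0) -> DecoderParams:
    """Small random initial decoder: stable, albeit poorly performing.

    Entries of F_v and G_v are i.i.d. N(0, scale^2); b_v is zero; G_v is
    rescaled if needed so its spectral radius stays below 1 (bounded output).
    """
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    F = scale * rng.standard_normal((D, N))
    G = scale * rng.standard_normal((D, D))
    rho = float(np.max(np.abs(np.linalg.eigvals(G)))) if scale > 0 else 0.0
    if rho >= 0.95:
        G *= 0.95 / rho
    return DecoderParams(F_v=F, b_v=np.zeros(D), G_v=G, dt=dt)


def params_to_json(params: DecoderParams) -> str:
    return json.dumps(
        {
            "F_v": params.F_v.tolist(),
            "b_v": params.b_v.tolist(),
            "G_v": params.G_v.tolist(),
            "dt": params.dt,
        }
    )


def params_from_json(doc: str) -> DecoderParams:
    d = json.loads(doc)
    return DecoderParams(
        F_v=np.asarray(d["F_v"]),
        b_v=np.asarray(d["b_v"]),
        G_v=np.asarray(d["G_v"]),
        dt=float(d.get("dt", 1.0)),
    )
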