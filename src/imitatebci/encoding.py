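"""Synthetic linear-Gaussian neural encoding.

Simulated neural activity is generated from the user's intended velocity u_t
through a fixed tuning matrix A plus Gaussian noise:

    n_t = A u_t + c_t,   c_t ~ N(0, C)

A is sampled with i.i.d. standard-normal entries (optionally rectified so
neurons do not encode every degree of freedom), and C is a scaled identity
calibrated so the per-neuron signal-to-noise ratio under the oracle action
distribution hits a target (1 by default, i.e. noise roughly as large as
signal).  The activity is a real-valued binned rate, not spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .oracle import OracleAction

__all__ = [
    "EncodingModel",
    "sample_encoding_model",
    "calibrate_noise",
    "encode",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class EncodingModel:
    """Tuning matrix A (N x D) and noise covariance C (N x N, PSD)."""

    A: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "C", C)
        if A.ndim != 2:
            raise ValueError("A must be a matrix")
        if C.shape != (A.shape[0], A.shape[0]):
            raise ValueError(f"C has shape {C.shape}, expected ({A.shape[0]}, {A.shape[0]})")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")
        eigs = np.linalg.eigvalsh(C)
        if eigs.min() < -1e-10 * max(1.0, eigs.max()):
            raise ValueError("C must be positive semi-definite")

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def n_dof(self) -> int:
        return self.A.shape[1]

    def noise_chol(self) -> np.ndarray | None:
        """Cholesky factor of C, or None when C = 0."""
        if not np.any(self.C):
            return None
        # jitter-free for diagonal C (the preset case)
        if np.count_nonzero(self.C - np.diag(np.diagonal(self.C))) == 0:
            return np.diag(np.sqrt(np.clip(np.diagonal(self.C), 0.0, None)))
        return np.linalg.cholesky(self.C + 1e-12 * np.eye(self.n_neurons))


def sample_encoding_model(N: int, D: int, rng: np.random.Generator, rectify: bool = False) -> np.ndarray:
    """Sample the tuning matrix A with i.i.d. N(0,1) entries.

    With ``rectify`` (the arm variant), negative entries are zeroed so that
    individual neurons do not encode all degrees of freedom.
    Returns A only; pair it with :func:`calibrate_noise` to build the model.
    """
    if N < 1 or D < 1:
        raise ValueError("N and D must be positive")
    A = rng.standard_normal((N, D))
    if rectify:
        A = np.maximum(A, 0.0)
    return A


def calibrate_noise(A: np.ndarray, oracle_speed: float, target_snr: float = 1.0) -> np.ndarray:
    """Scaled-identity noise covariance hitting a target SNR.

    SNR is operationalized as mean-over-neurons signal power divided by the
    noise variance, with the oracle action o uniformly distributed in
    direction with norm ``oracle_speed``.  Then E[(A o)_i^2] =
    speed^2 |a_i|^2 / D, so sigma^2 = speed^2 |A|_F^2 / (N D snr).
    """
    A = np.asarray(A, dtype=float)
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    fro2 = float(np.sum(A * A))
    if fro2 == 0.0:
        raise ValueError("A is zero: SNR is undefined")
    N, D = A.shape
    sigma2 = oracle_speed**2 * fro2 / (N * D * target_snr)
    return sigma2 * np.eye(N)


def encode(o_user: OracleAction | np.ndarray, model: EncodingModel, rng: np.random.Generator) -> np.ndarray:
    """One noisy neural sample n = A u + c from the user intention u.

    Note the user intention here is the intention *after* any mismatch
    transformation; the unmismatched oracle action remains the training
    label, so the oracle is used twice only when mismatch is absent.
    """
    u = o_user.velocity if isinstance(o_user, OracleAction) else np.asarray(o_user, dtype=float)
    if u.shape != (model.n_dof,):
        raise ValueError(f"intention has length {u.size}, expected {model.n_dof}")
    n = model.A @ u
    L = model.noise_chol()
    if L is not None:
        n = n + L @ rng.standard_normal(model.n_neurons)
    return n


def model_to_json(model: EncodingModel) -> str:
    return json.dumps({"A": model.A.tolist(), "C": model.C.tolist()})


def model_from_json(doc: str) -> EncodingModel:
    d = json.loads(doc)
    return EncodingModel(A=np.asarray(d["A"]), C=np.asarray(d["C"]))
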