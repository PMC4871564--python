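"""Dataset aggregation and the per-trial parameter-update rules.

Three update rules operate on the aggregated dataset of (state, neural,
oracle) triples collected in closed loop:

* OGD  — one gradient step on the newest trial's loss, rate 1/eta_k,
* MA   — convex combination of the current parameters with the newest
         trial's batch minimizer (smoothBatch),
* FTL  — full ridge refit on everything seen so far (follow-the-
         (regularized-)leader), computed either by a dense refit or, by
         default, exactly online via recursive least squares (RLS) with
         rank-one Sherman-Morrison updates.

All rules minimize the same surrogate imitation loss: the squared error
between the decoder/policy velocity and the oracle velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decoder import DecoderParams, fit_by_regression, ridge_mask

__all__ = [
    "Dataset",
    "UpdateSpec",
    "surrogate_loss",
    "ogd_update",
    "ma_update",
    "ftl_update",
    "RLSState",
    "rls_init",
    "rls_update",
    "make_updater",
    "tune_ogd_rate",
]


class Dataset:
    """Ordered (x, n, o) samples with per-trial boundaries.

    Regressors are z_t = [n_t; 1; v_t] (v_t the realized decoded velocity
    held in the state x_t) and targets are the oracle actions o_t.  Sufficient
    statistics (regressor Gram matrix, regressor-target cross-moment, count)
    are accumulated on append so follow-the-leader refits stay cheap.
    """

    def __init__(self, n_neurons: int, n_dof: int):
        self.n_neurons = int(n_neurons)
        self.n_dof = int(n_dof)
        self._trials: list[dict[str, np.ndarray]] = []
        p = n_neurons + 1 + n_dof
        self._gram = np.zeros((p, p))
        self._cross = np.zeros((p, n_dof))
        self._count = 0

    def __len__(self) -> int:
        return self._count

    @property
    def n_trials(self) -> int:
        return len(self._trials)

    @property
    def trial_lengths(self) -> list[int]:
        return [t["oracle"].shape[0] for t in self._trials]

    def append_trial(self, poses, velocities, neural, oracle) -> None:
        poses = np.atleast_2d(np.asarray(poses, dtype=float))
        velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
        neural = np.atleast_2d(np.asarray(neural, dtype=float))
        oracle = np.atleast_2d(np.asarray(oracle, dtype=float))
        T = oracle.shape[0]
        if not (poses.shape == velocities.shape == (T, self.n_dof)):
            raise ValueError("pose/velocity arrays inconsistent with dataset dimensions")
        if neural.shape != (T, self.n_neurons):
            raise ValueError("neural array inconsistent with dataset dimensions")
        self._trials.append(
            {"poses": poses, "velocities": velocities, "neural": neural, "oracle": oracle}
        )
        if T:
            Z = self._regressors_of(neural, velocities)
            self._gram += Z.T @ Z
            self._cross += Z.T @ oracle
            self._count += T

    @staticmethod
    def _regressors_of(neural: np.ndarray, velocities: np.ndarray) -> np.ndarray:
        ones = np.ones((neural.shape[0], 1))
        return np.hstack([neural, ones, velocities])

    def trial_arrays(self, k: int):
        """(Z, O) for trial k (0-based)."""
        t = self._trials[k]
        return self._regressors_of(t["neural"], t["velocities"]), t["oracle"]

    def regressors(self, trials=None) -> np.ndarray:
        idx = range(self.n_trials) if trials is None else trials
        return np.vstack(
            [self._regressors_of(self._trials[k]["neural"], self._trials[k]["velocities"]) for k in idx]
        )

    def targets(self, trials=None) -> np.ndarray:
        idx = range(self.n_trials) if trials is None else trials
        return np.vstack([self._trials[k]["oracle"] for k in idx])

    def prefix(self, k: int) -> "Dataset":
        """A new Dataset holding trials 0..k-1."""
        out = Dataset(self.n_neurons, self.n_dof)
        for t in self._trials[:k]:
            out.append_trial(t["poses"], t["velocities"], t["neural"], t["oracle"])
        return out

    def suffstats(self):
        """(Gram, cross-moment, count) accumulated over all samples."""
        return self._gram.copy(), self._cross.copy(), self._count


@dataclass(frozen=True)
class UpdateSpec:
    """Which update rule to run and its hyperparameters.

    lr0: base of the OGD schedule eta_k = lr0 * k ('linear', the log-regret
        regime) or eta_k = lr0 * sqrt(k) ('sqrt').
    lam: moving-average weight on the newest batch minimizer.
    ridge: l2 coefficient of the batch rules; each OGD update uses ridge/K.
    K: planned trial count (for the OGD regularization split).
    """

    rule: str = "ftl"
    lr0: float = 400.0
    lr_schedule: str = "linear"
    lam: float = 0.9
    ridge: float = 10.0
    K: int = 100

    def __post_init__(self):
        if self.rule not in ("ogd", "ma", "ftl", "rls"):
            raise ValueError(f"unknown update rule {self.rule!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")


def _loss_arrays(params: DecoderParams, Z: np.ndarray, O: np.ndarray) -> float:
    resid = Z @ params.as_weights().T - O
    return float(np.sum(resid * resid))


def surrogate_loss(params: DecoderParams, batch, trials=None) -> float:
    """Total squared error between policy velocity and oracle velocity over
    the batch.  The ridge penalty is never included here."""
    if isinstance(batch, tuple):
        Z, O = batch
    else:
        Z, O = batch.regressors(trials), batch.targets(trials)
    if Z.shape[0] == 0:
        raise ValueError("surrogate loss of an empty batch is undefined")
    return _loss_arrays(params, Z, O)


def ogd_update(params: DecoderParams, batch, spec: UpdateSpec, k: int) -> DecoderParams:
    """One step of online gradient descent on the newest trial.

    W <- W - (1/eta_k) * grad[ L(W, batch) + (ridge/K) |W m|^2 ], with
    eta_k = lr0 * k (or lr0 * sqrt(k)); the bias column is unpenalized.
    """
    if isinstance(batch, tuple):
        Z, O = batch
    else:
        Z, O = batch.regressors(), batch.targets()
    W = params.as_weights()
    grad = 2.0 * ((Z @ W.T - O).T @ Z)
    if spec.ridge:
        grad = grad + 2.0 * (spec.ridge / spec.K) * W * ridge_mask(params.n_neurons, params.n_dof)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("OGD gradient is not finite; reduce the learning rate")
    eta = spec.lr0 * (k if spec.lr_schedule == "linear" else np.sqrt(k))
    return DecoderParams.from_weights(W - grad / eta, params.n_neurons, dt=params.dt)


def ma_update(params: DecoderParams, batch, spec: UpdateSpec) -> DecoderParams:
    """Moving average (smoothBatch): (1-lam) * params + lam * argmin on the
    newest trial alone."""
    fitted, _ = fit_by_regression(batch, ridge=spec.ridge, dt=params.dt)
    W = (1.0 - spec.lam) * params.as_weights() + spec.lam * fitted.as_weights()
    return DecoderParams.from_weights(W, params.n_neurons, dt=params.dt)


def ftl_update(data: Dataset, spec: UpdateSpec, dt: float = 1.0) -> DecoderParams:
    """Follow-the-(regularized-)leader: full ridge refit on all data so far."""
    params, _ = fit_by_regression(data, ridge=spec.ridge, dt=dt)
    return params


@dataclass
class RLSState:
    """Streaming sufficient statistics for the exact online FTL solution.

    P is the inverse of (ridge * Itilde + Z^T Z); cross is Z^T O.  P is
    created lazily at the first sample (ridge * Itilde alone is singular in
    the unpenalized bias direction, but becomes strictly positive definite
    once a sample, whose bias entry is 1, is absorbed).
    """

    ridge: float
    mask: np.ndarray
    cross: np.ndarray
    P: np.ndarray | None = None
    count: int = 0

    def params(self, n_neurons: int, dt: float = 1.0) -> DecoderParams:
        if self.P is None:
            raise ValueError("no samples observed yet")
        return DecoderParams.from_weights((self.P @ self.cross).T, n_neurons, dt=dt)


def rls_init(n_neurons: int, n_dof: int, ridge: float) -> RLSState:
    if ridge <= 0:
        raise ValueError("RLS requires a positive ridge prior")
    p = n_neurons + 1 + n_dof
    return RLSState(ridge=ridge, mask=ridge_mask(n_neurons, n_dof), cross=np.zeros((p, n_dof)))


def rls_update(state: RLSState, Z: np.ndarray, O: np.ndarray, n_neurons: int, dt: float = 1.0):
    """Absorb new samples with rank-one Sherman-Morrison updates.

    Returns the updated state and the parameters, which equal the batch ridge
    refit on every sample seen so far (to numerical precision).
    """
    Z = np.atleast_2d(Z)
    O = np.atleast_2d(O)
    for i in range(Z.shape[0]):
        z = Z[i]
        state.cross += np.outer(z, O[i])
        if state.P is None:
            M = state.ridge * np.diag(state.mask) + np.outer(z, z)
            state.P = np.linalg.inv(M)
        else:
            Pz = state.P @ z
            denom = 1.0 + z @ Pz
            if denom <= 0:
                raise np.linalg.LinAlgError(
                    "inverse-Gram lost positive definiteness; re-factorize from raw sufficient statistics"
                )
            state.P -= np.outer(Pz, Pz) / denom
        state.count += 1
    if state.count == 0:
        raise ValueError("rls_update called before any samples were observed")
    return state, state.params(n_neurons, dt=dt)


class _Updater:
    """Binds an UpdateSpec to the run_session loop: called once per trial with
    the just-completed trial's samples and the full aggregate."""

    def __init__(self, spec: UpdateSpec, n_neurons: int, n_dof: int, dt: float = 1.0):
        self.spec = spec
        self.n_neurons = n_neurons
        self.dt = dt
        self._rls = (
            rls_init(n_neurons, n_dof, spec.ridge)
            if spec.rule in ("ftl", "rls") and spec.ridge > 0
            else None
        )

    def update(self, params: DecoderParams, trial_batch, aggregate: Dataset, k: int) -> DecoderParams:
        spec = self.spec
        Z, O = trial_batch
        if Z.shape[0] == 0:
            return params
        if spec.rule == "ogd":
            return ogd_update(params, trial_batch, spec, k)
        if spec.rule == "ma":
            return ma_update(params, trial_batch, spec)
        if self._rls is not None:
            _, new = rls_update(self._rls, Z, O, self.n_neurons, dt=self.dt)
            return new
        return ftl_update(aggregate, spec, dt=self.dt)


def make_updater(spec: UpdateSpec, n_neurons: int, n_dof: int, dt: float = 1.0) -> _Updater:
    return _Updater(spec, n_neurons, n_dof, dt)


def tune_ogd_rate(make_config, candidates, repeats: int = 3, seed: int = 0):
    """Small grid search for the OGD base learning rate.

    ``make_config(lr0, seed)`` must return a runnable session config; the
    candidate with the lowest mean cumulative trial SSE wins.  Returns
    (best lr0, {lr0: mean cumulative SSE}).
    """
    from .closed_loop import run_session  # local import to avoid a cycle

    scores = {}
    for lr0 in candidates:
        totals = []
        for r in range(repeats):
            result = run_session(make_config(lr0, seed + r))
            totals.append(sum(rec.sse for rec in result.records))
        scores[lr0] = float(np.mean(totals))
    best = min(scores, key=scores.get)
    return best, scores
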