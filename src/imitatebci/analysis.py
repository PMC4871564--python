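"""Evaluation of closed-loop training runs.

Covers the quantities the simulator is judged by: per-trial SSE/MSE and
acquisition time, empirical regret against the best-in-hindsight decoder,
log-log regret growth exponents, encoding-model recovery curves, plateau
detection, and the canned multi-repeat experiment presets with CSV/JSON
output (plots are a convenience layer; the tables are the canonical
artifact).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .closed_loop import (
    LoopConfig,
    SessionResult,
    TrialRecord,
    arm_preset,
    cursor_preset,
    run_session,
)
from .decoder import DecoderParams, fit_by_regression
from .oracle import MismatchSpec
from .updates import Dataset, UpdateSpec, surrogate_loss

__all__ = [
    "RegretCurve",
    "RecoveryCurve",
    "trial_sse",
    "trial_mse",
    "best_in_hindsight",
    "empirical_regret",
    "regret_growth_exponent",
    "encoding_recovery",
    "trials_to_recover",
    "plateau_trial",
    "summarize_sessions",
    "asymptotic_sse",
    "success_rate",
    "run_experiment_preset",
    "EXPERIMENT_PRESETS",
]


def trial_sse(record: TrialRecord) -> float:
    """Sum over the reach of squared error between the (pre-blend) decoded
    velocity and the oracle label.  SSE rather than MSE: it aggregates the
    single-timestep error with differences in acquisition time."""
    return record.sse


def trial_mse(record: TrialRecord) -> float:
    return record.mse


def best_in_hindsight(data: Dataset, ridge: float = 10.0, dt: float = 1.0) -> DecoderParams:
    """The best fixed realizable decoder on the realized sample sequence:
    the full-aggregate ridge minimizer (no goal access by construction)."""
    params, _ = fit_by_regression(data, ridge=ridge, dt=dt)
    return params


@dataclass
class RegretCurve:
    """Cumulative excess loss of the learning sequence versus the best fixed
    decoder in hindsight, per trial index."""

    regret: np.ndarray          # cumulative, length K
    losses: np.ndarray          # per-trial loss of the decoder held that trial
    best_losses: np.ndarray     # per-trial loss of the hindsight decoder
    best_params: DecoderParams

    @property
    def final(self) -> float:
        return float(self.regret[-1])


def empirical_regret(params_history, data: Dataset, ridge: float = 10.0) -> RegretCurve:
    """Regret_k = sum_{k'<=k} [L(pi^(k'), D(k')) - L(pi_flat, D(k'))], with
    the hindsight decoder fit once on the full aggregate with the same ridge
    as FTL, and losses evaluated on each trial's realized samples."""
    if len(params_history) != data.n_trials:
        raise ValueError(
            f"history has {len(params_history)} entries but the dataset has {data.n_trials} trials"
        )
    flat = best_in_hindsight(data, ridge=ridge)
    losses, best_losses = [], []
    for k in range(data.n_trials):
        Z, O = data.trial_arrays(k)
        if Z.shape[0] == 0:
            losses.append(0.0)
            best_losses.append(0.0)
            continue
        losses.append(surrogate_loss(params_history[k], (Z, O)))
        best_losses.append(surrogate_loss(flat, (Z, O)))
    losses = np.asarray(losses)
    best_losses = np.asarray(best_losses)
    return RegretCurve(
        regret=np.cumsum(losses - best_losses),
        losses=losses,
        best_losses=best_losses,
        best_params=flat,
    )


def regret_growth_exponent(curve: RegretCurve | np.ndarray, fit_range: tuple[int, int]) -> float:
    """Slope of the least-squares line of log(regret) vs log(k) over trials
    ``fit_range`` (1-based, inclusive).  Errors if regret is not positive on
    the whole range (start the range after regret becomes positive)."""
    regret = curve.regret if isinstance(curve, RegretCurve) else np.asarray(curve, dtype=float)
    lo, hi = fit_range
    if not 1 <= lo < hi <= regret.size:
        raise ValueError(f"fit range {fit_range} outside curve of length {regret.size}")
    ks = np.arange(lo, hi + 1)
    vals = regret[lo - 1 : hi]
    if np.any(vals <= 0):
        raise ValueError("regret must be positive over the fit range")
    slope, _ = np.polyfit(np.log(ks), np.log(vals), 1)
    return float(slope)


@dataclass
class RecoveryCurve:
    """Per-DOF correlation (across neurons) between the true tuning column
    and the column estimated from the aggregated data, per trial prefix."""

    correlations: np.ndarray  # (K, D); NaN where the prefix underdetermines the fit


def encoding_recovery(data: Dataset, true_A: np.ndarray, ridge: float = 1e-8) -> RecoveryCurve:
    """For each prefix D(1:k), estimate the encoding matrix by regressing the
    neural activity on the oracle actions and correlate each estimated column
    with the true one across neurons.

    Prefixes with fewer samples than DOF (or a DOF never excited) yield NaN
    entries rather than an error.
    """
    true_A = np.asarray(true_A, dtype=float)
    N, D = true_A.shape
    gram = np.zeros((D, D))
    cross = np.zeros((D, N))
    count = 0
    rows = []
    for k in range(data.n_trials):
        _, O = data.trial_arrays(k)
        if O.shape[0]:
            t = data._trials[k]
            gram += O.T @ O
            cross += O.T @ t["neural"]
            count += O.shape[0]
        if count < D:
            rows.append(np.full(D, np.nan))
            continue
        A_hat = np.linalg.solve(gram + ridge * np.eye(D), cross).T  # N x D
        corr = np.full(D, np.nan)
        for d in range(D):
            x, y = A_hat[:, d], true_A[:, d]
            sx, sy = x.std(), y.std()
            if sx > 0 and sy > 0:
                corr[d] = float(np.corrcoef(x, y)[0, 1])
        rows.append(corr)
    return RecoveryCurve(correlations=np.asarray(rows))


def trials_to_recover(curve: RecoveryCurve, dof: int, threshold: float = 0.8) -> int:
    """First trial (1-based) whose prefix estimate reaches the correlation
    threshold for the given DOF; one past the end if it never does."""
    col = curve.correlations[:, dof]
    hits = np.flatnonzero(~np.isnan(col) & (col >= threshold))
    return int(hits[0]) + 1 if hits.size else curve.correlations.shape[0] + 1


def plateau_trial(per_trial: np.ndarray, frac: float = 0.25, tail: float = 0.5) -> int:
    """First trial (1-based) at which the loss curve enters, and stays within,
    ``frac`` of the median over the final ``tail`` fraction of trials.

    One-sided: a value *below* the plateau reference is within the plateau
    (the curve approaches its floor from above).
    """
    per_trial = np.asarray(per_trial, dtype=float)
    K = per_trial.size
    ref = float(np.median(per_trial[int(np.floor(K * (1 - tail))):]))
    ok = per_trial <= (1.0 + frac) * ref
    # last index that violates the band, then the next trial starts the plateau
    bad = np.flatnonzero(~ok)
    return int(bad[-1]) + 2 if bad.size else 1


def summarize_sessions(results: list[SessionResult], **tags) -> pd.DataFrame:
    """Per-trial summary table over repeats: SSE, MSE, acquisition time,
    success, with one row per (repeat, trial)."""
    rows = []
    for r, res in enumerate(results):
        for rec in res.records:
            rows.append(
                dict(
                    repeat=r, trial=rec.k, sse=rec.sse, mse=rec.mse,
                    T_k=rec.T_k, success=bool(rec.success), **tags,
                )
            )
    return pd.DataFrame(rows)


def asymptotic_sse(df: pd.DataFrame, frac: float = 0.2) -> float:
    """Mean SSE over the final ``frac`` of trials, pooled across repeats.
    This is the package's single definition of 'asymptotic' loss."""
    K = int(df["trial"].max())
    cut = K - max(1, int(np.ceil(frac * K)))
    return float(df.loc[df["trial"] > cut, "sse"].mean())


def success_rate(df: pd.DataFrame, first_trial: int = 1) -> float:
    return float(df.loc[df["trial"] >= first_trial, "success"].mean())


def _median_curve(df: pd.DataFrame) -> np.ndarray:
    return df.groupby("trial")["sse"].median().sort_index().to_numpy()


def run_sessions(config: LoopConfig, repeats: int, seed: int) -> list[SessionResult]:
    """Run ``repeats`` independent sessions with per-repeat seeds derived from
    ``seed`` (sharing a repeat index across conditions pairs the encoding
    realization and goal sequence)."""
    return [run_session(dataclasses.replace(config, seed=_repeat_seed(seed, r))) for r in range(repeats)]


def _repeat_seed(seed: int, repeat: int) -> int:
    return (seed * 100_003 + repeat) % (2**31 - 1)


EXPERIMENT_PRESETS = ("cursor_compare", "arm_compare", "arm_recovery", "cursor_noise", "cursor_arc")

# conditions of the mismatch sweeps: intention-noise percentages and arc angles
NOISE_LEVELS = (0.0, 50.0, 100.0, 200.0)
ARC_ANGLES = (0.0, 15.0, 30.0, 45.0)


def run_experiment_preset(name: str, out_dir, repeats: int | None = None, reaches: int | None = None,
                          seed: int = 7, ogd_lr0: float | None = None) -> Path:
    """Run one of the canned multi-repeat experiments and write per-trial
    tables (summary.csv), derived curves, and a manifest to ``out_dir``.

    cursor_compare  — cursor task, FTL vs tuned OGD vs MA(0.9) learning curves.
    arm_compare     — arm task, same three update rules (all-DOF and
                   proximal-DOF losses both reported).
    arm_recovery— arm task, per-DOF encoding-recovery curves (FTL).
    cursor_noise   — cursor task, FTL under intention-noise mismatch sweeps.
    cursor_arc     — cursor task, FTL under arc-trajectory mismatch sweeps.
    """
    if name not in EXPERIMENT_PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(EXPERIMENT_PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    manifest: dict = {"preset": name, "seed": seed}

    def algo_specs(K):
        return {
            "ftl": UpdateSpec(rule="ftl", ridge=10.0, K=K),
            "ogd": UpdateSpec(rule="ogd", ridge=10.0, K=K, lr0=ogd_lr0 or UpdateSpec().lr0),
            "ma": UpdateSpec(rule="ma", lam=0.9, ridge=10.0, K=K),
        }

    if name in ("cursor_compare", "arm_compare"):
        preset = cursor_preset if name == "cursor_compare" else arm_preset
        reps = repeats if repeats is not None else (100 if name == "cursor_compare" else 50)
        base = preset()
        K = reaches or base.K
        for algo, spec in algo_specs(K).items():
            results = run_sessions(preset(K=K, update=spec), reps, seed)
            frames.append(summarize_sessions(results, algorithm=algo))
            if name == "arm_compare":
                frames[-1]["proximal_sse"] = _proximal_sse_column(results)
        manifest["algorithms"] = list(algo_specs(K))
    elif name == "arm_recovery":
        reps = repeats if repeats is not None else 1
        base = arm_preset()
        K = reaches or base.K
        recs = []
        for r in range(reps):
            res = run_session(arm_preset(K=K, seed=_repeat_seed(seed, r), update=UpdateSpec(rule="ftl", ridge=10.0, K=K)))
            curve = encoding_recovery(res.dataset, res.encoding.A)
            for k in range(curve.correlations.shape[0]):
                for d in range(curve.correlations.shape[1]):
                    recs.append(dict(repeat=r, trial=k + 1, dof=d, correlation=curve.correlations[k, d]))
            frame = summarize_sessions([res])
            frame["repeat"] = r
            frames.append(frame)
        pd.DataFrame(recs).to_csv(out / "recovery.csv", index=False)
    else:  # cursor_noise / cursor_arc
        reps = repeats if repeats is not None else 20
        base = cursor_preset()
        K = reaches or base.K
        levels = NOISE_LEVELS if name == "cursor_noise" else ARC_ANGLES
        for level in levels:
            if name == "cursor_noise":
                mm = MismatchSpec(kind="noise", noise_pct=level) if level else MismatchSpec()
            else:
                mm = MismatchSpec(kind="arc", phi_max=level) if level else MismatchSpec()
            results = run_sessions(
                cursor_preset(K=K, mismatch=mm, update=UpdateSpec(rule="ftl", ridge=10.0, K=K)),
                reps, seed,
            )
            frames.append(summarize_sessions(results, level=level))
        manifest["levels"] = list(levels)

    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out / "summary.csv", index=False)
    group_keys = [c for c in ("algorithm", "level") if c in df.columns]
    agg = (
        df.groupby(group_keys + ["trial"])["sse"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    agg["lo"] = agg["mean"] - 2 * agg["sem"]  # errorbars: 2 standard errors
    agg["hi"] = agg["mean"] + 2 * agg["sem"]
    agg.to_csv(out / "curves.csv", index=False)
    manifest.update(repeats=int(df["repeat"].max()) + 1, reaches=int(df["trial"].max()))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _proximal_sse_column(results: list[SessionResult]) -> list[float]:
    """Per-trial SSE restricted to the proximal (shoulder/elbow/wrist) DOF,
    aligned with the row order of summarize_sessions."""
    col = []
    for res in results:
        for rec in res.records:
            if rec.T_k:
                col.append(float(np.sum((rec.decoded[:, :5] - rec.oracle[:, :5]) ** 2)))
            else:
                col.append(0.0)
    return col


def plot_learning_curves(curves_csv, path, value: str = "mean") -> None:
    """Optional matplotlib rendering of curves.csv (mean with 2-SE band)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(curves_csv)
    key = "algorithm" if "algorithm" in df.columns else ("level" if "level" in df.columns else None)
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = df.groupby(key) if key else [("all", df)]
    for label, g in groups:
        g = g.sort_values("trial")
        ax.plot(g["trial"], g[value], label=str(label))
        ax.fill_between(g["trial"], g["lo"], g["hi"], alpha=0.25)
    ax.set_xlabel("reach index k")
    ax.set_ylabel("per-trial SSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
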