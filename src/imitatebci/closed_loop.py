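"""The closed-loop training meta-algorithm: dataset-aggregation imitation
learning for a BCI decoder.

Each session runs K reach trials.  Within a trial, every timestep (1) queries
the intention oracle for the training label o_t, (2) passes the (possibly
mismatched) user intention through the synthetic neural encoder, (3) decodes,
(4) executes a blend of oracle and decoder action (assisted decoding), and
(5) integrates the effector state.  After each trial the samples are appended
to the aggregated dataset and the configured update rule produces the next
decoder.

Randomness is split into independent streams (encoding model, neural noise,
goals, decoder init, mismatch, assisted-execution noise) spawned from one root
seed, so mismatch studies can share the encoding realization and goal sequence
across conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .decoder import DecoderParams, init_decoder
from .effector import (
    GRASP_MARKERS,
    ChainModel,
    Goal,
    KinematicState,
    arm_chain,
    forward_kinematics,
)
from .encoding import EncodingModel, calibrate_noise, sample_encoding_model
from .oracle import (
    ChainOracleSpec,
    MismatchSpec,
    OracleAction,
    chain_oracle,
    cursor_oracle,
    make_mismatch,
)
from .updates import Dataset, UpdateSpec, make_updater, surrogate_loss

__all__ = [
    "LoopConfig",
    "TrialRecord",
    "SessionResult",
    "blend_action",
    "sample_goal",
    "run_trial",
    "run_session",
    "cursor_preset",
    "arm_preset",
    "config_to_json",
    "config_from_json",
]


@dataclass(frozen=True)
class LoopConfig:
    """Everything needed to reproduce one closed-loop training session."""

    task: str = "cursor"
    K: int = 100                     # number of reach trials
    T: int = 200                     # max timesteps per reach
    epsilon: float = 0.5             # goal tolerance, task units
    beta: tuple = ()                 # assistance schedule; empty -> (1, 0, 0, ...)
    exec_noise_pct: float = 5.0      # intention noise on the *executed* oracle action while beta_k > 0
    n_neurons: int = 10
    snr: float = 1.0
    noise_sigma2: float | None = None  # overrides SNR calibration (0 = noiseless)
    rectify_A: bool = False
    oracle_speed: float = 0.5        # cursor oracle speed, task units/timestep
    workspace: float = 10.0          # cursor goals uniform in [-w, w]^3
    chain: ChainModel | None = None  # arm task effector
    chain_spec: ChainOracleSpec = field(default_factory=ChainOracleSpec)
    wand_radius: tuple = (1.2, 2.8)  # wand placement annulus, task units
    x0: tuple = ()                   # initial pose; empty -> task default
    reset_between: bool | None = None  # None -> cursor continues, arm resets
    mismatch: MismatchSpec = field(default_factory=MismatchSpec)
    update: UpdateSpec = field(default_factory=UpdateSpec)
    decoder_scale: float = 0.01
    speed_limit: float | None = None  # None -> 4x the oracle speed scale
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("cursor", "arm"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.T < 1 or self.K < 1:
            raise ValueError("K and T must be at least 1")
        for b in self.beta:
            if not 0.0 <= b <= 1.0:
                raise ValueError("beta values must lie in [0, 1]")
        if self.task == "arm" and self.chain is None:
            object.__setattr__(self, "chain", arm_chain())
        if self.task == "cursor" and self.workspace <= 0:
            raise ValueError("workspace half-width must be positive")
        if self.update.K != self.K:
            # the OGD per-update ridge split is 1/K of the batch coefficient
            object.__setattr__(self, "update", dataclasses.replace(self.update, K=self.K))

    @property
    def n_dof(self) -> int:
        return 3 if self.task == "cursor" else self.chain.n_joints

    def beta_at(self, k: int) -> float:
        """Assistance level for trial k (1-based).  Default schedule: full
        oracle assistance on the first trial, none afterwards."""
        if not self.beta:
            return 1.0 if k == 1 else 0.0
        return self.beta[min(k - 1, len(self.beta) - 1)]

    @property
    def effector_speed_limit(self) -> float:
        """Physical cap on the executed effector speed (Euclidean norm), per
        timestep.  A screen cursor or joint motor cannot move arbitrarily far
        in one step; the default (4x the oracle speed scale) never binds in
        normal operation but keeps a transiently unstable decoder rollout
        finite."""
        if self.speed_limit is not None:
            return self.speed_limit
        scale = self.oracle_speed if self.task == "cursor" else self.chain_spec.omega_max
        return 4.0 * scale * np.sqrt(self.n_dof)

    def initial_state(self) -> KinematicState:
        if self.x0:
            pose = np.asarray(self.x0, dtype=float)
        elif self.task == "cursor":
            pose = np.zeros(3)
        else:
            # bent rest pose: a fully extended chain is singular for the oracle
            pose = np.array([0.0, 0.6, 0.9, 0.0, 0.3, 0.2, 0.2, 0.2])[: self.n_dof]
        return KinematicState(pose=pose, velocity=np.zeros_like(pose), t=0)


@dataclass
class TrialRecord:
    """Everything observed during one reach."""

    k: int
    goal: Goal
    poses: np.ndarray       # (T_k, D) pose at each sampled step
    velocities: np.ndarray  # (T_k, D) realized velocity (regressor v_t)
    neural: np.ndarray      # (T_k, N)
    oracle: np.ndarray      # (T_k, D) oracle labels o_t
    decoded: np.ndarray     # (T_k, D) raw decoder output (pre-blend)
    executed: np.ndarray    # (T_k, D) blended action actually driving the effector
    success: bool
    final_distance: float

    @property
    def T_k(self) -> int:
        return self.oracle.shape[0]

    @property
    def step_losses(self) -> np.ndarray:
        return np.sum((self.decoded - self.oracle) ** 2, axis=1)

    @property
    def sse(self) -> float:
        return float(np.sum(self.step_losses)) if self.T_k else 0.0

    @property
    def mse(self) -> float:
        return self.sse / self.T_k if self.T_k else 0.0


@dataclass
class SessionResult:
    config: LoopConfig
    params_history: list[DecoderParams]  # params held during trial k (k = 1..K)
    final_params: DecoderParams
    best_params: DecoderParams
    records: list[TrialRecord]
    dataset: Dataset
    encoding: EncodingModel


def blend_action(o: OracleAction | np.ndarray, a_dec: np.ndarray, beta: float) -> np.ndarray:
    """Assisted decoding: the executed velocity is beta*oracle + (1-beta)*decoder."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    ov = o.velocity if isinstance(o, OracleAction) else np.asarray(o, dtype=float)
    return beta * ov + (1.0 - beta) * np.asarray(a_dec, dtype=float)


def sample_goal(config: LoopConfig, rng: np.random.Generator) -> Goal:
    """Random goal: uniform point in the cursor workspace, or a wand placed
    uniformly in direction within a reachable radius annulus for the arm.
    A fixed number of draws per trial keeps goal sequences aligned across
    conditions that share the goal stream."""
    if config.task == "cursor":
        w = config.workspace
        if w <= 0:
            raise ValueError("degenerate workspace")
        return Goal(kind="cursor_point", positions=rng.uniform(-w, w, size=3)[None, :])
    lo, hi = config.wand_radius
    if not 0 < lo < hi:
        raise ValueError("degenerate wand radius range")
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    radius = rng.uniform(lo, hi)
    pos = radius * direction
    offset = np.array([0.0, 0.0, 0.08])
    return Goal(kind="wand", positions=np.stack([pos, pos + offset, pos - offset]))


def _cursor_distance(state, goal, config):
    return float(np.linalg.norm(state.pose - goal.point))


def _arm_distance(state, goal, config):
    markers = forward_kinematics(config.chain, state.pose)
    touch = goal.touch_points
    return max(
        float(np.linalg.norm(markers[name] - touch[i % len(touch)]))
        for i, name in enumerate(GRASP_MARKERS)
    )


def run_trial(
    params: DecoderParams,
    goal: Goal,
    model: EncodingModel,
    config: LoopConfig,
    state: KinematicState,
    beta: float,
    noise_rng: np.random.Generator,
    mismatch_fn,
    exec_rng: np.random.Generator,
    k: int = 0,
):
    """One reach: loop until the goal condition is met or T steps elapse.

    Returns (TrialRecord, final state).  The *label* recorded for training is
    always the clean oracle action; the mismatch transformation applies only
    to the intention driving the neural encoding, and the assisted-execution
    noise only to the executed oracle share.
    """
    from .oracle import apply_intention_noise

    D, N = config.n_dof, config.n_neurons
    if model.n_dof != D or model.n_neurons != N or params.n_dof != D or params.n_neurons != N:
        raise ValueError(
            f"dimension mismatch: task D={D} N={N}, encoder ({model.n_neurons},{model.n_dof}), "
            f"decoder ({params.n_neurons},{params.n_dof})"
        )
    distance = _cursor_distance if config.task == "cursor" else _arm_distance
    cap = config.effector_speed_limit
    L = model.noise_chol()
    A = model.A
    spec = config.chain_spec
    poses, vels, neural, labels, decoded, executed = [], [], [], [], [], []
    steps = 0
    d = distance(state, goal, config)
    while d > config.epsilon and steps < config.T:
        if config.task == "cursor":
            o = cursor_oracle(state.pose, goal, config.oracle_speed, dt=config.dt)
        else:
            o = chain_oracle(config.chain, state.pose, goal, spec)
        u = mismatch_fn(o, state.pose, goal)
        n = A @ u.velocity
        if L is not None:
            n = n + L @ noise_rng.standard_normal(N)
        a_dec = params.velocity(n, state.velocity)
        if beta > 0.0:
            o_exec = apply_intention_noise(o, config.exec_noise_pct, exec_rng)
            action = blend_action(o_exec, a_dec, beta)
        else:
            action = a_dec
        speed = np.linalg.norm(action)
        if speed > cap:
            action = action * (cap / speed)
        poses.append(state.pose)
        vels.append(state.velocity)
        neural.append(n)
        labels.append(o.velocity)
        decoded.append(a_dec)
        executed.append(action)
        pose = state.pose + config.dt * state.velocity
        if config.task == "cursor":
            # the screen bounds the cursor: pose cannot leave the workspace
            np.clip(pose, -config.workspace, config.workspace, out=pose)
        state = KinematicState(pose=pose, velocity=action, t=state.t + 1)
        steps += 1
        d = distance(state, goal, config)

    def stack(rows, width):
        return np.asarray(rows, dtype=float) if rows else np.empty((0, width))

    record = TrialRecord(
        k=k,
        goal=goal,
        poses=stack(poses, D),
        velocities=stack(vels, D),
        neural=stack(neural, N),
        oracle=stack(labels, D),
        decoded=stack(decoded, D),
        executed=stack(executed, D),
        success=d <= config.epsilon,
        final_distance=d,
    )
    return record, state


def run_session(config: LoopConfig) -> SessionResult:
    """Run the full K-trial closed-loop training session."""
    ss = np.random.SeedSequence(config.seed)
    model_rng, noise_rng, goal_rng, init_rng, mismatch_rng, exec_rng = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    D, N = config.n_dof, config.n_neurons
    A = sample_encoding_model(N, D, model_rng, rectify=config.rectify_A)
    action_scale = config.oracle_speed if config.task == "cursor" else config.chain_spec.omega_max
    if config.noise_sigma2 is not None:
        C = config.noise_sigma2 * np.eye(N)
    else:
        C = calibrate_noise(A, action_scale, config.snr)
    model = EncodingModel(A=A, C=C)
    params = init_decoder(N, D, init_rng, scale=config.decoder_scale, dt=config.dt)
    mismatch_fn = make_mismatch(config.mismatch, mismatch_rng)
    reset = config.reset_between if config.reset_between is not None else (config.task == "arm")
    dataset = Dataset(N, D)
    updater = make_updater(config.update, N, D, dt=config.dt)
    state = config.initial_state()
    history: list[DecoderParams] = []
    records: list[TrialRecord] = []
    for k in range(1, config.K + 1):
        goal = sample_goal(config, goal_rng)
        record, end_state = run_trial(
            params, goal, model, config, state, config.beta_at(k),
            noise_rng, mismatch_fn, exec_rng, k=k,
        )
        history.append(params)
        records.append(record)
        dataset.append_trial(record.poses, record.velocities, record.neural, record.oracle)
        if record.T_k:
            try:
                params = updater.update(params, dataset.trial_arrays(k - 1), dataset, k)
            except Exception as err:
                raise RuntimeError(f"parameter update failed after trial {k}") from err
        state = config.initial_state() if reset else end_state

    best = _select_best(history, params, records, dataset, config)
    return SessionResult(
        config=config,
        params_history=history,
        final_params=params,
        best_params=best,
        records=records,
        dataset=dataset,
        encoding=model,
    )


def _select_best(history, final_params, records, dataset: Dataset, config: LoopConfig) -> DecoderParams:
    """'Best or last' policy selection: among the decoders held during the
    final 20% of trials (plus the final update), pick the one with lowest
    mean per-sample loss on that trailing window's samples."""
    K = len(history)
    start = max(0, K - max(1, int(np.ceil(0.2 * K))))
    window = [k for k in range(start, K) if records[k].T_k > 0]
    if not window:
        return final_params
    Z = dataset.regressors(window)
    O = dataset.targets(window)
    candidates = [history[k] for k in window] + [final_params]
    losses = [surrogate_loss(p, (Z, O)) for p in candidates]
    return candidates[int(np.argmin(losses))]


def cursor_preset(seed: int = 0, **overrides) -> LoopConfig:
    """The 3D cursor reach task: 10 neurons, SNR ~ 1 per neuron, up to 200
    timesteps per reach, 100 reaches."""
    base = dict(
        task="cursor", K=100, T=200, epsilon=0.5, n_neurons=10, snr=1.0,
        oracle_speed=0.5, workspace=10.0, seed=seed,
    )
    base.update(overrides)
    return LoopConfig(**base)


def arm_preset(seed: int = 0, **overrides) -> LoopConfig:
    """The articulated-arm wand task: 75 neurons, 8-DOF chain, up to 150
    timesteps per reach, 50 reaches, pose reset between reaches."""
    base = dict(
        task="arm", K=50, T=150, epsilon=0.2, n_neurons=75, snr=1.0,
        rectify_A=True, reset_between=True, seed=seed,
        chain_spec=ChainOracleSpec(mu=1e-3, omega_max=0.1, delta=0.5, goal_tol=0.2),
    )
    base.update(overrides)
    return LoopConfig(**base)


def config_to_json(config: LoopConfig) -> str:
    """Serialize a LoopConfig (chain and matrices included) to JSON."""
    from .effector import chain_to_json

    d = dataclasses.asdict(config)
    d["chain"] = json.loads(chain_to_json(config.chain)) if config.chain is not None else None
    if config.mismatch.M is not None:
        d["mismatch"]["M"] = np.asarray(config.mismatch.M).tolist()
    return json.dumps(d, indent=1)


def config_from_json(doc: str) -> LoopConfig:
    from .effector import chain_from_json

    d = json.loads(doc)
    chain = chain_from_json(json.dumps(d["chain"])) if d.get("chain") else None
    mm = d.get("mismatch", {})
    if mm.get("M") is not None:
        mm["M"] = np.asarray(mm["M"])
    d["chain"] = chain
    d["mismatch"] = MismatchSpec(**mm)
    d["update"] = UpdateSpec(**d.get("update", {}))
    d["chain_spec"] = ChainOracleSpec(**d.get("chain_spec", {}))
    d["beta"] = tuple(d.get("beta", ()))
    d["x0"] = tuple(d.get("x0", ()))
    d["wand_radius"] = tuple(d.get("wand_radius", (1.2, 2.8)))
    return LoopConfig(**d)
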