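# Methods

`imitatebci` simulates closed-loop training of a brain–computer-interface
decoder as online imitation learning.  This note records the model, the
defaults and why they were chosen, and what the synthetic studies do and do
not establish.

## The training loop

Data arrives in reach *trials* k = 1…K.  Within a trial the simulator cycles,
per timestep t:

1. **Oracle.**  A goal-aware intention oracle produces the intended velocity
   o_t = π*(x_t, g).  For the cursor this is the optimal-control solution
   under a quadratic velocity penalty — a constant-speed vector pointed at
   the goal, capped at the remaining distance so it never overshoots.  For
   the articulated chain it is one damped-least-squares (resolved-rate) step
   Δθ = Jᵀ(JJᵀ + μI)⁻¹e on the active marker errors, rescaled so no joint
   exceeds ω_max.  This closed-form incremental step stands in for an
   iterative optimal-control solver; it is the standard one-step optimum for
   a quadratic end-effector cost.
2. **Encoding.**  The *user intention* u_t — the oracle action passed through
   the configured mismatch transformation, or o_t itself when there is none —
   drives synthetic neural activity n_t = A u_t + c_t, c_t ∼ N(0, σ²I).
3. **Decoding.**  The steady-state velocity Kalman filter policy computes
   v̂ = F_v n_t + b_v + G_v v_t.
4. **Assisted execution.**  The executed velocity is β_k·(o_t + 5% intention
   noise) + (1 − β_k)·v̂.  The default schedule is abrupt: β₁ = 1, β_{k>1} = 0.
   The injected noise applies only to the *executed* oracle share, never to
   the recorded label; it enriches the otherwise single-direction first-trial
   design.
5. **Integration.**  p_{t+1} = p_t + dt·v_t and the velocity is replaced by
   the executed action.  The pose therefore follows the commanded velocity
   with a one-step lag — exactly the block structure of the decoder family.

The trial ends when the goal condition is met (cursor within ε of the goal;
both fingertips within the touch tolerance of the wand) or after T steps.
The trial's (x_t, n_t, o_t) triples are appended to the aggregate D(1:k) and
the update rule produces the next decoder.  The surrogate loss throughout is
Σ‖π(x, n) − o‖²: the decoder's *pre-blend* output against the oracle label.

## Update rules

* **OGD**: one gradient step on the newest trial's regularized loss with rate
  1/η_k, η_k = η₀·k (the schedule whose regret is logarithmic for quadratic
  losses; a √k schedule is available).  η₀ defaults to 400, fixed once by the
  shipped `tune_ogd_rate` grid search (candidates 10²…10⁵, criterion: mean
  cumulative trial SSE on the cursor preset).
* **MA (smoothBatch)**: π ← (1 − λ)π + λ·argmin on the newest trial alone,
  λ = 0.9 by default.
* **FTL/FTRL**: ridge refit on everything seen so far.  Executed by default
  through exact recursive least squares — rank-one Sherman–Morrison updates
  of the inverse regularized Gram — which reproduces the batch refit to
  machine precision at O(1) per sample; the dense refit path is retained and
  used automatically when ridge = 0.

The regression design is z_t = [n_t; 1; v_t] with target o_t, one shared
design for all output dimensions.  v_t is the *realized* closed-loop velocity,
so the state distribution is decoder-induced (the defining feature of
dataset-aggregation imitation learning).  The target is the oracle action
rather than the realized next velocity: the realized velocity is what the
possibly-poor decoder did, the oracle is what training should imitate.

### Regularization

One shared ridge coefficient (default 10) applies to the F_v and G_v blocks;
the bias is never penalized (it absorbs offsets, and penalizing it breaks
exact noiseless recovery).  Each OGD update carries 1/K of the batch
coefficient so all rules see equal total regularization pressure.  The ridge
is a *fixed* coefficient rather than one scaled with the sample count so the
RLS recursion with a fixed ridge·Ĩ prior is exactly the batch solution at
every sample.  Its scale — comparable to the regressor Gram of a single
typical trial — is chosen for the early updates: the first fits see a few
dozen samples from essentially one reach direction, and an unshrunk fit at
that point is aggressive and unstable in closed loop.  After ~10 trials the
penalty is below 1% of the Gram and the asymptotic fit is indistinguishable
from lightly regularized least squares.  With ridge = 0 rank-deficient
designs are resolved by the minimum-norm solution (they are unavoidable in
noiseless closed-loop data, where n_t lives in the D-dimensional column
space of A).

## Task presets

**Cursor** — D = 3, N = 10 neurons, A entries i.i.d. N(0, 1), SNR target 1,
oracle speed 0.5 units/step, workspace [−10, 10]³, goal tolerance ε = 0.5,
T = 200, K = 100, trials continue from the previous endpoint.  **Arm** —
8-DOF serial chain (two shoulder joints, elbow, two wrist joints, three
finger joints with progressively shorter distal links; total reach ≈ 3.7
units), N = 75 with negative tuning entries rectified to zero, ω_max = 0.1
rad/step, wand placed uniformly in direction at radius 1.2–2.8, phase-switch
radius δ = 0.5, touch tolerance 0.2, T = 150, K = 50, pose reset between
reaches to a bent rest configuration (a fully extended chain is a singular
start for the resolved-rate controller).  The chain geometry is deliberately
non-uniform in task relevance so that per-DOF encoding recovery separates
proximal from distal joints.

The SNR convention is mean-over-neurons signal power divided by noise
variance, with the intention uniformly distributed in direction at the
task's speed scale (cursor speed, or ω_max for the arm); this gives the
closed form σ² = speed²·‖A‖²_F / (N·D·SNR).  A per-neuron variant is a flag.

Two physical bounds keep pathological rollouts finite without affecting
normal operation: the cursor pose is clipped to the workspace (a screen
bounds its cursor), and the executed speed is capped at 4× the oracle speed
scale (normal decoded speeds sit far below it).  Without these, a transient
FTL fit whose velocity-feedback block has spectral radius slightly above 1 —
possible after the information-poor first trials — can grow its state
exponentially over a 200-step timeout trial and destroy the session
numerically.  With them, such a decoder produces one or two expensive trials
whose data then corrects the next fit.

## Randomness

Each session derives six independent streams (encoding model, neural noise,
goals, decoder initialization, mismatch draws, assisted-execution noise) from
one root seed.  Multi-repeat studies derive per-repeat roots from a master
seed, so two conditions run at the same repeat index share the encoding
realization and the goal sequence — mismatch sweeps are paired comparisons.
Goal sampling consumes a fixed number of draws per trial regardless of trial
length, keeping goal sequences aligned across conditions.

## Evaluation

* **Per-trial SSE** (decoded vs oracle, summed over a reach) is the headline
  loss: it compounds single-step error with acquisition time.  MSE and T_k
  are always emitted alongside.
* **Empirical regret**: Regret_k = Σ_{k′≤k} [L(π^(k′), D(k′)) − L(π♭, D(k′))]
  with π♭ the ridge fit to the full realized aggregate (same ridge as FTL),
  evaluated per trial on that trial's samples.  Growth exponents are
  least-squares slopes of log regret vs log k, fitted on the mean curve
  across repeats over trials 20–100.
* **Encoding recovery**: Â from regressing neural activity on oracle actions
  over each prefix D(1:k); per-DOF Pearson correlation with the true column
  across neurons.  Prefixes with fewer samples than DOF yield NaN, not an
  error.
* **Asymptotic loss** is the mean over the final 20% of trials, everywhere.
* **Plateau** is the first trial at which the median-across-repeats SSE curve
  enters, and stays within, +25% of its median over the final half of trials.
  The band is one-sided because the curve approaches its floor from above; a
  favourable dip must not postpone the plateau.  Note this statistic is
  demanding: with 20 repeats the median estimator's own trial-to-trial
  fluctuation is comparable to the 25% band (per-trial SSE varies with the
  drawn goal distance), and the curve also drifts slowly for tens of trials
  as early off-policy timeout data is diluted out of the aggregate — a real
  aggregation effect, since FTL never discards samples.  Visual flattening
  happens within ~10 reaches (the curve falls from ~200 to within a small
  multiple of its floor); the 25%-band statistic measures full saturation,
  which takes several times longer.

## What the generator does and does not emulate

The neural model is exactly linear-Gaussian rate coding of intended velocity
with stationary tuning: no spiking, no tuning drift, no history dependence,
no co-adaptation by the user.  The mismatch studies probe *intention* error
only — the encoding side is always correctly specified for the decoder
family.  Passing tests therefore establish the behaviour of the learning
rules under their own modelling assumptions (the regime in which the regret
theory applies), not robustness to misspecified encoding.  The arm is a
kinematic chain without contact, inertia or muscle dynamics, and its oracle
is a greedy one-step controller rather than a trajectory optimizer; the
qualitative proximal-before-distal recovery ordering is expected to be, and
is, insensitive to those simplifications, but joint-level numbers are not
transferable to a physical arm.

## Numerical notes and edge cases

Decoder initialization is small random (scale 0.01) with the velocity-
feedback block rescaled below spectral radius 0.95 — stable, albeit poorly
performing; an all-zero decoder would make the first trial's design rank
deficient.  The arc-mismatch rotation applies the angle sequentially in the
xy, yz and zx coordinate planes (equivalently an extrinsic z-x-y Euler
rotation with three equal angles); its logistic ramp defaults to midpoint 3
task units and unit slope.  The chain oracle refuses μ = 0; its phase
switches when the wrist enters δ, and it returns the zero action exactly
when the active goal condition is already met.  Updates are skipped for
zero-length trials (goal already within tolerance at trial start).  "Best"
decoder selection at session end evaluates the decoders held during the
final 20% of trials (plus the final update) on that window's samples and
keeps the argmin.
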