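# Methods

This note documents the models implemented in `emg2kin`, the parameters
that matter, what the synthetic generator does and does not emulate, and
the design choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Feature extraction

Raw EMG (R channels, sampling rate f_s, nominally 16 × 2048 Hz) is reduced
to per-channel RMS over non-overlapping windows of `window_seconds`
(default 0.1 s).  The window length in samples is `floor(f_s ·
window_seconds)` and a trailing partial window is discarded — a
deterministic rule chosen because nothing in the protocol constrains the
rounding; with 2048 Hz and 100 ms this gives 204-sample windows and a
10 Hz feature/control rate.  No software filtering is applied by default
(acquisition hardware is assumed to band-pass); an optional 6th-order
Butterworth band-pass (3–900 Hz, reduced below Nyquist when needed) is
provided for unfiltered recordings.  Channels are not normalized at the
feature level — scaling is handled downstream, where it can be undone.

## The autoencoder

Per DoF, the network is `a(t) = |IW · P(t)|` (two rectified linear hidden
units, no hidden bias) and `Q(t) = LW · a(t) + B`, trained so Q ≈ P.  The
absolute value guarantees nonnegative activations for arbitrary weights;
the generative assumption is that P is a nonnegative synergy mixture, so a
rank-2 rectified code suffices for single-DoF data and the two units come
to represent the two movement directions.

**Training.**  Levenberg–Marquardt on the stacked residual vector (R·N
residuals, 5R free parameters), with the analytic Jacobian using the
subgradient `sign(x)`, `sign(0) = 0`, for `|·|`.  Damping: λ starts at
1e−3, ×10 on a rejected step, ×0.1 on an accepted one; steps solve
`(JᵀJ + λI) δ = −Jᵀr` (Levenberg form; with per-channel max-normalized
features the parameter scales are homogeneous enough that Marquardt
diagonal scaling buys nothing).  Termination: relative SSE decrease below
`convergence_tol` (1e−8), `max_iterations` (200), or λ overflow (1e12,
i.e. no downhill step exists).  Accepted-step SSE is non-increasing by
construction.  A trial step with non-finite SSE is rejected like any
uphill step; non-finite parameters abort the restart.

**Normalization.**  Features are max-normalized per channel for training
only (it stabilizes the uniform ±0.5 weight initialization); the
normalization is folded back into the returned weights
(`IW/m`, `LW·m`, `B·m`), so the stored network applies to raw features.
Activations are unchanged by this folding.

**Restarts and selection.**  `n_restarts = 10` independent initializations,
each from a deterministic child seed of the configured seed
(`SeedSequence.spawn`), so the procedure is exactly reproducible.  The
kept network minimizes the *absolute* Pearson correlation between the two
hidden time courses over the calibration set: anti-correlated units are as
entangled as correlated ones, which is why the absolute value is minimized
rather than the signed correlation.  A hidden unit with zero variance is
treated as correlation 0 (perfectly decoupled).

## Calibration

Two indeterminacies remain after fitting: which unit is which direction,
and the activation scale (row/column rescaling of IW/LW leaves Q
unchanged).

**Direction assignment** uses the per-window direction annotations of the
calibration session: each unit goes to the direction with the larger mean
activation over that direction's windows; if both units prefer the same
direction the network is entangled and calibration refuses (refit with a
new seed).  Without annotations, the identity assignment is returned
flagged `unverified`, and the CLI exposes `--flip-dof1/--flip-dof2`
overrides.

**Scale** is set by correction factors τ.  The base rule maps the 0.95
quantile of each unit's activation, over windows where that unit
*dominates*, to the target range (quantile rather than maximum for outlier
robustness).  Dominance is judged on peak-normalized activations — raw
unit scales are arbitrary (they are the indeterminacy being corrected), so
comparing them directly can label one unit as "never dominant" purely
because it trained to a small scale.  Because the signed control signal
`c = τ₊a₊ − τ₋a₋` also carries the opposite unit's cross-response, the
base rule alone leaves the realized range of c short of the target; a
refinement stage (`refine_range`, on by default) therefore trims each τ
until the 0.95 quantile of ±c over the respective direction's windows hits
the target range.  This is the automated counterpart of the brief manual
per-subject fine-tuning a clinician would perform.  The coupled fixed
point oscillates under full steps (each τ enters the other direction's
quantile), so updates are under-relaxed (square-root factors, 12
iterations), which converges to well below 1% in the clean-data test.

**Rest threshold.**  Rest is declared when the channel-mean RMS falls below
3× the mean rest-window RMS of the calibration session (5th-percentile
fallback without annotations).  The factor 3 separates rest from active
windows at ≥99% accuracy on synthetic sessions, which is the only property
the controller needs.

## Controllers

**Position mode (AEN).**  Cursor = (c₁, c₂), clamped to the [−1, 1]²
workspace; at rest the cursor returns to the origin immediately (no decay
animation).  The map is memoryless by design.  Both DoFs act at once, so
one step can move diagonally.

**Velocity mode (SOA baseline).**  Two bipolar sites (differences of two
monopolar channels each) drive the active DoF: velocity = gain ×
(RMS − threshold) in the site's direction when above threshold, zero below
(cursor holds).  Threshold subtraction avoids a velocity jump at the
threshold crossing.  Both sites above their individual thresholds without
reaching the co-contraction level is an ambiguous command: the cursor
freezes.  A co-contraction (both sites above a dedicated threshold)
toggles the active DoF and suppresses motion that step; a 0.5 s refractory
period makes one sustained co-contraction produce one switch.  One axis at
most moves per step — the structural limitation position mode removes.

The control update rate equals the feature frame rate (10 Hz, dt = 0.1 s)
for both controllers.

## The task

Targets are circles of radius W = 0.08 (workspace units).  A trial
succeeds when the cursor stays inside for one *continuous* 0.3 s interval
(cumulative time on target does not count) and fails at 20 s.  An
overshoot is an entry whose in-target interval ends, by exit, before the
dwell completes; the terminal successful dwell is not counted, nor is an
interval cut short by the timeout (the cursor did not pass *through*).

Difficulty: ID = log2(A/W + 1) with A = (0.5γ₁ + 0.5γ₂)².  The three
amplitude levels 0.8 / 1.2 / 1.4 give 3.4 / 4.0 / 4.2 bits at one decimal,
truncated toward zero (log2(11) = 3.459→3.4); truncation rounds at the 9th
decimal first so values exact in real arithmetic (log2(16) = 4) are not
pulled down by floating-point error.  The angle-to-workspace mapping
places a target at distance `0.8 · (0.5γ₁ + 0.5γ₂)` from the origin along
the direction given by its signed angle pair; the scale 0.8 keeps every
target (max coordinate ≈ 0.88) inside the workspace with margin.  The
20-target set cycles the three amplitude levels through the four quadrants
(two-DoF targets, with several γ₁:γ₂ splits) and the four axis directions
(single-DoF targets), then shuffles by seed — positions are generated, not
reproduced from any particular laboratory layout.

Metrics: completion rate over all trials; completion time, throughput
(ID/CT, using the exact ID), speed (path length / CT) and path efficiency
averaged over successful trials; overshoots reported both summed and per
trial.  Path efficiency is 100 × straight-line distance (cue position →
target center) / realized path length up to success, capped at 100%: a
trajectory that stops just inside the near rim travels slightly less than
the center distance, and the cap keeps the metric within its stated range.
A two-way repeated-measures ANOVA helper (`rm_anova`) wraps
`statsmodels.stats.anova.AnovaRM` for exploratory method × difficulty
comparisons; it is a convenience only.

## Synthetic data

**Generator.**  Features are `P = H·(C·g) + rest + noise`, clipped at 0,
with `g ≥ 0` the four direction drives (flexion, extension, radial,
ulnar), `H` an R×4 nonnegative mixing matrix with smooth circular tuning
(Gaussian bumps of width 2 channels centered at channels 0/8/4/12 on the
16-channel ring, ±15% seeded gain jitter), and `C` a crosstalk matrix
leaking 5% of each drive uniformly into the others.  Noise has two parts:
the sampling error of an L-sample RMS estimator, std = level/√(2L) with
L = 204 (heteroscedastic — quiet channels are quiet), plus an additive
floor of 0.005 for electronics noise.  Full-range drive is g = 1; rest
level 0.05.

**Calibration session.**  Per DoF, six alternating-direction ramp–hold–ramp
contractions (raised-cosine ramps 2.5 s, hold 5 s, rest gap 5 s), i.e.
15 s per contraction and ≈3 minutes for the full two-DoF session at the
default timing.  Annotations are derived from the generator's own drives
(threshold 0.1 of full range).  A raw-EMG generator (band-limited white
noise amplitude-modulated by the synergy envelope) exercises the
feature-extraction stage.

**Simulated user.**  A practiced subject, modeled in two phases.  Before a
session the user *familiarizes*: probes each DoF in both directions at two
amplitudes and least-squares fits an affine model cursor ≈ G·s + c₀ of the
plant — this stands in for the adaptation human users perform, and it is
what lets the user compensate the cross-DoF coupling of networks trained
on single-DoF data only.  During a reach the user issues a ballistic
feedforward ramp (0.4 s) toward `G⁻¹(target − c₀)` and, after the ramp and
the 0.2 s reaction delay, integrates visual corrections through G⁻¹ at
gain 2 /s.  Commands pass through first-order muscle-activation dynamics
(τ = 0.12 s) with additive motor noise (σ = 0.02) entering before the
dynamics, and saturate at 1.5 (brief efforts above the calibrated
comfortable range are allowed).  For the sequential baseline the same user
relies on vision alone to servo an integrated state: reaction delay 0.3 s,
activation τ = 0.2 s, bang-bang drive with braking to a 0.6-level drive
only within 0.25 of the axis goal, co-contraction to switch DoF with the
two sites imperfectly synchronized (one leads by a frame), and relaxation
to dwell.  The asymmetry is deliberate: position control rides fast
proprioception (the wrist posture is the cursor), velocity control has no
proprioceptive correlate of the integrated cursor position.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: electrode shift, fatigue and other
non-stationarities; motor-unit-level signal structure; subject-to-subject
anatomical variability beyond seeded gain jitter; the cognitive load and
learning curves of real users.  Simulated-user magnitudes (completion
times around 1 s, throughputs around 4 bit/s) are faster than human
performance because the feedforward phase is nearly ideal; the meaningful
comparisons are the orderings between controllers (completion rate,
completion time, throughput, path efficiency), which the closed-loop tests
assert, not the absolute values.

## Problem sizes and determinism

Unit tests run on compressed calibration sessions (0.5 s ramps, 1 s holds,
1 s rests → 180 windows per DoF); recovery and closed-loop acceptance
tests use the full default protocol (900 windows per DoF, 10 restarts, 10
replicates for recovery).  Every stochastic component — generator noise,
restart initializations, user noise, target shuffling — draws from
`numpy.random.Generator` seeds spawned deterministically from one
configured seed, so models, sessions and trial logs reproduce bit-for-bit.

## Known limitations

- Two DoFs only; the calibration contract assumes exactly one DoF active
  per calibration recording.
- The LM objective is nonconvex and the subgradient at 0 is a convention;
  restarts mitigate but do not eliminate bad local minima (the
  min-|correlation| selector, not the SSE, picks the usable network).
- `refine_range` calibrates the range on single-DoF data; during combined
  movements the cross-DoF response of single-DoF-trained networks still
  distorts the map, which the closed loop (real or simulated user)
  compensates.
- The SOA baseline's thresholds and gain come from a simple fitting rule
  on the generator; real prosthesis fitting is iterative and
  subject-specific.
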