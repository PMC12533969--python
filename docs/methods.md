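# Methods

This note documents the generative model behind the synthetic sessions, the
estimators in the analysis stack, the defaults and the reasoning behind them,
and what the package's tests do and do not establish about real recordings.

## Task and coordinate conventions

The workspace is right-handed: X rightward, Y upward, Z toward the subject.
Eight targets sit at the vertices of a cube (default side 70 mm) centered on
the fixation point. Trial timing (defaults, all multiples of the 50 ms
decoding bin): fixation 400 ms, cue 300 ms, planning 400 ms, a variable
delay drawn uniformly in bins up to 600 ms, and a movement period with a
700 ms nominal minimum-jerk reach inside a 1,500 ms timeout. Every trial is
padded to a fixed bin count (the maximum delay); pre-go bins hold the cursor
at the fixation point and post-movement bins hold its final position, so
event indices in the trial table — not array padding — define all epochs.

The visuomotor rotation acts only on the X–Y (fronto-parallel) components
of cursor velocity, counterclockwise positive about +Z; each session is
purely CW or CCW. All analyses fold the rotation sign at alignment time
(the perturbation axis of the shared target frame points toward the applied
rotation), so CW and CCW sessions average coherently.

## Generative model of a session

Each unit fires around a linear (cosine) tuning law per 50 ms bin:

    E[count] = b0 + b · v(t) + c · |v(t)|

with baseline rate `b0` (default uniform 0.5–3 spikes/bin, i.e., 10–60 Hz),
tuning vector `b` with uniformly distributed preferred direction and
modulation 0.003–0.009 spikes/bin per mm/s (≈ ±0.5–1.5 spikes/bin at the
peak speed of ~162 mm/s), and a condition-independent speed sensitivity
`c` (0.002–0.006). The speed term exists because motor-cortical population
activity is dominated by a large movement-locked component shared across
conditions; it also makes the stable, condition-locked manifold genuinely
four-dimensional (three directional dimensions plus one speed dimension),
which is what the top-4-PC analyses assume there is to find. During the
planning period the directional term is scaled by a per-unit planning gain
(0.3–0.7) at a nominal fictive speed of 200 mm/s. Counts add a shared
latent term `L·z(t)` (rank 4, loadings N(0, 0.3²), `z` standard normal per
bin) and private Gaussian noise (sd 0.5 spikes/bin — slightly below the
Poisson sd at these rates), then are rounded to integers and clipped at
zero. Noiseless configurations skip rounding so that regression and
decoding identities are machine-exact; this is what makes the geometric
forcing check an exact identity rather than an approximate one.

**Closed loop.** Controlling units' counts are decoded bin by bin by the
velocity Kalman filter (calibrated on a simulated 40-trial manual-control
block); the cursor velocity is the decoder output, rotated by the
perturbation during rotation trials, and integrated into the cursor path.
Commands are feedforward: the intended velocity follows the minimum-jerk
profile toward the target direction rotated in-plane by the current aim
offset, with no within-trial feedback corrections. This is deliberate: the
midpoint error then measures pure feedforward adaptation, and the
geometric-forcing identity (unadapted command under a 30° rotation yields
exactly a 30° midpoint error) holds by construction.

**Learning.** Adaptation is a single scalar aim angle `a` in the
perturbation plane, updated after each trial from the measured CCW-signed
midpoint error α:

    a ← retention · a − learning_rate · α      (skipped when learning_rate = 0)

Defaults `learning_rate = 0.002`, `retention = 0.9996` give a decay of
≈ −0.0024 per trial with a small residual asymptote, the scale of pooled
exponential fits in this paradigm. With retention 1 the aim converges
monotonically to full compensation. Each unit expresses the shared aim
scaled by its population's `adaptation_gain` (controlling units 1 by
definition of behavior; noncontrolling groups configurable), which makes
relative gains a direct parameter-recovery target. Units may alternatively
be tuned in the *visual* frame (they track the realized, perturbed cursor
velocity, and the unrotated target direction during planning). The three
canonical constructions for the offline readout are: gain 0 (stationary,
H1), visual frame (H2), and motor frame with gain 1 (H3).

Because the latent factors are shared session-wide, latent noise in the
controlling units propagates into the cursor and couples any
latent-carrying population to the command — a realistic effect, but one
that biases the H1 (stationary) construction away from zero. Hypothesis
arbitration and gain-recovery simulations therefore give readout
populations private noise only; the manifold analyses keep the full latent
structure, which is their object of study.

## Analysis stack

**Geometry.** Trajectories are projected onto the X–Y plane first, then
expressed in the (center→target, orthogonal-in-plane) basis; the first
sample is shifted to the origin. The midpoint angle is taken at 50% of
cumulative path length by default (robust to asymmetric speed profiles; a
time-based variant is available since either reading is defensible).
Deflections are read at a fraction of normalized movement *time* by default
(trajectory traces are conventionally plotted against percent of movement),
with a path-length variant by flag. Averages resample each trajectory to
100 points by linear interpolation over normalized time.

**Kalman filter.** State = (vx, vy, vz, 1); the observation matrix absorbs
units (counts/bin vs mm/s); `H, Q` come from per-unit least squares of
counts on (v, 1), `A, W` from least squares of v_t on v_{t−1}. Near-singular
designs get a tiny ridge loading and a loud warning. The filter update is
computed in information form on the 3-D velocity block with the constant
channel pinned analytically; this is algebraically the standard
predict/update cycle (verified against a textbook Joseph-form oracle and
the discrete algebraic Riccati fixed point) and is what makes decoding
10,000-trial sessions cheap. A numerically zero `Q` receives a 1e-9
diagonal floor, which turns the low-noise limit into the exact
pseudo-inverse of the tuning matrix. The initial state is zero velocity
with a broad diagonal covariance (10× process noise); the first two bins
are treated as burn-in in error metrics. Assisted control blends computer
and decoded velocity per bin (`w·computer + (1−w)·decoded`), with blocked
weights decreasing from 0.7 to 0.

**Offline reconstruction.** Decoders are always trained on baseline
activity of the selected population — movement period against realized
cursor velocities, memory period against unit vectors to the cued target —
and applied to rotation trials; baseline evaluation uses leave-one-out so
every baseline trial is analyzable. Memory-period reconstructions are
cumulative sums of decoded vectors and live in arbitrary units. The 8-way
classifier takes the nearest target to the planning endpoint, ties broken
by lowest index and flagged (because the endpoint enters only through its
inner products with a centrally symmetric target set, an untuned population
classifies at exactly 1/8 in expectation). The relative gain is the signed
final angle of the mean aligned reconstruction, as a percentage of the
controlling population's. Only successful trials enter any reconstruction.

**Manifold.** The covariance substrate is per-target trial-averaged
activity, bins concatenated (movement period, or the fixed 400 ms pre-go
planning window), soft-normalized by range + 5 spikes/s and mean-centered.
The alignment index projects one epoch's covariance onto another's top-4
PCs, normalized by the projected epoch's own top-4 variance. The
baseline-vs-late-rotation comparison uses a **matched-sampling design**
(`manifold_preservation`): per split, baseline trials are divided into
target-stratified halves; the cross-validated baseline index projects one
half onto the other's PCs, and the late-rotation index projects a
late-rotation subsample with identical per-target trial counts onto the
same half-baseline PCs. Without this matching the two indices carry
different finite-sample deficits (different trial counts per average) and
their difference reflects sampling noise, ~1% under the default generator,
rather than manifold change; with matching, a preserved manifold yields
differences of ~0.2–0.3% while a genuine reconfiguration (tested by
splicing rotation-phase counts generated under permuted tuning) still
lowers the late-rotation index by well over 5%. Two PC-count conventions
coexist — top-4 (default) and a 90%-variance criterion — since both appear
in practice.

**Statistics.** The adaptation curve is fitted pooled across sessions as
`α(t) = a·exp(b·t)` by multi-start nonlinear least squares; p-values come
from a session-clustered bootstrap (default 2,000 resamples; tests pass
smaller counts explicitly). Deflections are tested per session against zero
with a one-sample t test. Preferred-direction shifts are reported as the
rotation of a unit's target→command mapping: the tuning vector is fitted
per phase against the straight-to-target reference, and since a unit that
re-aims by θ rotates its *fitted* vector by −θ, the shift is the negated
fitted-angle difference, sign-folded by the session's rotation direction
(positive = toward the applied rotation; adaptation appears as negative,
compensatory shifts). Units with near-zero in-plane tuning are excluded and
logged. The decoder contribution of a unit is ‖(b1, b2, b3)‖ + b0.

The planning→movement model is
`movement ~ 1 + planning + planning:trial_number + (1 | animal/session)`
fitted with statsmodels MixedLM (random intercept for animal, variance
component for session nested in animal); when that fit is singular or fails
to converge — common with two animals — it falls back to session
fixed-effects OLS with cluster-robust errors, flagged in the report.
Confidence intervals are t-based on the session-clustered bootstrap SE
(centered on the bootstrapped estimator, df = sessions − 1, with a small
m/(m−1) inflation): percentile intervals undercover badly with few
clusters. Pairwise population slope comparisons use a planning × population
interaction with Bonferroni correction over all pairs.

## Simulation sizes

The package's own validation runs use: experiment-scale sessions (160/300/160
trials, ~100 units) for the manifold analyses; 96 baseline / 160 rotation
trials with ~50–75 units for hypothesis arbitration and gain recovery,
where the effect directions are scale-free; 10,200 trials for the
classifier chance calibration; 30 sessions × 300 trials for
exponential-fit recovery; and 100 replicates of 24 sessions × 100 trials
for the hierarchical-model coverage check. The acceptance script simulates
20 experiment-scale sessions.

## What the synthetic sessions do and do not emulate

They emulate: linear velocity tuning with planning-period direction
signals, shared low-dimensional variability, closed-loop decoding with
assisted-control machinery, the baseline → 30° rotation → washout schedule,
trial-by-trial error-corrective re-association with per-population gains,
and motor- vs visual-frame coding. They do not emulate: spiking point
processes (counts are rounded Gaussians; a Poisson-ish regime is
approached only in rate), within-trial feedback corrections, non-stationary
unit waveforms or drift, eye movements, kinematic variability of real
reaches, or any change of the network's correlation structure during
learning other than the constructed reconfiguration used to test
sensitivity. Passing tests therefore show that the estimators recover the
truth of *this* generative family at realistic noise levels — not that real
cortex adapts this way.

## Known limitations

- Offline decoders trained on realized cursor velocities inherit a small
  session-specific bias from the condition-independent speed component
  (it enters `Q` as structured noise); this mimics real decoder
  miscalibration and is absorbed by the session-level statistics.
- The scalar-aim learner cannot produce target-specific (local) adaptation
  or generalization gradients.
- With only two simulated animals the mixed model usually falls back to
  the fixed-effects estimator; the report flags this.
- Cluster-bootstrap inference is approximate below ~10 sessions.
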