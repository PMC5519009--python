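# Methods

## The task and the model

The package models the classic multiple-object-tracking (MOT) paradigm in two
and three dimensions: six identical objects move continuously, three are cued
as targets, the observer covertly tracks them for 5 s, and a single probed
object must be classified as target or non-target. The scientific question is
how sensory uncertainty and data association limit tracking, and in
particular why adding continuous depth (stereoscopic) information improves
performance more than additively with inter-object spacing.

### Stimulus dynamics

Objects follow a discrete-time damped-spring (Ornstein–Uhlenbeck) process per
axis,

    v_t = λ v_{t−1} − k x_{t−1} + w_t,   w_t ~ N(0, σ_w²)
    x_t = x_{t−1} + v_t

with damping λ = 0.9 and a 60 Hz update. The process is stationary, and the
spring constant and acceleration variance are solved in closed form from the
desired stationary SDs of position (σ_x) and velocity (σ_v):

    k = (1 + λ) σ_v² / (2 σ_x²)
    σ_w² = (λ² − 1) σ_v² (σ_v² − 4 σ_x²) / (4 σ_x²)

These closed forms were cross-validated against the exact discrete Lyapunov
solution of the state-space recursion (agreement to machine precision); the
test suite keeps that cross-check. The solver requires σ_v² < 4 σ_x² — beyond
that no positive process-noise variance exists — and the stationary formulas
require the stable regime k < 2λ + 2.

The experiment design crosses σ_x ∈ {2, 3, 4}° with ten σ_v levels
(0.005–0.2 °/frame, session-specific sets) and {2D, 3D}, i.e. 60 cells in six
sessions; 30 trials per cell plus 6×15 practice trials gives 1890 trials per
subject. Angles convert to meters by the exact tangent at the 1.75 m viewing
distance (this convention reproduces the physical screen's 77.9° horizontal
extent). The depth axis uses the same metric SDs as the frontoparallel axes;
2D trials freeze the depth axis at exactly zero. Each trial holds the objects
stationary for 90 frames (cue phase, zero velocity), then draws fresh
velocities from N(0, σ_v²) and evolves 300 tracking frames.

### Sensory noise

Measurement noise is state dependent. Frontoparallel position noise grows
linearly with eccentricity, σ_px = c(1 + 14|p_x|) (and likewise for y); depth
noise grows with frontoparallel eccentricity and depth offset,
σ_pz = d(1 + 14·√(p_x²+p_y²))(1 + 1.5|p_z|). Velocity noise is Weber-scaled
at 5% of speed in the frontoparallel plane and proportional to the depth
position noise with slope 1.66 (stereomotion). The scales c and d (meters)
are the model's only free parameters. A velocity-noise floor (default
1e-6 m/frame, configurable) keeps measurement covariances invertible at zero
speed; it is far below any behaviorally relevant noise level.

Generative noise SDs are evaluated at the *true* state. The observer cannot
see truth, so its measurement-noise covariance R is evaluated at the measured
values by default (`r_eval="measured"`), with `"predicted"` available as a
config switch. This makes the Kalman filter mildly suboptimal under
state-dependent noise, which is the intended reading of the model.

### Tracking and data association

Each object is tracked by a per-axis Kalman filter on (position, velocity);
process noise enters position and velocity with full correlation (rank-1 Q
per axis) because the same w_t drives both. Because percepts are unlabeled,
each frame the observer scores all 6! = 720 measurement-to-object assignments
by their joint innovation log-likelihood, expands each of the three retained
assignment hypotheses by its three best continuations, and keeps the global
top three by cumulative (unnormalized) log-weight — a pruned K-best
multiple-hypothesis tracker. Hypothesis weights are normalized only at the
probe stage. Duplicate-history merging never triggers in this scheme:
children of distinct parents have distinct histories by construction.

State estimates are initialized from the cue phase: position means are the
average of the 90 stationary position percepts (variance: estimated noise
variance / 90), velocity means are zero with prior variance σ_v² of the
condition. The probe is position-only: a sample from one uniformly chosen
object's true final position, corrupted by position noise, is scored under
each object's hypothesis-averaged position marginal plus measurement noise
(re-estimated at the probe sample); the response is "target" iff the summed
target likelihood is at least the summed non-target likelihood (exact ties —
a measure-zero event except for deliberately symmetric inputs — answer
"target").

Four observer variants: FE (full extrapolation, transition λ = 0.9, correct
dynamics), NE-cd (no extrapolation, transition λ = 0, but k and σ_w² solved
with λ = 0.9), NE-id (transition and dynamics λ = 0), and NV (velocity
removed from state and measurement entirely). In 2D trials the observer still
runs the full 3D model; depth percepts are genuine noise around zero and
carry no discriminative signal.

### Numerical design

The per-trial math is axis-separable (independent per-axis dynamics, diagonal
R), so beliefs are stored as three 2×2 covariance blocks per object and the
whole simulation is vectorized across trials; 2×2 determinants and inverses
are evaluated in closed form, and the Joseph-form update plus explicit
symmetrization keeps covariances PSD. The equivalence of this block engine to
a conventional full-matrix Kalman filter is pinned by a single-object test at
1e-8 absolute tolerance. Assignment scoring uses one dense matrix product
against a precomputed permutation one-hot matrix; ties in
`top_k_assignments` break lexicographically.

### Psychometrics

Per-session accuracy is fit with a cumulative Weibull on the 1/σ_v axis,
p = g + (1 − g − γ)(1 − exp(−(1/(a σ_v))^β)), with g = 0.5 fixed and
γ ∈ [0, 0.2]. Fitting maximizes the binomial log-likelihood over
(log a, log β, logit(γ/0.2)) — the transforms enforce the bounds smoothly —
with multi-start from a log-spaced scale grid crossed with β ∈ {0.5, 1, 2, 4}
and Nelder-Mead polishing of the best starts. Probabilities are clipped to
[1e-9, 1−1e-9] inside the likelihood. A fit that does no better than pure
guessing (flat likelihood in a, e.g. chance-only data) is flagged
non-converged; a lapse estimate pinned to a bound is flagged. The 75%
threshold is the algebraic inverse of the Weibull at p = 0.75; the printed
closed form is treated as normative through the round-trip identity
`invert(weibull(s)) = s`.

### Model fitting and comparison

Noise scales (c, d) are fit per variant by grid search on the binomial
log-likelihood of per-condition correct counts, with the model's proportion
correct per cell obtained by simulation. Grid cells share common random
numbers (one child seed per condition, reused across cells), so the surface
is a deterministic function of (c, d, seed) and its shape — checked by a
local-maximum count diagnostic — reflects parameter sensitivity rather than
simulation jitter. Model proportions are clipped to [1/(2N), 1 − 1/(2N)]
before the likelihood. Variants have equal parameter counts, so comparison
uses raw relative log-likelihood (best variant = 0).

## Synthetic subjects

`synthetic_subject` generates count tables with the data's statistical
structure. Weibull mode draws binomial counts from known per-session
psychometric curves and exists so the fitting stack can be validated in
milliseconds; observer mode runs a tracker variant with known (c, d) and is
the full-fidelity closed loop. The generator reproduces the design's shape
(60 conditions × 30 trials = 1800 experimental trials per subject) but not
human nuisance structure: no session-order effects, no lapses of attention
beyond the Weibull lapse parameter, no learning, no reaction times. Passing
recovery tests therefore demonstrates the estimators are consistent for data
generated by the assumed models, not that human data satisfy those
assumptions.

## Problem sizes used in the test suite

The behavioral-pattern suite runs the NE-cd observer at its best-fitting
scales (c = 0.0082 m, d = 0.0202 m) over the full 60-condition design at 200
trials per condition, then fits
per-session Weibulls and checks: accuracy decreases with σ_v; 75% thresholds
increase with σ_x; 3D thresholds exceed 2D at every σ_x; and the 3D−2D gap
grows with σ_x. Grid-search recovery and variant comparison run on a reduced
16-condition design (σ_x ∈ {2, 4}°, four σ_v levels, both dimensionalities)
with 40–60 trials per condition, a 4×3 grid bracketing the true scales for
recovery, and five seeds for the comparison direction. These sizes are the
package's chosen desk-scale defaults; all are overridable through the public
APIs and CLI.

## Known limitations

- The exact Bayesian observer would mix over all 720 assignments per frame;
  the K = 3 pruned-hypothesis scheme is the modeled approximation, and the
  exact scheme is deliberately out of scope.
- The Kalman filter is suboptimal under state-dependent noise (acknowledged
  above); no iterated/unscented correction is attempted.
- Targets and non-targets are tracked identically; asymmetric tracking is not
  modeled.
- No rendering or display geometry beyond the deg↔m conversion; no human data
  ingestion beyond the count-table CSV schema.
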