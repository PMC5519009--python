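# mot3d — ideal-observer modeling of multiple-object tracking in 2D and 3D

`mot3d` is a research toolkit for studying how sensory uncertainty and the
correspondence (data-association) problem limit our ability to track several
identical moving objects at once, and how continuous depth information helps.
It is aimed at computational-neuroscience and visual-psychophysics work: it
simulates the classic track-3-of-6 MOT task, runs Bayesian observer models on
the stimuli, and provides the psychometric and model-comparison machinery to
analyze either simulated or human count data.

## What it implements

**Stimuli.** Objects move as discrete-time Brownian motion on a damped
virtual spring (an Ornstein–Uhlenbeck process) per axis,

    v_t = λ v_{t−1} − k x_{t−1} + w_t,  w_t ~ N(0, σ_w²),   x_t = x_{t−1} + v_t

with λ = 0.9 at 60 Hz. Difficulty is parameterized by the stationary SDs of
position (σ_x, average spacing) and velocity (σ_v, average speed); `k` and
σ_w² are solved in closed form from (σ_x, σ_v). The full design crosses
σ_x ∈ {2, 3, 4}° × ten σ_v levels × {2D, 3D} = 60 conditions.

**Observer.** Each object is tracked by a Kalman filter under state-dependent
sensory noise (position noise grows with eccentricity; depth noise with
eccentricity and depth offset; velocity noise is Weber-scaled, stereomotion
noise proportional to depth noise). Because percepts are unlabeled, the
observer scores all 6! = 720 measurement-to-object assignments per frame and
carries the three best assignment hypotheses (K-best multiple-hypothesis
tracking). Four variants differ in how velocity enters prediction: FE (full
extrapolation), NE-cd (no extrapolation, correct dynamics), NE-id (no
extrapolation, incorrect dynamics), NV (no velocity at all). Free parameters:
the noise scales c (frontoparallel) and d (depth), in meters.

**Analysis.** Per-session accuracy is fit by binomial maximum likelihood with
a cumulative Weibull on the 1/σ_v axis (guess rate 0.5, lapse ∈ [0, 0.2]);
performance is summarized by the σ_v giving 75% correct. Observer variants
are fit to count data by grid search on the binomial log-likelihood (common
random numbers across the grid) and compared by relative log-likelihood.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate the best-fitting observer (NE-cd, c = 0.0082 m, d = 0.0202 m) on the
closest-spacing session (σ_x = 2°) in 2D and 3D, fit psychometric curves, and
extract 75% thresholds:

```python
import numpy as np
from mot3d import (NoiseParams, TrialCondition, simulate_condition,
                   fit_psychometric, threshold_at)
from mot3d.synthetic_subject import session_data

noise = NoiseParams(c=0.0082, d=0.0202)  # best-fitting observer scales (m)
levels = [0.005, 0.02, 0.035, 0.05, 0.065, 0.08, 0.1, 0.12, 0.156, 0.2]

for session, dims in ((1, "2D"), (4, "3D")):
    results = []
    for i, sv in enumerate(levels):
        cond = TrialCondition(session, 2, sv, dims)
        rng = np.random.default_rng(np.random.SeedSequence([7, session, i]))
        results.append(simulate_condition(cond, "NE-cd", noise, 200, rng))
    data = session_data(results, session)
    fit = fit_psychometric(data)
    th = threshold_at(fit.params)
    print(f"{dims} (sigma_x = 2 deg): accuracy {np.round(data.proportion, 2)}")
    print(f"  Weibull a = {fit.params.a:.1f}/deg/frame, beta = {fit.params.beta:.2f}, "
          f"lapse = {fit.params.gamma_:.3f} -> 75% threshold = {th:.4f} deg/frame")
```

Output:

```
2D (sigma_x = 2 deg): accuracy [0.96 0.82 0.74 0.64 0.55 0.58 0.53 0.55 0.5  0.45]
  Weibull a = 41.4/deg/frame, beta = 1.55, lapse = 0.046 -> 75% threshold = 0.0279 deg/frame
3D (sigma_x = 2 deg): accuracy [0.98 0.94 0.84 0.79 0.69 0.66 0.57 0.55 0.58 0.46]
  Weibull a = 23.8/deg/frame, beta = 1.61, lapse = 0.033 -> 75% threshold = 0.0497 deg/frame
```

Accuracy falls from near-ceiling toward chance (0.5) as average speed grows,
and the 3D threshold (0.050 °/frame) is well above the 2D threshold
(0.028 °/frame): with depth information the observer tolerates nearly twice
the speed at the same 75% criterion, because depth disambiguates
measurement-to-object assignments that overlap in the frontoparallel plane.

## Command line

The `mot3d` console script wraps the same pipeline: `mot3d design`,
`mot3d simulate-stimuli`, `mot3d simulate-observer`, `mot3d make-subject`,
`mot3d fit-psych`, `mot3d fit-model`, and `mot3d compare`. All commands
exchange flat CSV count tables with columns
`(session, sigma_x_deg, sigma_v_deg, dims, n_trials, n_correct)`.

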