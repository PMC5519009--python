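"""Weibull psychometric functions and 75%-correct velocity thresholds.

Accuracy in the tracking task falls from near-ceiling to chance as the
velocity SD grows, so per-session accuracy is summarized by a cumulative
Weibull on the reciprocal stimulus axis 1/sigma_v (which co-varies positively
with performance)::

    p(sigma_v) = g + (1 - g - gamma) * (1 - exp(-(1 / (a sigma_v))^beta))

with guess rate g fixed at 0.5 (two-alternative probe judgment), lapse rate
gamma constrained to [0, 0.2], scale a (frame/deg) and shape beta.  The 75%
threshold is the sigma_v at which the fitted curve crosses 0.75, obtained by
algebraic inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import binom

__all__ = [
    "PsychometricParams",
    "SessionData",
    "PsychometricFit",
    "weibull_p",
    "invert_weibull",
    "threshold_at",
    "fit_psychometric",
]

GAMMA_MAX = 0.2
_P_EPS = 1e-9


@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-Weibull parameters: scale ``a`` (frame/deg), shape ``beta``,
    lapse ``gamma_`` in [0, 0.2] and guess rate ``g`` (fixed at 0.5)."""

    a: float
    beta: float
    gamma_: float = 0.0
    g: float = 0.5

    def __post_init__(self):
        if self.a <= 0 or self.beta <= 0:
            raise ValueError("scale and shape must be positive")
        if not 0 <= self.gamma_ <= GAMMA_MAX:
            raise ValueError(f"lapse rate must lie in [0, {GAMMA_MAX}]")


@dataclass
class SessionData:
    """Per-level response counts for one (sigma_x, dims) session."""

    sigma_v: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self):
        self.sigma_v = np.asarray(self.sigma_v, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if not (self.sigma_v.shape == self.n_trials.shape == self.n_correct.shape):
            raise ValueError("sigma_v, n_trials and n_correct must align")
        if (self.sigma_v <= 0).any():
            raise ValueError("sigma_v levels must be positive")
        if (self.n_correct < 0).any() or (self.n_correct > self.n_trials).any():
            raise ValueError("need 0 <= n_correct <= n_trials")

    @property
    def proportion(self) -> np.ndarray:
        return self.n_correct / self.n_trials


@dataclass
class PsychometricFit:
    params: PsychometricParams
    loglik: float
    converged: bool
    gamma_at_boundary: bool


def weibull_p(sigma_v, params: PsychometricParams):
    """Probability correct at velocity SD ``sigma_v`` (> 0)."""
    sigma_v = np.asarray(sigma_v, dtype=float)
    if (sigma_v <= 0).any():
        raise ValueError("sigma_v must be positive")
    # evaluate (1/(a sv))^beta in log space; overflow saturates at the ceiling
    x = np.exp(np.minimum(-params.beta * np.log(params.a * sigma_v), 700.0))
    p = params.g + (1 - params.g - params.gamma_) * (1 - np.exp(-x))
    return p if p.ndim else float(p)


def invert_weibull(p: float, params: PsychometricParams) -> float:
    """The sigma_v at which the Weibull crosses probability ``p``.

    Algebraic inverse of :func:`weibull_p`; only defined on the open range
    (g, 1 - gamma).
    """
    lo, hi = params.g, 1 - params.gamma_
    if not lo < p < hi:
        raise ValueError(f"p={p} outside the attainable range ({lo}, {hi})")
    frac = (1 - p - params.gamma_) / (1 - params.g - params.gamma_)
    return float(1.0 / (params.a * (-np.log(frac)) ** (1.0 / params.beta)))


def threshold_at(params: PsychometricParams, p: float = 0.75) -> float:
    """Criterion-level velocity threshold (default: 75% correct)."""
    return invert_weibull(p, params)


def _nll(theta, sigma_v, n_trials, n_correct):
    a, beta = np.exp(theta[0]), np.exp(theta[1])
    gamma_ = GAMMA_MAX * expit(theta[2])
    # evaluate (1/(a sv))^beta in log space; overflow saturates harmlessly
    x = np.exp(np.minimum(-beta * np.log(a * sigma_v), 700.0))
    p = 0.5 + (0.5 - gamma_) * (1 - np.exp(-x))
    p = np.clip(p, _P_EPS, 1 - _P_EPS)
    return -(n_correct * np.log(p) + (n_trials - n_correct) * np.log(1 - p)).sum()


def fit_psychometric(data: SessionData, n_starts_kept: int = 4) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the Weibull to one session.

    Optimizes over (log a, log beta, logit(gamma/0.2)) so the bounds are
    enforced smoothly, starting from a log-spaced grid of scales crossed with
    shapes {0.5, 1, 2, 4}; the ``n_starts_kept`` most promising grid points
    are polished with Nelder-Mead.  ``converged`` is False when the optimizer
    fails or the likelihood is flat in the scale (chance-only data);
    ``gamma_at_boundary`` flags a lapse estimate pinned to 0 or 0.2.
    """
    if len(np.unique(data.sigma_v)) < 3:
        raise ValueError("need at least 3 distinct sigma_v levels")
    sv, nt, nc = data.sigma_v, data.n_trials, data.n_correct

    a_grid = 1.0 / np.geomspace(sv.min() / 3, sv.max() * 3, 8)
    starts = [
        np.array([np.log(a0), np.log(b0), logit(0.1)])
        for a0 in a_grid
        for b0 in (0.5, 1.0, 2.0, 4.0)
    ]
    start_nll = np.array([_nll(th, sv, nt, nc) for th in starts])
    order = np.argsort(start_nll)[:n_starts_kept]

    best, best_nll, ok = None, np.inf, False
    for i in order:
        res = minimize(_nll, starts[i], args=(sv, nt, nc), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if res.fun < best_nll:
            best, best_nll, ok = res.x, res.fun, bool(res.success)

    a, beta = float(np.exp(best[0])), float(np.exp(best[1]))
    gamma_ = float(GAMMA_MAX * expit(best[2]))
    params = PsychometricParams(a=a, beta=beta, gamma_=gamma_)

    # a fit no better than pure guessing means the likelihood is flat in a
    guess_nll = _nll(np.array([np.log(1e12), 0.0, logit(0.5)]), sv, nt, nc)
    flat = guess_nll - best_nll < 1e-6
    boundary = gamma_ < 1e-4 or gamma_ > GAMMA_MAX - 1e-4

    loglik = float(binom.logpmf(nc, nt, np.clip(
        weibull_p(sv, params), _P_EPS, 1 - _P_EPS)).sum())
    return PsychometricFit(
        params=params,
        loglik=loglik,
        converged=ok and not flat,
        gamma_at_boundary=boundary,
    )
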