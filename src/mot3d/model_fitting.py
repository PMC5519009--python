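"""Fitting the observer noise scales (c, d) and comparing observer variants.

The behavioral data are per-condition binomial counts, so a parameter pair
(c, d) is scored by the binomial log-likelihood of the observed correct counts
under the model's simulated proportion correct::

    log L = sum_i log B(c_i; N_i, p_i)

over the design cells i.  The likelihood surface is evaluated on a (c, d)
grid with common random numbers across cells, so reruns at a fixed seed
reproduce the surface exactly and the surface shape reflects parameter
sensitivity rather than simulation jitter.  Variants all have the same number
of free parameters, so they are compared directly by relative log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .observer_noise import NoiseParams
from .tracker import ConditionResult, get_variant, simulate_condition

__all__ = [
    "FitResult",
    "binomial_loglik",
    "grid_fit",
    "compare_variants",
    "DEFAULT_C_GRID",
    "DEFAULT_D_GRID",
]

#: Default grids bracket plausible frontoparallel / depth noise scales (m).
DEFAULT_C_GRID = tuple(np.geomspace(0.001, 0.04, 8))
DEFAULT_D_GRID = tuple(np.geomspace(0.005, 0.05, 8))


@dataclass
class FitResult:
    """Grid maximum-likelihood fit of one observer variant.

    ``surface[i, j]`` is the log-likelihood at ``(c_grid[i], d_grid[j])``;
    ``unimodal`` flags whether the evaluated surface has a single local
    maximum (a multi-modal surface suggests the grid is too coarse or the
    simulation too noisy to trust the argmax).
    """

    variant: str
    c: float
    d: float
    loglik: float
    c_grid: np.ndarray
    d_grid: np.ndarray
    surface: np.ndarray
    n_trials_per_condition: int


def binomial_loglik(model_p: Sequence[float], data: Sequence[ConditionResult]) -> float:
    """Binomial log-likelihood of observed counts under model proportions.

    ``model_p`` must hold one probability per data condition, in the same
    order; probabilities are clipped away from {0, 1} upstream.
    """
    model_p = np.asarray(model_p, dtype=float)
    if model_p.shape != (len(data),):
        raise ValueError("need exactly one model probability per condition")
    n = np.array([r.n_trials for r in data])
    c = np.array([r.n_correct for r in data])
    return float(binom.logpmf(c, n, model_p).sum())


def _model_proportions(variant, conditions, noise: NoiseParams, n_trials: int,
                       seed: int, r_eval: str) -> np.ndarray:
    """Simulated proportion correct per condition, clipped to the open interval.

    Each condition gets its own child seed derived from (seed, condition
    index); the same seeds are reused for every (c, d) cell, giving common
    random numbers across the grid.
    """
    p = np.empty(len(conditions))
    for i, cond in enumerate(conditions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        res = simulate_condition(cond, variant, noise, n_trials, rng, r_eval)
        p[i] = res.n_correct / res.n_trials
    return np.clip(p, 0.5 / n_trials, 1 - 0.5 / n_trials)


def _count_local_maxima(surface: np.ndarray) -> int:
    """Strict local maxima under 4-neighbor comparison (edges padded with -inf)."""
    padded = np.pad(surface, 1, constant_values=-np.inf)
    center = padded[1:-1, 1:-1]
    is_max = (
        (center > padded[:-2, 1:-1]) & (center > padded[2:, 1:-1])
        & (center > padded[1:-1, :-2]) & (center > padded[1:-1, 2:])
    )
    return int(is_max.sum())


def grid_fit(variant, data: Sequence[ConditionResult],
             c_grid: Sequence[float] = DEFAULT_C_GRID,
             d_grid: Sequence[float] = DEFAULT_D_GRID,
             n_trials: int = 200, seed: int = 0,
             r_eval: str = "measured",
             noise_overrides: dict | None = None) -> FitResult:
    """Maximize the binomial likelihood of ``data`` over a (c, d) grid.

    For every grid cell the full set of data conditions is re-simulated with
    ``n_trials`` trials per condition and common random numbers, then scored
    against the observed counts.  ``noise_overrides`` passes through any
    non-default sensory constants (Weber fraction etc.).
    """
    variant = get_variant(variant)
    c_grid = np.asarray(c_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if (c_grid <= 0).any() or (d_grid <= 0).any():
        raise ValueError("noise-scale grids must be positive")
    conditions = [r.condition for r in data]
    extra = noise_overrides or {}

    surface = np.empty((c_grid.size, d_grid.size))
    for i, c in enumerate(c_grid):
        for j, d in enumerate(d_grid):
            noise = NoiseParams(c=c, d=d, **extra)
            p = _model_proportions(variant, conditions, noise, n_trials, seed, r_eval)
            surface[i, j] = binomial_loglik(p, data)

    best = np.unravel_index(np.argmax(surface), surface.shape)
    return FitResult(
        variant=variant.name,
        c=float(c_grid[best[0]]),
        d=float(d_grid[best[1]]),
        loglik=float(surface[best]),
        c_grid=c_grid,
        d_grid=d_grid,
        surface=surface,
        n_trials_per_condition=n_trials,
    )


def unimodal(fit: FitResult) -> bool:
    """True when the evaluated likelihood surface has at most one local maximum."""
    return _count_local_maxima(fit.surface) <= 1


def compare_variants(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tabulate fits by log-likelihood relative to the best variant (= 0)."""
    if not fits:
        raise ValueError("need at least one fit")
    lls = np.array([f.loglik for f in fits])
    rel = lls - lls.max()
    df = pd.DataFrame(
        {
            "variant": [f.variant for f in fits],
            "c": [f.c for f in fits],
            "d": [f.d for f in fits],
            "loglik": lls,
            "relative_loglik": rel,
        }
    )
    return df.sort_values("relative_loglik", ascending=False, ignore_index=True)
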