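"""Synthetic behavioral subjects: binomial count tables with known structure.

Two generating modes produce per-condition (n_trials, n_correct) tables with
the same schema as a real subject's data:

* ``weibull`` -- success probabilities come from known per-session Weibull
  psychometric parameters; fast, used to validate psychometric fitting and
  threshold recovery in closed loop.
* ``observer`` -- success probabilities come from actually running a tracker
  variant with known noise scales; the full-fidelity path used to validate
  model fitting and comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import TrialCondition, design_from_frame
from .observer_noise import NoiseParams
from .psychometrics import PsychometricParams, SessionData, weibull_p
from .tracker import ConditionResult, simulate_condition

__all__ = [
    "SubjectSpec",
    "generate_counts",
    "counts_to_frame",
    "counts_from_frame",
    "session_data",
]


@dataclass
class SubjectSpec:
    """How to generate one synthetic subject.

    For ``mode="weibull"`` supply ``weibull_params``: a mapping from session id
    to :class:`PsychometricParams`.  For ``mode="observer"`` supply the
    ``variant`` name and the noise scales ``c`` and ``d`` (meters).
    """

    mode: str
    n_trials: int = 30
    seed: int = 0
    weibull_params: Mapping[int, PsychometricParams] | None = None
    variant: str = "NE-cd"
    c: float = 0.0082
    d: float = 0.0202
    noise_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("weibull", "observer"):
            raise ValueError("mode must be 'weibull' or 'observer'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


def generate_counts(spec: SubjectSpec, design: Sequence[TrialCondition]) -> list[ConditionResult]:
    """Draw one synthetic subject's counts for every condition in the design."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    results = []
    if spec.mode == "weibull":
        params = spec.weibull_params
        missing = {c.session for c in design} - set(params)
        if missing:
            raise ValueError(f"no psychometric parameters for sessions {sorted(missing)}")
        for cond in design:
            p = weibull_p(cond.sigma_v_deg, params[cond.session])
            n_correct = int(rng.binomial(spec.n_trials, p))
            results.append(ConditionResult(cond, spec.n_trials, n_correct))
    else:
        noise = NoiseParams(c=spec.c, d=spec.d, **spec.noise_overrides)
        for i, cond in enumerate(design):
            child = np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + i]))
            results.append(simulate_condition(cond, spec.variant, noise, spec.n_trials, child))
    return results


def counts_to_frame(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """Standard count-table schema: one row per condition."""
    return pd.DataFrame(
        [
            (r.condition.session, r.condition.sigma_x_deg, r.condition.sigma_v_deg,
             r.condition.dims, r.n_trials, r.n_correct)
            for r in results
        ],
        columns=["session", "sigma_x_deg", "sigma_v_deg", "dims", "n_trials", "n_correct"],
    )


def counts_from_frame(df: pd.DataFrame) -> list[ConditionResult]:
    conditions = design_from_frame(df)
    return [
        ConditionResult(cond, int(row.n_trials), int(row.n_correct))
        for cond, row in zip(conditions, df.itertuples(index=False))
    ]


def session_data(results: Sequence[ConditionResult], session: int) -> SessionData:
    """Collect one session's levels into the psychometric-fitting container."""
    rows = [r for r in results if r.condition.session == session]
    if not rows:
        raise ValueError(f"no conditions for session {session}")
    rows.sort(key=lambda r: r.condition.sigma_v_deg)
    return SessionData(
        sigma_v=[r.condition.sigma_v_deg for r in rows],
        n_trials=[r.n_trials for r in rows],
        n_correct=[r.n_correct for r in rows],
    )
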