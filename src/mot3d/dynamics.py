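"""Stimulus dynamics: damped-spring Ornstein-Uhlenbeck motion and experiment design.

Objects move as discrete-time Brownian motion attached to a virtual spring at
the display center::

    v_t = lambda * v_{t-1} - k * x_{t-1} + w_t,   w_t ~ N(0, sigma_w2)
    x_t = x_{t-1} + v_t

independently per axis (horizontal, vertical, depth).  ``lambda`` is a damping
factor (0.9 for the stimuli), ``k`` a spring constant and ``sigma_w2`` the
random-acceleration variance.  The process is stationary with closed-form
position / velocity standard deviations, so (k, sigma_w2) can be solved from a
desired (sigma_x, sigma_v) pair; experimental difficulty is parameterized by
those two SDs.

Units: positions in meters, velocities in meters per frame (60 Hz update), with
condition tables specified in degrees of visual angle at a 1.75 m viewing
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VIEWING_DISTANCE_M",
    "FRAME_RATE_HZ",
    "N_OBJECTS",
    "N_TARGETS",
    "N_STATIONARY_FRAMES",
    "N_TRACKING_FRAMES",
    "LAMBDA_DEFAULT",
    "DynamicsParams",
    "ObjectState",
    "TrialCondition",
    "Trajectory",
    "deg_to_m",
    "m_to_deg",
    "solve_dynamics",
    "stationary_stats",
    "step",
    "sample_initial",
    "generate_trial",
    "build_experiment_design",
    "trials_per_subject",
    "design_to_frame",
    "design_from_frame",
    "trajectory_to_frame",
]

VIEWING_DISTANCE_M = 1.75
FRAME_RATE_HZ = 60.0
N_OBJECTS = 6
N_TARGETS = 3
#: 1.5 s stationary cue phase and 5 s tracking phase at 60 Hz.
N_STATIONARY_FRAMES = 90
N_TRACKING_FRAMES = 300
LAMBDA_DEFAULT = 0.9

Dims = Literal["2D", "3D"]

# sigma_v sets (deg/frame) per sigma_x session, as used in the experiment
_SIGMA_V_SETS = {
    2: (0.005, 0.02, 0.035, 0.05, 0.065, 0.08, 0.1, 0.12, 0.156, 0.2),
    3: (0.005, 0.0267, 0.0483, 0.07, 0.0917, 0.1133, 0.135, 0.1567, 0.1783, 0.2),
    4: (0.005, 0.0267, 0.0483, 0.07, 0.0917, 0.1133, 0.135, 0.1567, 0.1783, 0.2),
}
_SESSION_LAYOUT = (  # (session, sigma_x_deg, dims)
    (1, 2, "2D"),
    (2, 3, "2D"),
    (3, 4, "2D"),
    (4, 2, "3D"),
    (5, 3, "3D"),
    (6, 4, "3D"),
)


def deg_to_m(angle_deg):
    """Convert visual angle (deg) to meters on the display at 1.75 m distance.

    Uses the exact tangent relation ``x = D tan(angle)``; a 2.83 m screen
    width then subtends 2*atan(1.415/1.75) = 77.9 deg, matching the physical
    setup.
    """
    return VIEWING_DISTANCE_M * np.tan(np.radians(angle_deg))


def m_to_deg(x_m):
    """Inverse of :func:`deg_to_m`."""
    return np.degrees(np.arctan(np.asarray(x_m) / VIEWING_DISTANCE_M))


@dataclass(frozen=True)
class DynamicsParams:
    """Per-axis OU-spring parameters together with the stationary SDs they produce.

    Attributes
    ----------
    lambda_ : damping factor per frame, in [0, 1).
    k : spring constant per frame.
    sigma_w2 : random-acceleration variance, m^2/frame^2.
    sigma_x, sigma_v : stationary SDs of position (m) and velocity (m/frame).
    """

    lambda_: float
    k: float
    sigma_w2: float
    sigma_x: float
    sigma_v: float


class ObjectState:
    """Position (m) and velocity (m/frame) of a single object, as 3-vectors.

    Axes are x = horizontal, y = vertical, z = depth, origin at the fixation
    point in the screen center.
    """

    __slots__ = ("position", "velocity")

    def __init__(self, position, velocity):
        self.position = np.asarray(position, dtype=float)
        self.velocity = np.asarray(velocity, dtype=float)
        if self.position.shape != (3,) or self.velocity.shape != (3,):
            raise ValueError("position and velocity must be 3-vectors")
        if not (np.isfinite(self.position).all() and np.isfinite(self.velocity).all()):
            raise ValueError("non-finite object state")


def solve_dynamics(sigma_x: float, sigma_v: float, lambda_: float = LAMBDA_DEFAULT) -> DynamicsParams:
    """Solve for (k, sigma_w2) that make the process stationary at (sigma_x, sigma_v).

    Closed forms::

        k        = (1 + lambda) sigma_v^2 / (2 sigma_x^2)
        sigma_w2 = (lambda^2 - 1) sigma_v^2 (sigma_v^2 - 4 sigma_x^2) / (4 sigma_x^2)

    Raises
    ------
    ValueError
        If inputs are non-positive, ``lambda_`` outside [0, 1), or
        ``sigma_v^2 >= 4 sigma_x^2`` (which would need non-positive process
        noise).
    """
    if sigma_x <= 0 or sigma_v <= 0:
        raise ValueError("sigma_x and sigma_v must be positive")
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda_ must lie in [0, 1)")
    if sigma_v**2 >= 4 * sigma_x**2:
        raise ValueError(
            "sigma_v^2 >= 4 sigma_x^2: no positive process-noise variance exists"
        )
    k = (1 + lambda_) * sigma_v**2 / (2 * sigma_x**2)
    sigma_w2 = (lambda_**2 - 1) * sigma_v**2 * (sigma_v**2 - 4 * sigma_x**2) / (4 * sigma_x**2)
    return DynamicsParams(lambda_=lambda_, k=k, sigma_w2=sigma_w2, sigma_x=sigma_x, sigma_v=sigma_v)


def stationary_stats(k: float, sigma_w2: float, lambda_: float) -> tuple[float, float]:
    """Stationary (sigma_x, sigma_v) of the process for given (k, sigma_w2, lambda).

    Closed forms::

        sigma_x = sqrt((1 + lambda) sigma_w2 / (k (lambda - 1)(k - 2 lambda - 2)))
        sigma_v = sqrt(2 sigma_w2 / ((lambda - 1)(k - 2 lambda - 2)))

    Only valid in the stable regime ``k > 0``, ``0 <= lambda < 1`` and
    ``k < 2 lambda + 2``; raises :class:`ValueError` otherwise.  ``sigma_w2 = 0``
    returns (0, 0).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda_ must lie in [0, 1)")
    if k >= 2 * lambda_ + 2:
        raise ValueError("unstable regime: require k < 2 lambda + 2")
    if sigma_w2 < 0:
        raise ValueError("sigma_w2 must be non-negative")
    denom = (lambda_ - 1) * (k - 2 * lambda_ - 2)  # > 0 in the stable regime
    sigma_x = math.sqrt((1 + lambda_) * sigma_w2 / (k * denom))
    sigma_v = math.sqrt(2 * sigma_w2 / denom)
    return sigma_x, sigma_v


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the design: (sigma_x, sigma_v) in deg and the motion dimensionality."""

    session: int
    sigma_x_deg: float
    sigma_v_deg: float
    dims: Dims

    def __post_init__(self):
        if self.dims not in ("2D", "3D"):
            raise ValueError(f"dims must be '2D' or '3D', got {self.dims!r}")

    @property
    def sigma_x_m(self) -> float:
        return float(deg_to_m(self.sigma_x_deg))

    @property
    def sigma_v_m(self) -> float:
        return float(deg_to_m(self.sigma_v_deg))

    def dynamics(self, lambda_: float = LAMBDA_DEFAULT) -> DynamicsParams:
        """Per-axis dynamics in meters.  The depth axis reuses the same metric SDs."""
        return solve_dynamics(self.sigma_x_m, self.sigma_v_m, lambda_)

    @property
    def key(self) -> tuple:
        return (self.session, self.sigma_x_deg, self.sigma_v_deg, self.dims)


@dataclass
class Trajectory:
    """Ground-truth states for one trial.

    ``positions`` and ``velocities`` have shape (n_frames, n_objects, 3) with
    the stationary cue phase first.  ``target_indices`` are the three cued
    objects.
    """

    positions: np.ndarray
    velocities: np.ndarray
    target_indices: np.ndarray
    condition: TrialCondition
    n_stationary_frames: int = N_STATIONARY_FRAMES
    n_tracking_frames: int = N_TRACKING_FRAMES

    @property
    def n_objects(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def _axis_mask(dims: Dims) -> np.ndarray:
    """1 for axes that carry motion; depth is frozen at zero in 2D trials."""
    return np.array([1.0, 1.0, 0.0]) if dims == "2D" else np.ones(3)


def _step_arrays(pos, vel, params: DynamicsParams, rng, mask):
    """One dynamics step on arrays of shape (..., 3).  Returns (pos, vel)."""
    w = rng.standard_normal(pos.shape) * math.sqrt(params.sigma_w2)
    vel = (params.lambda_ * vel - params.k * pos + w) * mask
    pos = pos + vel
    return pos, vel


def step(state: ObjectState, params: DynamicsParams, rng, dims: Dims = "3D") -> ObjectState:
    """Advance one object by one frame of the damped-spring dynamics."""
    pos, vel = _step_arrays(state.position, state.velocity, params, rng, _axis_mask(dims))
    return ObjectState(pos, vel)


def sample_initial(params: DynamicsParams, dims: Dims, rng) -> ObjectState:
    """Draw position ~ N(0, sigma_x^2), velocity ~ N(0, sigma_v^2) per active axis."""
    mask = _axis_mask(dims)
    pos = rng.standard_normal(3) * params.sigma_x * mask
    vel = rng.standard_normal(3) * params.sigma_v * mask
    return ObjectState(pos, vel)


def _simulate_truth(cond: TrialCondition, n_trials: int, rng,
                    lambda_: float = LAMBDA_DEFAULT):
    """Vectorized ground truth for a batch of trials.

    Returns (positions, velocities, targets) with positions/velocities of
    shape (n_frames, n_trials, N_OBJECTS, 3) and targets (n_trials, N_TARGETS).

    During the cue phase objects sit at their sampled initial positions with
    zero velocity; motion starts at frame ``N_STATIONARY_FRAMES`` with
    velocities freshly drawn from N(0, sigma_v^2).
    """
    params = cond.dynamics(lambda_)
    mask = _axis_mask(cond.dims)
    n_frames = N_STATIONARY_FRAMES + N_TRACKING_FRAMES

    pos = np.empty((n_frames, n_trials, N_OBJECTS, 3))
    vel = np.zeros_like(pos)

    init_pos = rng.standard_normal((n_trials, N_OBJECTS, 3)) * params.sigma_x * mask
    pos[:N_STATIONARY_FRAMES] = init_pos

    p = init_pos.copy()
    v = rng.standard_normal((n_trials, N_OBJECTS, 3)) * params.sigma_v * mask
    for t in range(N_STATIONARY_FRAMES, n_frames):
        p, v = _step_arrays(p, v, params, rng, mask)
        pos[t] = p
        vel[t] = v

    # three cued targets per trial, uniform over the 6!/3!(3!) subsets
    targets = np.argsort(rng.random((n_trials, N_OBJECTS)), axis=1)[:, :N_TARGETS]
    targets.sort(axis=1)
    return pos, vel, targets


def generate_trial(cond: TrialCondition, rng, lambda_: float = LAMBDA_DEFAULT) -> Trajectory:
    """Generate ground truth for one trial: 90 cue frames then 300 tracking frames."""
    pos, vel, targets = _simulate_truth(cond, 1, rng, lambda_)
    return Trajectory(
        positions=pos[:, 0],
        velocities=vel[:, 0],
        target_indices=targets[0],
        condition=cond,
    )


def build_experiment_design() -> list[TrialCondition]:
    """The 60-cell design: {2, 3, 4} deg sigma_x x 10 sigma_v levels x {2D, 3D}."""
    design = []
    for session, sigma_x_deg, dims in _SESSION_LAYOUT:
        for sigma_v_deg in _SIGMA_V_SETS[sigma_x_deg]:
            design.append(TrialCondition(session, sigma_x_deg, sigma_v_deg, dims))
    return design


def trials_per_subject(n_trials_per_condition: int = 30, n_practice_per_session: int = 15) -> int:
    """Total trials one subject runs: 60 conditions x 30 trials + 6 x 15 practice = 1890."""
    n_sessions = len(_SESSION_LAYOUT)
    n_conditions = len(build_experiment_design())
    return n_conditions * n_trials_per_condition + n_sessions * n_practice_per_session


def design_to_frame(design: Sequence[TrialCondition]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.session, c.sigma_x_deg, c.sigma_v_deg, c.dims) for c in design],
        columns=["session", "sigma_x_deg", "sigma_v_deg", "dims"],
    )


def design_from_frame(df: pd.DataFrame) -> list[TrialCondition]:
    return [
        TrialCondition(int(r.session), float(r.sigma_x_deg), float(r.sigma_v_deg), str(r.dims))
        for r in df.itertuples(index=False)
    ]


def trajectory_to_frame(traj: Trajectory, trial: int = 0) -> pd.DataFrame:
    """Long-format export: one row per (frame, object) with positions and velocities."""
    n_frames, n_objects, _ = traj.positions.shape
    frames, objects = np.meshgrid(np.arange(n_frames), np.arange(n_objects), indexing="ij")
    is_target = np.isin(objects, traj.target_indices)
    p = traj.positions.reshape(-1, 3)
    v = traj.velocities.reshape(-1, 3)
    return pd.DataFrame(
        {
            "trial": trial,
            "frame": frames.ravel(),
            "object": objects.ravel(),
            "is_target": is_target.ravel().astype(int),
            "px": p[:, 0], "py": p[:, 1], "pz": p[:, 2],
            "vx": v[:, 0], "vy": v[:, 1], "vz": v[:, 2],
        }
    )
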