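"""State-dependent sensory measurement noise for position and velocity.

Frontoparallel position noise grows linearly with eccentricity; depth
(stereoscopic) position noise grows with frontoparallel eccentricity and with
distance from fixation in depth::

    sigma_px = c (1 + 14 |px|)
    sigma_py = c (1 + 14 |py|)
    sigma_pz = d (1 + 14 sqrt(px^2 + py^2)) (1 + 1.5 |pz|)

with positions in meters relative to fixation and free scale factors ``c``
(frontoparallel) and ``d`` (depth).  Velocity noise uses Weber scaling in the
frontoparallel plane (5% of speed) while stereomotion noise is proportional to
the depth position noise with slope 1.66::

    sigma_vx = 0.05 |vx|,   sigma_vy = 0.05 |vy|,   sigma_vz = 1.66 sigma_pz

A small configurable floor keeps the velocity-noise SD positive at zero speed
so measurement covariances stay invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["NoiseParams", "Measurement", "position_noise_sd", "velocity_noise_sd",
           "measurement_noise_sd", "corrupt"]


@dataclass(frozen=True)
class NoiseParams:
    """Sensory-noise constants.

    Attributes
    ----------
    c : frontoparallel position-noise scale (m).
    d : depth position-noise scale (m).
    weber : velocity Weber fraction (default 0.05).
    stereo_slope : stereomotion-to-stereoacuity slope (default 1.66).
    ecc_slope : eccentricity scaling of position noise, per meter (default 14).
    depth_slope : depth-distance scaling of depth noise, per meter (default 1.5).
    v_floor : minimum velocity-noise SD (m/frame); numerical guard only.
    """

    c: float
    d: float
    weber: float = 0.05
    stereo_slope: float = 1.66
    ecc_slope: float = 14.0
    depth_slope: float = 1.5
    v_floor: float = 1e-6

    def __post_init__(self):
        if self.c <= 0 or self.d <= 0:
            raise ValueError("noise scales c and d must be positive")
        if self.v_floor < 0:
            raise ValueError("v_floor must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseParams":
        return cls(**d)


@dataclass(frozen=True)
class Measurement:
    """A noisy percept of one object: values plus the SDs used to generate them."""

    position: np.ndarray
    velocity: np.ndarray
    position_sd: np.ndarray
    velocity_sd: np.ndarray


def position_noise_sd(pos, params: NoiseParams):
    """Per-axis position-noise SDs (m) at true position ``pos`` (..., 3)."""
    pos = np.asarray(pos, dtype=float)
    sx = params.c * (1 + params.ecc_slope * np.abs(pos[..., 0]))
    sy = params.c * (1 + params.ecc_slope * np.abs(pos[..., 1]))
    ecc = np.hypot(pos[..., 0], pos[..., 1])
    sz = params.d * (1 + params.ecc_slope * ecc) * (1 + params.depth_slope * np.abs(pos[..., 2]))
    return np.stack([sx, sy, sz], axis=-1)


def velocity_noise_sd(vel, sigma_pz, params: NoiseParams):
    """Per-axis velocity-noise SDs (m/frame).

    ``sigma_pz`` is the depth position-noise SD evaluated at the same state;
    the stereomotion SD is ``stereo_slope * sigma_pz``.
    """
    vel = np.asarray(vel, dtype=float)
    sx = np.maximum(params.weber * np.abs(vel[..., 0]), params.v_floor)
    sy = np.maximum(params.weber * np.abs(vel[..., 1]), params.v_floor)
    sz = params.stereo_slope * np.asarray(sigma_pz, dtype=float)
    return np.stack([sx, sy, sz + np.zeros_like(sx)], axis=-1)


def measurement_noise_sd(pos, vel, params: NoiseParams):
    """SDs for the full 6-component percept, ordered (px, py, pz, vx, vy, vz)."""
    psd = position_noise_sd(pos, params)
    vsd = velocity_noise_sd(vel, psd[..., 2], params)
    return np.concatenate([psd, vsd], axis=-1)


def corrupt(state, params: NoiseParams, rng) -> Measurement:
    """Corrupt a true object state with independent Gaussian sensory noise.

    Noise SDs are evaluated at the *true* state (the generative model); an
    observer estimating them can only do so from the measured values.
    """
    psd = position_noise_sd(state.position, params)
    vsd = velocity_noise_sd(state.velocity, psd[..., 2], params)
    pos = state.position + psd * rng.standard_normal(3)
    vel = state.velocity + vsd * rng.standard_normal(3)
    return Measurement(position=pos, velocity=vel, position_sd=psd, velocity_sd=vsd)
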