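"""Ideal-observer tracking core: Kalman filtering with explicit data association.

Each of the six objects is tracked by a per-object Kalman filter over position
and velocity in 3D (position only for the NV variant).  Because measurements
are unlabeled, the observer must also infer which percept belongs to which
object: every frame it scores all 720 permutations of measurement-to-object
assignments by their joint innovation likelihood, expands each retained
assignment hypothesis by its three best continuations, and keeps the global
top three by cumulative log-probability (a pruned K-best multiple-hypothesis
tracker).  At the end of a trial a probe position sample is drawn from one
object and the observer reports "target" if the combined posterior likelihood
of the probe under the three cued objects exceeds that under the uncued ones.

Four observer variants differ in how velocity enters the state transition:

======  =================  ===============  ==============
name    transition lambda  dynamics lambda  velocity state
======  =================  ===============  ==============
FE      0.9                0.9              yes
NE-cd   0                  0.9              yes
NE-id   0                  0                yes
NV      --                 0.9              no
======  =================  ===============  ==============

"transition lambda" is the damping used in the observer's state-transition
matrix (zero removes velocity-based extrapolation); "dynamics lambda" is the
damping used when solving the spring constant and process-noise variance from
the condition's stationary SDs (zero gives an observer with incorrect
dynamics).

The per-trial maths is axis-separable (independent dynamics and diagonal
measurement noise per axis), so beliefs are stored internally as three 2x2
(or 1x1) blocks per object and the whole simulation is vectorized across
trials.  The public operations below expose the conventional full-matrix view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy.special import logsumexp

from .dynamics import (
    N_STATIONARY_FRAMES,
    TrialCondition,
    Trajectory,
    _simulate_truth,
    solve_dynamics,
)
from .observer_noise import NoiseParams, position_noise_sd, velocity_noise_sd

__all__ = [
    "VariantSpec",
    "VARIANTS",
    "GaussianBelief",
    "Hypothesis",
    "MeasurementSet",
    "ProbeOutcome",
    "ConditionResult",
    "build_matrices",
    "predict",
    "kalman_update",
    "assignment_log_likelihood",
    "top_k_assignments",
    "track_trial",
    "probe_decision",
    "simulate_condition",
]

_LOG2PI = math.log(2.0 * math.pi)
K_HYPOTHESES = 3


@dataclass(frozen=True)
class VariantSpec:
    """Observer variant: how damping enters the transition and the dynamics solver."""

    name: str
    transition_lambda: float | None
    dynamics_lambda: float
    has_velocity_state: bool = True


VARIANTS = {
    "FE": VariantSpec("FE", 0.9, 0.9, True),
    "NE-cd": VariantSpec("NE-cd", 0.0, 0.9, True),
    "NE-id": VariantSpec("NE-id", 0.0, 0.0, True),
    "NV": VariantSpec("NV", None, 0.9, False),
}


def get_variant(variant) -> VariantSpec:
    if isinstance(variant, VariantSpec):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")


@dataclass
class GaussianBelief:
    """Gaussian state estimate of one object.

    ``mean`` is (6,) ordered (x, y, z, vx, vy, vz), or (3,) positions for the
    position-only observer.  ``cov`` is the matching covariance matrix.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        m = self.mean.shape[0]
        if self.cov.shape != (m, m):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass
class Hypothesis:
    """One assignment history: a belief per object plus its cumulative log-weight."""

    beliefs: list
    log_weight: float


@dataclass(frozen=True)
class MeasurementSet:
    """Unlabeled percepts for one frame: values and the diagonal noise SDs.

    ``values`` has shape (n_objects, m) with components ordered like the state;
    ``sds`` are the per-component noise SDs.
    """

    values: np.ndarray
    sds: np.ndarray


@dataclass(frozen=True)
class ProbeOutcome:
    probed_object: int
    is_target: bool
    response_target: bool

    @property
    def correct(self) -> bool:
        return self.is_target == self.response_target


@dataclass(frozen=True)
class ConditionResult:
    """Binomial outcome of simulating one design cell."""

    condition: TrialCondition
    n_trials: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


# ---------------------------------------------------------------------------
# state-space construction
# ---------------------------------------------------------------------------

def _axis_matrices(variant: VariantSpec, cond: TrialCondition):
    """Per-axis transition and process-noise blocks (2x2, or 1x1 for NV)."""
    dyn = solve_dynamics(cond.sigma_x_m, cond.sigma_v_m, variant.dynamics_lambda)
    k, sw2 = dyn.k, dyn.sigma_w2
    if variant.has_velocity_state:
        lt = variant.transition_lambda
        A = np.array([[1.0 - k, lt], [-k, lt]])
        Q = sw2 * np.ones((2, 2))  # the same w_t drives position and velocity
    else:
        A = np.array([[1.0 - k]])
        Q = np.array([[sw2]])
    return A, Q


def build_matrices(variant, cond: TrialCondition):
    """Full transition A, process-noise covariance Q and observation map H.

    State ordering is (x, y, z, vx, vy, vz); the NV variant carries positions
    only.  All variants observe every state component, so H is the identity.
    """
    variant = get_variant(variant)
    A_ax, Q_ax = _axis_matrices(variant, cond)
    s = A_ax.shape[0]
    m = 3 * s
    A = np.zeros((m, m))
    Q = np.zeros((m, m))
    for a in range(3):
        idx = [a] if s == 1 else [a, 3 + a]
        A[np.ix_(idx, idx)] = A_ax
        Q[np.ix_(idx, idx)] = Q_ax
    return A, Q, np.eye(m)


# ---------------------------------------------------------------------------
# public full-matrix operations
# ---------------------------------------------------------------------------

def predict(belief: GaussianBelief, A: np.ndarray, Q: np.ndarray) -> GaussianBelief:
    """Kalman time update: mean -> A mean, cov -> A cov A' + Q (symmetrized)."""
    mean = A @ belief.mean
    cov = A @ belief.cov @ A.T + Q
    return GaussianBelief(mean, 0.5 * (cov + cov.T))


def kalman_update(belief: GaussianBelief, z: np.ndarray, r_diag: np.ndarray) -> GaussianBelief:
    """Kalman measurement update with diagonal noise variances ``r_diag``.

    Uses the Joseph-form covariance update for numerical robustness.
    """
    P = belief.cov
    R = np.diag(np.asarray(r_diag, dtype=float))
    S = P + R
    K = np.linalg.solve(S.T, P.T).T
    mean = belief.mean + K @ (np.asarray(z, dtype=float) - belief.mean)
    ImK = np.eye(P.shape[0]) - K
    cov = ImK @ P @ ImK.T + K @ R @ K.T
    return GaussianBelief(mean, 0.5 * (cov + cov.T))


def _mvn_logpdf(diff: np.ndarray, cov: np.ndarray) -> float:
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("innovation covariance is not positive definite") from err
    y = np.linalg.solve(L, diff)
    return -0.5 * (diff.shape[0] * _LOG2PI + (y**2).sum()) - np.log(np.diag(L)).sum()


def assignment_log_likelihood(predicted, measurements: MeasurementSet, r_per_meas) -> np.ndarray:
    """Matrix of innovation log-likelihoods: entry (i, j) scores measurement j
    under predicted belief i.

    ``r_per_meas`` holds the diagonal measurement-noise *variances*, one row
    per measurement.  Raises :class:`ValueError` on a non-positive-definite
    innovation covariance.
    """
    z = np.asarray(measurements.values, dtype=float)
    r = np.asarray(r_per_meas, dtype=float)
    n = len(predicted)
    if z.shape[0] != n or r.shape != z.shape:
        raise ValueError("need one measurement and one noise row per object")
    out = np.empty((n, n))
    for i, belief in enumerate(predicted):
        for j in range(n):
            S = belief.cov + np.diag(r[j])
            out[i, j] = _mvn_logpdf(z[j] - belief.mean, S)
    return out


@lru_cache(maxsize=8)
def _perm_table(n: int):
    """All n! permutations (lexicographic) and the one-hot scoring matrix.

    ``onehot`` maps a flattened n x n log-likelihood matrix to per-permutation
    scores: ``scores = loglik.ravel() @ onehot`` where
    ``onehot[i * n + perm[p, i], p] = 1``.
    """
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    n_perm = perms.shape[0]
    onehot = np.zeros((n * n, n_perm))
    rows = (np.arange(n)[None, :] * n + perms).ravel()
    cols = np.repeat(np.arange(n_perm), n)
    onehot[rows, cols] = 1.0
    return perms, onehot


def top_k_assignments(loglik: np.ndarray, k: int = K_HYPOTHESES):
    """The k highest-scoring measurement-to-object assignments.

    Enumerates all n! permutations of the square score matrix, scoring each as
    the sum of its selected entries; ties are broken by lexicographic
    permutation order.  Returns ``[(permutation, score), ...]`` in descending
    score order, where ``permutation[i]`` is the measurement assigned to
    object i.
    """
    loglik = np.asarray(loglik, dtype=float)
    n = loglik.shape[0]
    if loglik.shape != (n, n):
        raise ValueError("log-likelihood matrix must be square")
    perms, _ = _perm_table(n)
    scores = loglik[np.arange(n)[None, :], perms].sum(axis=1)
    order = np.argsort(-scores, kind="stable")[:k]
    return [(tuple(int(v) for v in perms[o]), float(scores[o])) for o in order]


# ---------------------------------------------------------------------------
# batched block engine
# ---------------------------------------------------------------------------

def _block_loglik(e0, e1, p00, p01, p11, r0, r1):
    """Log-density of a 2D innovation with covariance P + diag(r), elementwise."""
    a = p00 + r0
    c = p11 + r1
    det = a * c - p01 * p01
    quad = (e0 * e0 * c - 2.0 * e0 * e1 * p01 + e1 * e1 * a) / det
    return -0.5 * (2.0 * _LOG2PI + np.log(det) + quad)


def _block_update(means, covs, z, r):
    """Vectorized per-axis Kalman update.

    means (..., s), covs (..., s, s), z (..., s), r (..., s) diagonal noise
    variances.  Joseph-form covariance update; returns (means, covs).
    """
    s = means.shape[-1]
    e = z - means
    if s == 1:
        S = covs[..., 0, 0] + r[..., 0]
        K = covs[..., 0, 0] / S
        means = means + (K * e[..., 0])[..., None]
        ImK = 1.0 - K
        newP = ImK * ImK * covs[..., 0, 0] + K * K * r[..., 0]
        return means, newP[..., None, None]
    p00, p01, p11 = covs[..., 0, 0], covs[..., 0, 1], covs[..., 1, 1]
    r0, r1 = r[..., 0], r[..., 1]
    a = p00 + r0
    c = p11 + r1
    det = a * c - p01 * p01
    # K = P S^-1 with S = P + diag(r)
    k00 = (p00 * c - p01 * p01) / det
    k01 = (p01 * a - p00 * p01) / det
    k10 = (p01 * c - p11 * p01) / det
    k11 = (p11 * a - p01 * p01) / det
    e0, e1 = e[..., 0], e[..., 1]
    m0 = means[..., 0] + k00 * e0 + k01 * e1
    m1 = means[..., 1] + k10 * e0 + k11 * e1
    # Joseph form: (I-K) P (I-K)' + K diag(r) K'
    i00, i01, i10, i11 = 1.0 - k00, -k01, -k10, 1.0 - k11
    q00 = i00 * (i00 * p00 + i01 * p01) + i01 * (i00 * p01 + i01 * p11)
    q01 = i10 * (i00 * p00 + i01 * p01) + i11 * (i00 * p01 + i01 * p11)
    q11 = i10 * (i10 * p00 + i11 * p01) + i11 * (i10 * p01 + i11 * p11)
    q00 = q00 + k00 * k00 * r0 + k01 * k01 * r1
    q01 = q01 + k10 * k00 * r0 + k11 * k01 * r1
    q11 = q11 + k10 * k10 * r0 + k11 * k11 * r1
    means = np.stack([m0, m1], axis=-1)
    covs = np.stack(
        [np.stack([q00, q01], axis=-1), np.stack([q01, q11], axis=-1)], axis=-2
    )
    return means, covs


def _measure_batch(pos_t, vel_t, noise: NoiseParams, rng, has_vel: bool):
    """Draw one frame of percepts from truth, in block layout (T, N, 3, s).

    Per-axis components are ordered (position, velocity); the generative noise
    SDs are evaluated at the true state.
    """
    psd = position_noise_sd(pos_t, noise)
    zp = pos_t + psd * rng.standard_normal(pos_t.shape)
    if has_vel:
        vsd = velocity_noise_sd(vel_t, psd[..., 2], noise)
        zv = vel_t + vsd * rng.standard_normal(vel_t.shape)
        z = np.stack([zp, zv], axis=-1)
    else:
        z = zp[..., None]
    return z


def _noise_var_blocks(z, noise: NoiseParams, has_vel: bool):
    """Measurement-noise variances evaluated at measured (or predicted) values."""
    zp = z[..., 0]
    psd = position_noise_sd(zp, noise)
    if has_vel:
        vsd = velocity_noise_sd(z[..., 1], psd[..., 2], noise)
        return np.stack([psd**2, vsd**2], axis=-1)
    return (psd**2)[..., None]


def _track_batch(pos, vel, cond: TrialCondition, variant: VariantSpec,
                 noise: NoiseParams, rng, r_eval: str = "measured",
                 k_hyp: int = K_HYPOTHESES, n_stationary: int = N_STATIONARY_FRAMES):
    """Run the observer on a batch of trials.

    pos, vel: ground truth of shape (n_frames, T, N, 3).
    Returns (means, covs, logw) with means (T, k_hyp, N, 3, s),
    covs (T, k_hyp, N, 3, s, s) and cumulative unnormalized log-weights
    logw (T, k_hyp).
    """
    if r_eval not in ("measured", "predicted"):
        raise ValueError("r_eval must be 'measured' or 'predicted'")
    variant = get_variant(variant)
    has_vel = variant.has_velocity_state
    s = 2 if has_vel else 1
    n_frames, T, N, _ = pos.shape
    A_ax, Q_ax = _axis_matrices(variant, cond)

    # --- initialization from the stationary cue phase (positions only) ---
    stat_pos = pos[0]                                   # (T, N, 3), constant over cue
    sd_true = position_noise_sd(stat_pos, noise)
    avg_meas = stat_pos + sd_true / math.sqrt(n_stationary) * rng.standard_normal(stat_pos.shape)
    sd_est = position_noise_sd(avg_meas, noise)
    pos_var = sd_est**2 / n_stationary

    means = np.zeros((T, k_hyp, N, 3, s))
    covs = np.zeros((T, k_hyp, N, 3, s, s))
    means[..., 0] = avg_meas[:, None]
    covs[..., 0, 0] = pos_var[:, None]
    if has_vel:
        covs[..., 1, 1] = cond.sigma_v_m**2  # diffuse velocity prior at motion onset
    logw = np.full((T, k_hyp), -np.inf)
    logw[:, 0] = 0.0  # a single live hypothesis until the first expansion

    perms, onehot = _perm_table(N)
    t_idx = np.arange(T)[:, None]
    t_idx2 = np.arange(T)[:, None, None]

    for t in range(n_stationary, n_frames):
        # one shared set of percepts per frame (all hypotheses see the same input)
        z = _measure_batch(pos[t], vel[t], noise, rng, has_vel)   # (T, N, 3, s)

        # predict every belief in every hypothesis
        means = np.einsum("ab,thnxb->thnxa", A_ax, means)
        covs = np.einsum("ab,thnxbc,dc->thnxad", A_ax, covs, A_ax) + Q_ax

        if r_eval == "measured":
            r = _noise_var_blocks(z, noise, has_vel)              # (T, N, 3, s)
            r_bi = r[:, None, None]                               # broadcast over (h, i)
        else:  # evaluated at each hypothesis' predicted state
            r_pred = _noise_var_blocks(means, noise, has_vel)     # (T, H, N, 3, s)
            r_bi = r_pred[:, :, :, None]                          # broadcast over j

        # innovation log-likelihood matrix, summed over axes -> (T, H, N_obj, N_meas)
        e = z[:, None, None] - means[:, :, :, None]               # (T, H, N, N, 3, s)
        if s == 2:
            ll = _block_loglik(
                e[..., 0], e[..., 1],
                covs[:, :, :, None, :, 0, 0], covs[:, :, :, None, :, 0, 1],
                covs[:, :, :, None, :, 1, 1],
                r_bi[..., 0], r_bi[..., 1],
            ).sum(axis=-1)
        else:
            var = covs[:, :, :, None, :, 0, 0] + r_bi[..., 0]
            ll = (-0.5 * (_LOG2PI + np.log(var) + e[..., 0] ** 2 / var)).sum(axis=-1)

        # K-best expansion: each hypothesis proposes its k_hyp best assignments,
        # then the global k_hyp best children survive
        scores = (ll.reshape(T * k_hyp, N * N) @ onehot).reshape(T, k_hyp, -1)
        child = logw[:, :, None] + scores
        k_exp = min(k_hyp, scores.shape[2])  # a parent cannot expand beyond n! children
        top = np.argpartition(-child, k_exp - 1, axis=2)[:, :, :k_exp]   # (T, H, k_exp)
        cand = np.take_along_axis(child, top, axis=2).reshape(T, -1)     # (T, H*k_exp)
        sel = np.argpartition(-cand, k_hyp - 1, axis=1)[:, :k_hyp]       # (T, k)
        logw = np.take_along_axis(cand, sel, axis=1)
        parent = sel // k_exp
        perm_idx = np.take_along_axis(top.reshape(T, -1), sel, axis=1)   # (T, k)

        means = means[t_idx, parent]                                     # (T, k, N, 3, s)
        covs = covs[t_idx, parent]
        assign = perms[perm_idx]                                         # (T, k, N)
        z_a = z[t_idx2, assign]                                          # (T, k, N, 3, s)
        if r_eval == "measured":
            r_a = r[t_idx2, assign]
        else:
            r_a = r_pred[t_idx, parent]
        means, covs = _block_update(means, covs, z_a, r_a)

    return means, covs, logw


def _probe_object_logliks(means, covs, logw, z_probe, r_probe):
    """Hypothesis-averaged log-likelihood of a probe position sample per object.

    means (T, H, N, 3, s), covs matching, z_probe (T, 3), r_probe (T, 3)
    position noise variances.  Returns (T, N).
    """
    pm = means[..., 0]                       # position components (T, H, N, 3)
    pv = covs[..., 0, 0]                     # per-axis position variance
    e = z_probe[:, None, None, :] - pm
    var = pv + r_probe[:, None, None, :]
    ll = (-0.5 * (_LOG2PI + np.log(var) + e**2 / var)).sum(axis=-1)   # (T, H, N)
    w = logw - logsumexp(logw, axis=1, keepdims=True)
    return logsumexp(w[:, :, None] + ll, axis=1)


def _probe_batch(pos_final, targets, means, covs, logw, noise: NoiseParams, rng):
    """Probe decisions for a batch; returns (probe_idx, is_target, response, correct)."""
    T, N = pos_final.shape[:2]
    probe = rng.integers(N, size=T)
    tr = np.arange(T)
    p_true = pos_final[tr, probe]                          # (T, 3)
    psd = position_noise_sd(p_true, noise)
    z_probe = p_true + psd * rng.standard_normal(p_true.shape)
    r_probe = position_noise_sd(z_probe, noise) ** 2       # noise re-estimated at the sample
    obj_ll = _probe_object_logliks(means, covs, logw, z_probe, r_probe)

    tmask = np.zeros((T, N), dtype=bool)
    tmask[tr[:, None], targets] = True
    lt = logsumexp(obj_ll, axis=1, b=tmask)
    ln = logsumexp(obj_ll, axis=1, b=~tmask)
    response = lt >= ln                                    # ties answered "target"
    is_target = tmask[tr, probe]
    return probe, is_target, response, response == is_target


def _blocks_to_full(mean_b, cov_b, has_vel: bool) -> GaussianBelief:
    """Assemble the (x, y, z, vx, vy, vz)-ordered belief from per-axis blocks."""
    if not has_vel:
        return GaussianBelief(mean_b[:, 0], np.diag(cov_b[:, 0, 0]))
    mean = np.concatenate([mean_b[:, 0], mean_b[:, 1]])
    cov = np.zeros((6, 6))
    for a in range(3):
        cov[a, a] = cov_b[a, 0, 0]
        cov[a, 3 + a] = cov[3 + a, a] = cov_b[a, 0, 1]
        cov[3 + a, 3 + a] = cov_b[a, 1, 1]
    return GaussianBelief(mean, cov)


def track_trial(traj: Trajectory, variant, noise: NoiseParams, rng,
                r_eval: str = "measured") -> list[Hypothesis]:
    """Track one trial; returns the final retained hypotheses (best first)."""
    variant = get_variant(variant)
    pos = traj.positions[:, None]
    vel = traj.velocities[:, None]
    means, covs, logw = _track_batch(
        pos, vel, traj.condition, variant, noise, rng, r_eval,
        n_stationary=traj.n_stationary_frames,
    )
    order = np.argsort(-logw[0])
    hyps = []
    for h in order:
        beliefs = [
            _blocks_to_full(means[0, h, i], covs[0, h, i], variant.has_velocity_state)
            for i in range(traj.n_objects)
        ]
        hyps.append(Hypothesis(beliefs=beliefs, log_weight=float(logw[0, h])))
    return hyps


def probe_decision(hyps: list, traj: Trajectory, noise: NoiseParams, rng) -> ProbeOutcome:
    """Draw a probe from one object's true final position and classify it.

    The probe likelihood per object is the hypothesis-weighted density of the
    corrupted probe sample under that object's position marginal plus
    measurement noise; the response is "target" iff the summed likelihood of
    the cued objects is at least that of the uncued ones.
    """
    n = traj.n_objects
    has_vel = hyps[0].beliefs[0].mean.shape[0] == 6
    means = np.stack([
        np.stack([b.mean.reshape(2, 3).T if has_vel else b.mean[:, None] for b in h.beliefs])
        for h in hyps
    ])[None]                                                  # (1, H, N, 3, s)
    covs = np.zeros(means.shape + (means.shape[-1],))
    for hi, h in enumerate(hyps):
        for oi, b in enumerate(h.beliefs):
            for a in range(3):
                if has_vel:
                    covs[0, hi, oi, a] = [
                        [b.cov[a, a], b.cov[a, 3 + a]],
                        [b.cov[3 + a, a], b.cov[3 + a, 3 + a]],
                    ]
                else:
                    covs[0, hi, oi, a, 0, 0] = b.cov[a, a]
    logw = np.array([[h.log_weight for h in hyps]])
    probe, is_target, response, _ = _probe_batch(
        traj.positions[-1][None], traj.target_indices[None], means, covs, logw, noise, rng
    )
    return ProbeOutcome(
        probed_object=int(probe[0]),
        is_target=bool(is_target[0]),
        response_target=bool(response[0]),
    )


def simulate_condition(cond: TrialCondition, variant, noise: NoiseParams,
                       n_trials: int, rng, r_eval: str = "measured") -> ConditionResult:
    """Simulate ``n_trials`` full trials of one design cell and count correct probes.

    Trials are generated, tracked and probed in a single vectorized batch;
    statistically this is the per-trial pipeline generate -> track -> probe.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    variant = get_variant(variant)
    pos, vel, targets = _simulate_truth(cond, n_trials, rng)
    means, covs, logw = _track_batch(pos, vel, cond, variant, noise, rng, r_eval)
    _, _, _, correct = _probe_batch(pos[-1], targets, means, covs, logw, noise, rng)
    return ConditionResult(condition=cond, n_trials=n_trials, n_correct=int(correct.sum()))
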