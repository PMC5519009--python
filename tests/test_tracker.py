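"""Tests of the Kalman + data-association observer core."""

import math
from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from mot3d import (
    GaussianBelief,
    Hypothesis,
    MeasurementSet,
    NoiseParams,
    TrialCondition,
    VariantSpec,
    assignment_log_likelihood,
    build_matrices,
    predict,
    probe_decision,
    simulate_condition,
    top_k_assignments,
    track_trial,
)
from mot3d.dynamics import Trajectory, _simulate_truth, solve_dynamics
from mot3d.tracker import get_variant


def _single_object_trajectory(cond, seed):
    pos, vel, _ = _simulate_truth(cond, 1, np.random.default_rng(seed))
    return Trajectory(
        positions=pos[:, 0, :1],
        velocities=vel[:, 0, :1],
        target_indices=np.array([0]),
        condition=cond,
    )


class TestBuildMatrices:
    def test_constant_velocity_limit(self):
        # transition damping 1 and a vanishing spring give pure inertial motion
        variant = VariantSpec("limit", transition_lambda=1.0, dynamics_lambda=0.9)
        cond = TrialCondition(1, 4, 1e-4, "3D")  # k ~ 1e-9
        A, _, _ = build_matrices(variant, cond)
        expected = np.block([[np.eye(3), np.eye(3)], [np.zeros((3, 3)), np.eye(3)]])
        np.testing.assert_allclose(A, expected, atol=1e-8)

    def test_no_extrapolation_predicts_spring_velocity(self):
        # NE-cd ignores the velocity estimate: predicted velocity is -k x
        cond = TrialCondition(1, 2, 0.1, "3D")
        A, Q, _ = build_matrices("NE-cd", cond)
        k = solve_dynamics(cond.sigma_x_m, cond.sigma_v_m, 0.9).k
        mean = np.array([0.1, -0.2, 0.05, 1.0, 2.0, -3.0])  # wild velocity estimate
        belief = predict(GaussianBelief(mean, np.eye(6) * 1e-4), A, Q)
        np.testing.assert_allclose(belief.mean[3:], -k * mean[:3], rtol=1e-12)

    def test_process_noise_rank_one_per_axis(self):
        _, Q, _ = build_matrices("FE", TrialCondition(1, 2, 0.1, "3D"))
        for a in range(3):
            block = Q[np.ix_([a, 3 + a], [a, 3 + a])]
            assert np.linalg.matrix_rank(block, tol=1e-15) == 1

    def test_nv_is_position_only(self):
        A, Q, H = build_matrices("NV", TrialCondition(1, 2, 0.1, "3D"))
        assert A.shape == (3, 3) and Q.shape == (3, 3) and H.shape == (3, 3)
        dyn = solve_dynamics(
            TrialCondition(1, 2, 0.1, "3D").sigma_x_m,
            TrialCondition(1, 2, 0.1, "3D").sigma_v_m, 0.9)
        np.testing.assert_allclose(A, (1 - dyn.k) * np.eye(3))


class TestPredict:
    def test_identity_dynamics_no_noise(self):
        b = GaussianBelief(np.arange(6.0), np.diag(np.arange(1.0, 7.0)))
        out = predict(b, np.eye(6), np.zeros((6, 6)))
        np.testing.assert_allclose(out.mean, b.mean)
        np.testing.assert_allclose(out.cov, b.cov)

    def test_matches_monte_carlo_pushforward(self, rng):
        m = 4
        A = rng.standard_normal((m, m)) * 0.5
        L = rng.standard_normal((m, m)) * 0.3
        P0 = L @ L.T + 0.5 * np.eye(m)
        Lq = rng.standard_normal((m, m)) * 0.2
        Q = Lq @ Lq.T + 0.1 * np.eye(m)
        mean0 = rng.standard_normal(m)
        out = predict(GaussianBelief(mean0, P0), A, Q)
        n = 200_000
        x = rng.multivariate_normal(mean0, P0, size=n) @ A.T
        x += rng.multivariate_normal(np.zeros(m), Q, size=n)
        np.testing.assert_allclose(out.mean, x.mean(axis=0), atol=0.02)
        np.testing.assert_allclose(out.cov, np.cov(x.T), rtol=0.03, atol=0.02)

    def test_uncertainty_grows_with_process_noise(self):
        b = GaussianBelief(np.zeros(6), np.eye(6))
        out = predict(b, np.eye(6), 0.3 * np.eye(6))
        assert np.trace(out.cov) > np.trace(b.cov)


class TestAssignmentLogLikelihood:
    def _random_problem(self, rng, n=6, m=6):
        beliefs = []
        for _ in range(n):
            L = rng.standard_normal((m, m)) * 0.3
            beliefs.append(GaussianBelief(rng.standard_normal(m), L @ L.T + 0.2 * np.eye(m)))
        z = rng.standard_normal((n, m))
        r = rng.uniform(0.05, 0.4, size=(n, m))
        return beliefs, MeasurementSet(values=z, sds=np.sqrt(r)), r

    def test_matches_multivariate_normal_oracle(self, rng):
        beliefs, meas, r = self._random_problem(rng)
        out = assignment_log_likelihood(beliefs, meas, r)
        for i, b in enumerate(beliefs):
            for j in range(6):
                ref = multivariate_normal(b.mean, b.cov + np.diag(r[j])).logpdf(meas.values[j])
                assert out[i, j] == pytest.approx(ref, rel=1e-10)

    def test_measurement_permutation_equivariance(self, rng):
        beliefs, meas, r = self._random_problem(rng)
        base = assignment_log_likelihood(beliefs, meas, r)
        perm = np.array([3, 1, 4, 0, 5, 2])
        permuted = assignment_log_likelihood(
            beliefs, MeasurementSet(meas.values[perm], meas.sds[perm]), r[perm]
        )
        np.testing.assert_allclose(permuted, base[:, perm])

    def test_separation_limit_dominates_diagonal(self):
        beliefs = [
            GaussianBelief(np.array([0.0, 0, 0, 0, 0, 0]), 1e-4 * np.eye(6)),
            GaussianBelief(np.array([1.0, 0, 0, 0, 0, 0]), 1e-4 * np.eye(6)),
        ]
        z = np.array([[0.0, 0, 0, 0, 0, 0], [1.0, 0, 0, 0, 0, 0]])
        r = np.full((2, 6), 1e-4)
        out = assignment_log_likelihood(beliefs, MeasurementSet(z, np.sqrt(r)), r)
        assert out[0, 0] - out[0, 1] > 10
        assert out[1, 1] - out[1, 0] > 10

    def test_rejects_non_psd_innovation(self):
        bad = GaussianBelief(np.zeros(2), np.array([[1.0, 0.0], [0.0, 1.0]]))
        bad.cov = np.array([[-1.0, 0.0], [0.0, -1.0]])  # bypass constructor check
        meas = MeasurementSet(np.zeros((1, 2)), np.full((1, 2), 0.1))
        with pytest.raises(ValueError, match="positive definite"):
            assignment_log_likelihood([bad], meas, np.full((1, 2), 1e-8))


class TestTopKAssignments:
    def test_enumerates_all_720_permutations(self, rng):
        out = top_k_assignments(rng.standard_normal((6, 6)), k=10_000)
        assert len(out) == 720
        scores = [s for _, s in out]
        assert scores == sorted(scores, reverse=True)

    def test_identity_dominant_matrix(self):
        loglik = np.full((6, 6), -50.0) + 40 * np.eye(6)
        (perm, _), *_ = top_k_assignments(loglik)
        assert perm == (0, 1, 2, 3, 4, 5)

    def test_agrees_with_plain_python_enumeration(self, rng):
        loglik = rng.standard_normal((5, 5))
        expected = sorted(
            ((p, sum(loglik[i, p[i]] for i in range(5))) for p in permutations(range(5))),
            key=lambda t: (-t[1], t[0]),
        )[:3]
        out = top_k_assignments(loglik, k=3)
        for (perm, score), (eperm, escore) in zip(out, expected):
            assert perm == eperm
            assert score == pytest.approx(escore, rel=1e-12)

    def test_top1_matches_hungarian_oracle(self, rng):
        for _ in range(50):
            loglik = rng.standard_normal((6, 6))
            (perm, score), *_ = top_k_assignments(loglik, k=1)
            rows, cols = linear_sum_assignment(loglik, maximize=True)
            assert score == pytest.approx(loglik[rows, cols].sum(), rel=1e-12)

    def test_tie_break_is_lexicographic(self):
        out = top_k_assignments(np.zeros((3, 3)), k=6)
        assert [p for p, _ in out] == sorted(permutations(range(3)))


class TestTrackTrial:
    def test_single_object_fe_matches_reference_kalman(self, best_noise):
        """With one object there is no association problem: the engine must
        reduce to a textbook Kalman filter run on the same percept sequence.

        The reference implementation below is full-matrix and self-contained;
        it replays the engine's percepts by drawing from an identically seeded
        generator (initialization average first, then per frame position and
        velocity noise).
        """
        cond = TrialCondition(1, 2, 0.05, "3D")
        traj = _single_object_trajectory(cond, seed=7)
        hyps = track_trial(traj, "FE", best_noise, np.random.default_rng(99))

        c, d, weber, vfloor = best_noise.c, best_noise.d, best_noise.weber, best_noise.v_floor

        def psd(p):
            ecc = math.hypot(p[0], p[1])
            return np.array([
                c * (1 + 14 * abs(p[0])),
                c * (1 + 14 * abs(p[1])),
                d * (1 + 14 * ecc) * (1 + 1.5 * abs(p[2])),
            ])

        def vsd(v, spz):
            return np.array([
                max(weber * abs(v[0]), vfloor),
                max(weber * abs(v[1]), vfloor),
                1.66 * spz,
            ])

        dyn = solve_dynamics(cond.sigma_x_m, cond.sigma_v_m, 0.9)
        A = np.zeros((6, 6))
        Q = np.zeros((6, 6))
        for a in range(3):
            A[np.ix_([a, 3 + a], [a, 3 + a])] = [[1 - dyn.k, 0.9], [-dyn.k, 0.9]]
            Q[np.ix_([a, 3 + a], [a, 3 + a])] = dyn.sigma_w2
        r = np.random.default_rng(99)

        p0 = traj.positions[0, 0]
        avg = p0 + psd(p0) / math.sqrt(90) * r.standard_normal((1, 1, 3))[0, 0]
        mean = np.concatenate([avg, np.zeros(3)])
        P = np.diag(np.concatenate([psd(avg) ** 2 / 90, np.full(3, cond.sigma_v_m**2)]))

        for t in range(90, traj.n_frames):
            pt, vt = traj.positions[t, 0], traj.velocities[t, 0]
            sp = psd(pt)
            zp = pt + sp * r.standard_normal((1, 1, 3))[0, 0]
            zv = vt + vsd(vt, sp[2]) * r.standard_normal((1, 1, 3))[0, 0]
            spm = psd(zp)
            R = np.diag(np.concatenate([spm**2, vsd(zv, spm[2]) ** 2]))
            mean = A @ mean
            P = A @ P @ A.T + Q
            S = P + R
            K = P @ np.linalg.inv(S)
            mean = mean + K @ (np.concatenate([zp, zv]) - mean)
            P = (np.eye(6) - K) @ P

        best = hyps[0].beliefs[0]
        np.testing.assert_allclose(best.mean, mean, rtol=0, atol=1e-8)
        np.testing.assert_allclose(best.cov, P, rtol=0, atol=1e-8)

    def test_noiseless_limit_tracks_truth(self, rng):
        tiny = NoiseParams(c=1e-7, d=1e-7, weber=1e-7, v_floor=1e-10)
        cond = TrialCondition(1, 2, 0.1, "3D")
        pos, vel, targets = _simulate_truth(cond, 1, rng)
        traj = Trajectory(pos[:, 0], vel[:, 0], targets[0], cond)
        hyps = track_trial(traj, "FE", tiny, rng)
        for i, belief in enumerate(hyps[0].beliefs):
            np.testing.assert_allclose(belief.mean[:3], traj.positions[-1, i], atol=1e-5)
        # with unambiguous percepts the correct history dominates: the runner-up
        # hypotheses (K-best retention always keeps distinct histories) carry
        # negligible posterior weight
        assert hyps[0].log_weight - hyps[1].log_weight > 50

    def test_noiseless_probe_accuracy_is_perfect(self):
        tiny = NoiseParams(c=1e-7, d=1e-7, weber=1e-7, v_floor=1e-10)
        cond = TrialCondition(1, 3, 0.1, "3D")
        res = simulate_condition(cond, "NE-cd", tiny, 50, np.random.default_rng(3))
        assert res.n_correct == 50


class TestProbeDecision:
    def _identical_hypotheses(self, n=6):
        belief = GaussianBelief(np.zeros(6), np.diag([0.01] * 3 + [1e-4] * 3))
        return [Hypothesis([GaussianBelief(belief.mean.copy(), belief.cov.copy())
                            for _ in range(n)], 0.0)]

    def _flat_trajectory(self, cond):
        n_frames = 390
        pos = np.zeros((n_frames, 6, 3))
        vel = np.zeros_like(pos)
        return Trajectory(pos, vel, np.array([0, 1, 2]), cond)

    def test_indistinguishable_beliefs_answer_target(self, best_noise):
        # perfectly symmetric beliefs tie, and ties are resolved as "target"
        traj = self._flat_trajectory(TrialCondition(1, 2, 0.05, "3D"))
        out = probe_decision(self._identical_hypotheses(), traj, best_noise, np.random.default_rng(5))
        assert out.response_target

    def test_invariant_to_common_log_weight_shift(self, best_noise):
        cond = TrialCondition(1, 2, 0.1, "3D")
        pos, vel, targets = _simulate_truth(cond, 1, np.random.default_rng(11))
        traj = Trajectory(pos[:, 0], vel[:, 0], targets[0], cond)
        hyps = track_trial(traj, "NE-cd", best_noise, np.random.default_rng(12))
        out1 = probe_decision(hyps, traj, best_noise, np.random.default_rng(77))
        shifted = [Hypothesis(h.beliefs, h.log_weight + 12345.0) for h in hyps]
        out2 = probe_decision(shifted, traj, best_noise, np.random.default_rng(77))
        assert out1 == out2


class TestSimulateCondition:
    def test_rejects_zero_trials(self, best_noise):
        with pytest.raises(ValueError):
            simulate_condition(TrialCondition(1, 2, 0.05, "2D"), "FE", best_noise, 0,
                               np.random.default_rng(0))

    def test_result_bookkeeping(self, best_noise):
        cond = TrialCondition(1, 2, 0.05, "2D")
        res = simulate_condition(cond, "NV", best_noise, 20, np.random.default_rng(1))
        assert res.n_trials == 20
        assert 0 <= res.n_correct <= 20
        assert res.condition == cond

    def test_r_eval_modes_both_run(self, best_noise):
        cond = TrialCondition(1, 2, 0.05, "3D")
        for mode in ("measured", "predicted"):
            res = simulate_condition(cond, "NE-cd", best_noise, 20,
                                     np.random.default_rng(2), r_eval=mode)
            assert res.n_correct > 5  # a slow condition is comfortably above chance

    def test_unknown_variant_rejected(self, best_noise):
        with pytest.raises(ValueError, match="unknown variant"):
            get_variant("nope")
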