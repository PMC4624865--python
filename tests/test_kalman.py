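"""Gaussian fusion, the filter recursion, and the Wiener baseline."""

import numpy as np
import pytest

from emg2pen import (
    GaussianBelief,
    InvalidInputError,
    KFModel,
    ObservationSequence,
    fuse_gaussians,
    kalman_gain,
    kf_decode,
    kf_predict,
    kf_update,
    wiener_decode,
)


def _random_pd(rng, d, scale=1.0):
    M = rng.standard_normal((d, d))
    return scale * (M @ M.T + d * np.eye(d))


def _fuse_information_form(b1, b2):
    """Independent oracle: explicit inverse-sum-of-inverses formulas."""
    S1i, S2i = np.linalg.inv(b1.cov), np.linalg.inv(b2.cov)
    cov = np.linalg.inv(S1i + S2i)
    mean = cov @ (S1i @ b1.mean + S2i @ b2.mean)
    return mean, cov


class TestFusion:
    def test_scalar_closed_form(self):
        # product of N(0,1) and N(2,1) is N(1, 0.5)
        fused = fuse_gaussians(
            GaussianBelief([0.0], [[1.0]]), GaussianBelief([2.0], [[1.0]])
        )
        assert fused.mean[0] == pytest.approx(1.0)
        assert fused.cov[0, 0] == pytest.approx(0.5)

    def test_uninformative_source_is_ignored(self, rng):
        b1 = GaussianBelief(rng.standard_normal(4), _random_pd(rng, 4))
        b2 = GaussianBelief(rng.standard_normal(4), 1e9 * np.eye(4))
        fused = fuse_gaussians(b1, b2)
        np.testing.assert_allclose(fused.mean, b1.mean, atol=1e-6)
        np.testing.assert_allclose(fused.cov, b1.cov, rtol=1e-3)

    def test_self_fusion_halves_covariance(self, rng):
        b = GaussianBelief(rng.standard_normal(3), _random_pd(rng, 3))
        fused = fuse_gaussians(b, b)
        np.testing.assert_allclose(fused.mean, b.mean, atol=1e-10)
        np.testing.assert_allclose(fused.cov, 0.5 * b.cov, atol=1e-10)

    def test_gain_form_matches_information_form(self, rng):
        for _ in range(100):
            d = int(rng.integers(1, 13))
            b1 = GaussianBelief(rng.standard_normal(d), _random_pd(rng, d))
            b2 = GaussianBelief(rng.standard_normal(d), _random_pd(rng, d))
            fused = fuse_gaussians(b1, b2)
            mean, cov = _fuse_information_form(b1, b2)
            np.testing.assert_allclose(fused.mean, mean, atol=1e-8)
            np.testing.assert_allclose(fused.cov, cov, atol=1e-8)

    def test_order_invariance(self, rng):
        b1 = GaussianBelief(rng.standard_normal(5), _random_pd(rng, 5))
        b2 = GaussianBelief(rng.standard_normal(5), _random_pd(rng, 5))
        f12, f21 = fuse_gaussians(b1, b2), fuse_gaussians(b2, b1)
        np.testing.assert_allclose(f12.mean, f21.mean, atol=1e-8)
        np.testing.assert_allclose(f12.cov, f21.cov, atol=1e-8)

    def test_fused_covariance_dominated_by_both_sources(self, rng):
        b1 = GaussianBelief(np.zeros(6), _random_pd(rng, 6))
        b2 = GaussianBelief(np.zeros(6), _random_pd(rng, 6))
        fused = fuse_gaussians(b1, b2)
        for src in (b1, b2):
            assert np.min(np.linalg.eigvalsh(src.cov - fused.cov)) >= -1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            fuse_gaussians(
                GaussianBelief([0.0], [[1.0]]), GaussianBelief([0.0, 1.0], np.eye(2))
            )


class TestGain:
    def test_perfect_measurement_gain_is_identity(self, rng):
        P = _random_pd(rng, 4)
        np.testing.assert_allclose(kalman_gain(P, np.zeros((4, 4))), np.eye(4),
                                   atol=1e-10)

    def test_equal_covariances_give_half_identity(self, rng):
        P = _random_pd(rng, 5)
        np.testing.assert_allclose(kalman_gain(P, P), 0.5 * np.eye(5), atol=1e-10)

    def test_matches_explicit_inverse_oracle(self, rng):
        P, R = _random_pd(rng, 6), _random_pd(rng, 6)
        K = kalman_gain(P, R)
        np.testing.assert_allclose(K, P @ np.linalg.inv(P + R), atol=1e-10)
        eig = np.linalg.eigvals(K)
        assert np.all(eig.real >= -1e-10) and np.all(eig.real <= 1 + 1e-10)


class TestPredictUpdate:
    def test_identity_dynamics_no_noise_is_fixed_point(self, rng):
        b = GaussianBelief(rng.standard_normal(3), _random_pd(rng, 3))
        out = kf_predict(b, np.eye(3), np.zeros((3, 3)))
        np.testing.assert_allclose(out.mean, b.mean)
        np.testing.assert_allclose(out.cov, b.cov)

    def test_zero_dynamics_resets_to_process_noise(self, rng):
        Q = _random_pd(rng, 3)
        out = kf_predict(
            GaussianBelief(rng.standard_normal(3), _random_pd(rng, 3)),
            np.zeros((3, 3)), Q,
        )
        np.testing.assert_allclose(out.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.cov, Q)

    def test_scalar_prediction_by_hand(self):
        # a=0.5, p=1, q=0.1: var -> 0.25*1 + 0.1 = 0.35
        out = kf_predict(GaussianBelief([2.0], [[1.0]]), [[0.5]], [[0.1]])
        assert out.mean[0] == pytest.approx(1.0)
        assert out.cov[0, 0] == pytest.approx(0.35)

    def test_infinite_measurement_noise_keeps_prior(self, rng):
        prior = GaussianBelief(rng.standard_normal(2), np.eye(2))
        post = kf_update(prior, rng.standard_normal(2), np.eye(2), 1e12 * np.eye(2))
        np.testing.assert_allclose(post.mean, prior.mean, atol=1e-9)

    def test_zero_measurement_noise_trusts_measurement(self, rng):
        H = rng.standard_normal((2, 4))
        z = rng.standard_normal(4)
        post = kf_update(
            GaussianBelief(np.zeros(2), np.eye(2)), z, H, np.zeros((2, 2))
        )
        np.testing.assert_allclose(post.mean, H @ z, atol=1e-12)

    def test_update_equals_fusion_of_prior_and_measurement_belief(self, rng):
        prior = GaussianBelief(rng.standard_normal(4), _random_pd(rng, 4))
        H = rng.standard_normal((4, 8))
        R = _random_pd(rng, 4)
        z = rng.standard_normal(8)
        upd = kf_update(prior, z, H, R)
        fused = fuse_gaussians(prior, GaussianBelief(H @ z, R))
        np.testing.assert_allclose(upd.mean, fused.mean, atol=1e-8)
        np.testing.assert_allclose(upd.cov, fused.cov, atol=1e-8)

    def test_scalar_two_step_recursion_by_hand(self):
        # a=1, q=1, h=1, r=1, z=(1,2), s0=0, P0=1:
        #  t1: prior (0, 2), K = 2/3, post (2/3, 2/3)
        #  t2: prior (2/3, 5/3), K = 5/8, post (3/2, 5/8)
        model = _scalar_model(a=1.0, q=1.0, h=1.0, r=1.0)
        obs = ObservationSequence(np.array([[1.0], [2.0]]), L=1)
        trace = kf_decode(model, obs, s0=[0.0], P0=[[1.0]], store_cov=True,
                          store_gain=True)
        assert trace.means[0, 0] == pytest.approx(2 / 3, abs=1e-12)
        assert trace.covs[0, 0, 0] == pytest.approx(2 / 3, abs=1e-12)
        assert trace.gains[1, 0, 0] == pytest.approx(5 / 8, abs=1e-12)
        assert trace.means[1, 0] == pytest.approx(1.5, abs=1e-12)
        assert trace.covs[1, 0, 0] == pytest.approx(0.625, abs=1e-12)


def _scalar_model(a, q, h, r):
    return KFModel(
        A=np.array([[a]]), Q=np.array([[q]]), H=np.array([[h]]),
        R=np.array([[r]]), K=1, L=1, n_channels=1,
    )


def _random_model(rng, d=6, c=16):
    A = rng.standard_normal((d, d))
    A *= 0.85 / max(abs(np.linalg.eigvals(A)))
    M = rng.standard_normal((d, d))
    Q = 0.05 * (M @ M.T + d * np.eye(d)) / d
    H = rng.standard_normal((d, c))
    M = rng.standard_normal((d, d))
    R = 0.5 * (M @ M.T + d * np.eye(d)) / d
    return KFModel(A=A, Q=Q, H=H, R=R, K=1, L=2, n_channels=8)


class TestDecode:
    def test_large_process_noise_limit_is_wiener(self, rng):
        model = _random_model(rng)
        obs = ObservationSequence(rng.standard_normal((100, 16)), L=2)
        inflated = KFModel(
            A=model.A, Q=1e12 * np.eye(6), H=model.H, R=model.R,
            K=1, L=2, n_channels=8,
        )
        kf = kf_decode(inflated, obs)
        wf = wiener_decode(model, obs)
        rel = np.abs(kf.means - wf.means) / (np.abs(wf.means) + 1e-9)
        assert np.max(rel) < 1e-4

    def test_large_measurement_noise_limit_is_ar_rollout(self, rng):
        model = _random_model(rng)
        obs = ObservationSequence(rng.standard_normal((50, 16)), L=2)
        inflated = KFModel(
            A=model.A, Q=model.Q, H=model.H, R=1e12 * np.eye(6),
            K=1, L=2, n_channels=8,
        )
        s0 = rng.standard_normal(6)
        kf = kf_decode(inflated, obs, s0=s0)
        rollout = np.empty((50, 6))
        x = s0
        for t in range(50):
            x = model.A @ x
            rollout[t] = x
        np.testing.assert_allclose(kf.means, rollout, atol=1e-4)

    def test_causality_truncation_bit_exact(self, rng):
        model = _random_model(rng)
        Z = rng.standard_normal((80, 16))
        full = kf_decode(model, ObservationSequence(Z, L=2))
        part = kf_decode(model, ObservationSequence(Z[:30], L=2))
        np.testing.assert_array_equal(full.means[:30], part.means)

    def test_posterior_contraction_every_step(self, rng):
        model = _random_model(rng)
        obs = ObservationSequence(rng.standard_normal((60, 16)), L=2)
        trace = kf_decode(model, obs, store_gain=True)
        for t in range(60):
            shrink = trace.gains[t] @ trace.prior_covs[t]
            assert np.min(np.linalg.eigvalsh(0.5 * (shrink + shrink.T))) >= -1e-9

    def test_wiener_identity_map_returns_envelope(self, rng):
        Z = rng.random((30, 6))
        model = KFModel(
            A=np.eye(6), Q=np.eye(6), H=np.eye(6), R=np.eye(6),
            K=1, L=1, n_channels=6,
        )
        wf = wiener_decode(model, ObservationSequence(Z, L=1))
        np.testing.assert_array_equal(wf.means, Z)

    def test_wiener_zero_observations_zero_output(self, rng):
        model = _random_model(rng)
        wf = wiener_decode(model, ObservationSequence(np.zeros((20, 16)), L=2))
        np.testing.assert_array_equal(wf.means, 0.0)

    def test_kf_mse_never_worse_than_wiener_on_model_data(self, rng):
        # On data simulated exactly from the linear-Gaussian model the KF
        # posterior mean is the optimal causal estimate, so its MSE cannot
        # exceed the static regression's (averaged over seeded trials).
        kf_err, wf_err = [], []
        for trial in range(30):
            model = _random_model(rng, d=6, c=16)
            n = 120
            states = np.empty((n, 6))
            Lq = np.linalg.cholesky(model.Q)
            Lr = np.linalg.cholesky(model.R)
            x = np.zeros(6)
            Z = np.empty((n, 16))
            Hp = np.linalg.pinv(model.H)
            for t in range(n):
                x = model.A @ x + Lq @ rng.standard_normal(6)
                states[t] = x
                # observation consistent with the inverse model:
                # H z = s + noise  =>  z = H^+ (s + w)
                Z[t] = Hp @ (x + Lr @ rng.standard_normal(6))
            obs = ObservationSequence(Z, L=2)
            kf = kf_decode(model, obs)
            wf = wiener_decode(model, obs)
            kf_err.append(np.mean((kf.means - states) ** 2))
            wf_err.append(np.mean((wf.means - states) ** 2))
        assert np.mean(kf_err) <= np.mean(wf_err)
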