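"""Gaussian-process regressor: kernel values, marginal likelihood and
posterior against dense closed-form oracles, ARD recovery, and the
uncertainty behaviour the model exists for."""

import numpy as np
import pytest

import toxgp as tg
from toxgp.exceptions import FitError, ValidationError
from toxgp.gp_model import GaussianProcessRegressorARD, KernelParams


# --------------------------------------------------------------------------
# independent dense oracle (naive matrix inversion, no Cholesky reuse)
# --------------------------------------------------------------------------
def brute_kernel(Xa, Xb, ls, sf):
    K = np.empty((len(Xa), len(Xb)))
    for i, a in enumerate(Xa):
        for j, b in enumerate(Xb):
            K[i, j] = sf**2 * np.exp(-0.5 * np.sum((a - b) ** 2 / ls**2))
    return K


def brute_posterior(X, y, Xs, ls, sf, sn):
    K = brute_kernel(X, X, ls, sf) + sn**2 * np.eye(len(X))
    Ks = brute_kernel(X, Xs, ls, sf)
    Kss = brute_kernel(Xs, Xs, ls, sf) + sn**2 * np.eye(len(Xs))
    Kinv = np.linalg.inv(K)
    mean = Ks.T @ Kinv @ y
    cov = Kss - Ks.T @ Kinv @ Ks
    return mean, np.sqrt(np.diag(cov))


def brute_lml(X, y, ls, sf, sn):
    K = brute_kernel(X, X, ls, sf) + sn**2 * np.eye(len(X))
    n = len(y)
    return float(
        -0.5 * y @ np.linalg.inv(K) @ y
        - 0.5 * np.log(np.linalg.det(K))
        - 0.5 * n * np.log(2 * np.pi)
    )


class TestKernel:
    def test_same_point_gives_signal_variance(self):
        p = KernelParams(length_scales=np.array([1.5]), signal_sd=2.0, noise_sd=0.3)
        x = np.array([0.4, -1.0])
        assert tg.kernel_eval(x, x, p) == pytest.approx(4.0)

    def test_hand_computed_value(self):
        # x_i=(0,0), x_j=(2,0), l=2, sf=1 -> exp(-0.5 * 4/4) = exp(-0.5)
        p = KernelParams(length_scales=np.array([2.0, 2.0]), signal_sd=1.0,
                         noise_sd=0.1)
        val = tg.kernel_eval(np.array([0.0, 0.0]), np.array([2.0, 0.0]), p)
        assert val == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_symmetry(self, rng):
        p = KernelParams(length_scales=rng.uniform(0.5, 2, 3), signal_sd=1.3,
                         noise_sd=0.1)
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        assert tg.kernel_eval(a, b, p) == pytest.approx(tg.kernel_eval(b, a, p))

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValidationError):
            KernelParams(length_scales=np.array([-1.0]), signal_sd=1.0, noise_sd=0.1)
        with pytest.raises(ValidationError):
            KernelParams(length_scales=np.array([1.0]), signal_sd=0.0, noise_sd=0.1)


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        # K = sf^2 + sn^2 = 2, y = 0: lml = -0.5 log 2 - 0.5 log 2pi
        p = KernelParams(length_scales=np.array([1.0]), signal_sd=1.0, noise_sd=1.0)
        lml = tg.log_marginal_likelihood(p, np.array([[0.0]]), np.array([0.0]))
        assert lml == pytest.approx(-0.5 * np.log(2) - 0.5 * np.log(2 * np.pi))

    def test_matches_brute_force(self, rng):
        X = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        ls = rng.uniform(0.5, 2.0, 3)
        p = KernelParams(length_scales=ls, signal_sd=1.4, noise_sd=0.6)
        assert tg.log_marginal_likelihood(p, X, y) == pytest.approx(
            brute_lml(X, y, ls, 1.4, 0.6), abs=1e-8
        )

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        p = KernelParams(length_scales=np.array([1.0, 2.0]), signal_sd=1.0,
                         noise_sd=0.4)
        perm = rng.permutation(8)
        assert tg.log_marginal_likelihood(p, X, y) == pytest.approx(
            tg.log_marginal_likelihood(p, X[perm], y[perm]), abs=1e-9
        )

    def test_duplicate_training_point_stays_finite(self, rng):
        # exact duplicate with tiny noise exercises the jitter path
        X = np.vstack([rng.standard_normal((4, 2)), np.zeros((2, 2))])
        y = np.concatenate([rng.standard_normal(4), [1.0, 1.0]])
        p = KernelParams(length_scales=np.array([1.0, 1.0]), signal_sd=1.0,
                         noise_sd=1e-9)
        assert np.isfinite(tg.log_marginal_likelihood(p, X, y))


class TestPosterior:
    def test_matches_brute_force_mean_and_sd(self, rng):
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        Xs = rng.standard_normal((2, 2))
        ls = np.array([0.8, 1.7])
        p = KernelParams(length_scales=ls, signal_sd=1.2, noise_sd=0.5)
        model = GaussianProcessRegressorARD.with_params(X, y, p)
        means, sds = model.predict(Xs, return_std=True)
        bm, bs = brute_posterior(X, y - y.mean(), Xs, ls, 1.2, 0.5)
        np.testing.assert_allclose(means, bm + y.mean(), atol=1e-8)
        np.testing.assert_allclose(sds, bs, atol=1e-8)

    def test_matches_sklearn_reference(self, rng):
        # independent library cross-check with pinned hyperparameters
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        ls, sf, sn = np.array([1.1, 0.7, 2.0]), 1.5, 0.4
        p = KernelParams(length_scales=ls, signal_sd=sf, noise_sd=sn)
        model = GaussianProcessRegressorARD.with_params(X, y, p)
        Xs = rng.standard_normal((4, 3))
        means, sds = model.predict(Xs, return_std=True)

        kernel = ConstantKernel(sf**2, "fixed") * RBF(ls, "fixed")
        ref = GaussianProcessRegressor(kernel=kernel, alpha=sn**2,
                                       optimizer=None).fit(X, y - y.mean())
        ref_mean, ref_sd_latent = ref.predict(Xs, return_std=True)
        np.testing.assert_allclose(means, ref_mean + y.mean(), atol=1e-8)
        # sklearn's sd is latent; ours adds the noise variance
        np.testing.assert_allclose(
            sds, np.sqrt(ref_sd_latent**2 + sn**2), atol=1e-8
        )

    def test_interpolates_training_points_at_tiny_noise(self, rng):
        X = rng.standard_normal((7, 2))
        y = rng.standard_normal(7)
        p = KernelParams(length_scales=np.array([1.0, 1.0]), signal_sd=1.0,
                         noise_sd=1e-6)
        model = GaussianProcessRegressorARD.with_params(X, y, p)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-4)

    def test_posterior_sd_bounded_by_prior(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        p = KernelParams(length_scales=np.array([1.0, 1.0]), signal_sd=1.3,
                         noise_sd=0.5)
        model = GaussianProcessRegressorARD.with_params(X, y, p)
        _, sds = model.predict(rng.standard_normal((50, 2)), return_std=True)
        prior_sd = np.sqrt(1.3**2 + 0.5**2)
        assert (sds <= prior_sd + 1e-8).all()

    def test_width_mismatch_rejected(self, rng):
        model = tg.fit_gp(rng.standard_normal((6, 3)), rng.standard_normal(6),
                          ard=False, n_restarts=1)
        with pytest.raises(ValidationError):
            model.predict(rng.standard_normal((2, 4)))


class TestFit:
    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((20, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        m1 = tg.fit_gp(X, y, ard=True, n_restarts=3, seed=5)
        m2 = tg.fit_gp(X, y, ard=True, n_restarts=3, seed=5)
        np.testing.assert_array_equal(
            m1.kernel_params_.length_scales, m2.kernel_params_.length_scales
        )
        assert m1.kernel_params_.noise_sd == m2.kernel_params_.noise_sd

    def test_constant_targets_give_constant_predictions(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.full(12, 17.0)
        model = tg.fit_gp(X, y, ard=False, n_restarts=1)
        means, sds = model.predict(rng.standard_normal((5, 3)), return_std=True)
        np.testing.assert_allclose(means, 17.0, atol=1e-6)
        assert np.isfinite(sds).all()

    def test_target_centering_restores_offset(self, rng):
        X = rng.standard_normal((25, 2))
        y = 30.0 + X[:, 0]
        model = tg.fit_gp(X, y, ard=False, n_restarts=2)
        assert model.y_train_mean_ == pytest.approx(30.0, abs=1.0)
        preds = model.predict(X)
        assert preds.mean() == pytest.approx(30.0, abs=0.5)

    def test_unfitted_model_raises(self):
        with pytest.raises(FitError):
            GaussianProcessRegressorARD().predict(np.zeros((1, 2)))

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((15, 3))
        y = X[:, 1] + 0.1 * rng.standard_normal(15)
        model = tg.fit_gp(X, y, ard=True, n_restarts=2, seed=1)
        path = tmp_path / "gp.json"
        model.save(path)
        back = GaussianProcessRegressorARD.load(path)
        Xs = rng.standard_normal((4, 3))
        np.testing.assert_allclose(back.predict(Xs), model.predict(Xs), atol=1e-10)


class TestARD:
    def test_informative_feature_gets_shortest_scale(self):
        # one informative feature among noise dims: recovered as the
        # shortest length scale in at least 18 of 20 seeds
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed + 100)
            X = r.standard_normal((60, 6))
            y = np.sin(2.0 * X[:, 2]) + 0.01 * r.standard_normal(60)
            model = tg.fit_gp(X, y, ard=True, n_restarts=3, seed=seed)
            wins += model.length_scale_ranking()[0][0] == 2
        assert wins >= 18

    def test_ranking_requires_ard(self, rng):
        model = tg.fit_gp(rng.standard_normal((10, 3)), rng.standard_normal(10),
                          ard=False, n_restarts=1)
        with pytest.raises(ValidationError):
            model.length_scale_ranking()

    def test_ranking_ascending_with_index_ties(self):
        p = KernelParams(length_scales=np.array([2.0, 1.0, 2.0]), signal_sd=1.0,
                         noise_sd=0.1)
        r = np.random.default_rng(0)
        model = GaussianProcessRegressorARD.with_params(
            r.standard_normal((5, 3)), r.standard_normal(5), p
        )
        assert [d for d, _ in model.length_scale_ranking()] == [1, 0, 2]

    def test_ranking_invariant_to_row_permutation(self, rng):
        X = rng.standard_normal((30, 4))
        y = X[:, 1] ** 2 + 0.05 * rng.standard_normal(30)
        perm = rng.permutation(30)
        m1 = tg.fit_gp(X, y, ard=True, n_restarts=2, seed=3)
        m2 = tg.fit_gp(X[perm], y[perm], ard=True, n_restarts=2, seed=3)
        assert [d for d, _ in m1.length_scale_ranking()] == [
            d for d, _ in m2.length_scale_ranking()
        ]
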