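"""GPR engine: kernel values, evidence, predictions vs dense linear-algebra
oracles and an independent library implementation, CV mechanics."""

import numpy as np
import pytest

from chimetraits import gpr
from chimetraits.gpr import GPRHyperparams


def brute_force_predict(X, y, hp, xstar, center=True):
    """Independent oracle: dense inverse, no Cholesky, no caching."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    y_mean = y.mean() if center else 0.0
    K = np.array([[gpr.se_kernel(a, b, hp) for b in X] for a in X])
    Kinv = np.linalg.inv(K + hp.sigma_n2 * np.eye(len(y)))
    kstar = np.array([gpr.se_kernel(xstar, b, hp) for b in X])
    mean = y_mean + kstar @ Kinv @ (y - y_mean)
    cstar = hp.sigma_s2 + hp.sigma_n2
    var = cstar - kstar @ Kinv @ kstar
    return float(mean), float(var)


def brute_force_lml(X, y, hp, center=True):
    y = np.asarray(y, float)
    yc = y - y.mean() if center else y
    K = np.array([[gpr.se_kernel(a, b, hp) for b in X] for a in X])
    Ky = K + hp.sigma_n2 * np.eye(len(y))
    sign, logdet = np.linalg.slogdet(Ky)
    assert sign > 0
    return float(
        -0.5 * yc @ np.linalg.inv(Ky) @ yc - 0.5 * logdet
        - 0.5 * len(y) * np.log(2 * np.pi)
    )


@pytest.fixture(scope="module")
def toy_instance():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(6, 2))
    y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
    hp = GPRHyperparams(1.3, 0.05, np.array([0.9, 1.4]))
    return X, y, hp


class TestKernel:
    def test_zero_distance_returns_signal_variance(self):
        hp = GPRHyperparams(2.5, 0.1, np.array([1.0, 2.0]))
        x = np.array([0.3, -1.2])
        assert gpr.se_kernel(x, x, hp) == pytest.approx(2.5)

    def test_unit_distance_hand_value(self):
        hp = GPRHyperparams(1.0, 0.0, np.array([1.0]))
        val = gpr.se_kernel(np.array([0.0]), np.array([1.0]), hp)
        assert val == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_monotone_decay_to_zero(self):
        hp = GPRHyperparams(1.0, 0.0, np.array([1.0]))
        vals = [gpr.se_kernel(np.array([0.0]), np.array([d]), hp) for d in range(8)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-9

    def test_dimension_mismatch_rejected(self):
        hp = GPRHyperparams(1.0, 0.0, np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            gpr.se_kernel(np.array([0.0]), np.array([0.0, 1.0]), hp)

    def test_kernel_matrix_symmetric_psd(self, toy_instance):
        X, _, hp = toy_instance
        K = gpr.kernel_matrix(X, X, hp)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_kernel_matrix_matches_pairwise(self, toy_instance):
        X, _, hp = toy_instance
        K = gpr.kernel_matrix(X, X, hp)
        brute = np.array([[gpr.se_kernel(a, b, hp) for b in X] for a in X])
        assert np.max(np.abs(K - brute)) < 1e-12


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        hp = GPRHyperparams(2.0, 0.5, np.array([1.0]))
        y = np.array([0.7])
        got = gpr.log_marginal_likelihood(np.array([[0.0]]), y, hp, center=False)
        want = -0.5 * (0.7**2 / 2.5 + np.log(2.5) + np.log(2 * np.pi))
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_brute_force_oracle(self, toy_instance):
        X, y, hp = toy_instance
        got = gpr.log_marginal_likelihood(X, y, hp)
        assert got == pytest.approx(brute_force_lml(X, y, hp), abs=1e-8)

    def test_permutation_invariance(self, toy_instance):
        X, y, hp = toy_instance
        perm = np.array([3, 1, 5, 0, 4, 2])
        a = gpr.log_marginal_likelihood(X, y, hp)
        b = gpr.log_marginal_likelihood(X[perm], y[perm], hp)
        assert a == pytest.approx(b, abs=1e-9)

    def test_gradient_matches_finite_differences(self, toy_instance):
        X, y, hp = toy_instance
        yc = y - y.mean()
        theta = hp.to_log_vector()
        _, grads = gpr._lml_and_grad(X, yc, hp, center=False)
        eps = 1e-6
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            fp = gpr.log_marginal_likelihood(X, yc, GPRHyperparams.from_log_vector(tp), center=False)
            fm = gpr.log_marginal_likelihood(X, yc, GPRHyperparams.from_log_vector(tm), center=False)
            assert grads[j] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)


class TestPredict:
    def test_matches_brute_force_oracle(self, toy_instance):
        X, y, hp = toy_instance
        model = gpr.refit_solve(X, y, hp)
        for xstar in (np.array([0.2, -0.5]), X[2], np.array([3.0, 3.0])):
            mean, var = gpr.predict(model, xstar)
            bmean, bvar = brute_force_predict(X, y, hp, xstar)
            assert mean == pytest.approx(bmean, abs=1e-8)
            assert var == pytest.approx(bvar, abs=1e-8)

    def test_interpolation_limit_at_training_point(self, toy_instance):
        X, y, _ = toy_instance
        hp = GPRHyperparams(1.0, 1e-10, np.array([1.0, 1.0]))
        model = gpr.refit_solve(X, y, hp)
        mean, var = gpr.predict(model, X[3])
        assert mean == pytest.approx(y[3], abs=1e-4)
        assert var == pytest.approx(0.0, abs=1e-4)

    def test_prior_reversion_far_from_data(self, toy_instance):
        X, y, hp = toy_instance
        model = gpr.refit_solve(X, y, hp)
        mean, var = gpr.predict(model, np.array([100.0, 100.0]))
        assert mean == pytest.approx(y.mean(), abs=1e-8)
        assert var == pytest.approx(hp.sigma_s2 + hp.sigma_n2, abs=1e-8)

    def test_variance_bounds(self, toy_instance):
        X, y, hp = toy_instance
        model = gpr.refit_solve(X, y, hp)
        rng = np.random.default_rng(2)
        _, var = gpr.predict(model, rng.normal(size=(50, 2)))
        assert np.all(var >= 0)
        assert np.all(var <= hp.sigma_s2 + hp.sigma_n2 + 1e-12)

    def test_permutation_invariant_predictions(self, toy_instance):
        X, y, hp = toy_instance
        perm = np.array([5, 0, 3, 1, 4, 2])
        a = gpr.refit_solve(X, y, hp)
        b = gpr.refit_solve(X[perm], y[perm], hp)
        xstar = np.array([0.1, 0.7])
        assert gpr.predict(a, xstar)[0] == pytest.approx(gpr.predict(b, xstar)[0], abs=1e-9)

    def test_dimension_mismatch_rejected(self, toy_instance):
        X, y, hp = toy_instance
        model = gpr.refit_solve(X, y, hp)
        with pytest.raises(ValueError):
            gpr.predict(model, np.array([0.0, 1.0, 2.0]))


class TestFit:
    def test_learns_noiseless_smooth_function(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, size=(40, 1))
        y = np.sin(1.5 * X[:, 0])
        model = gpr.fit(X, y, restarts=2, seed=0)
        Xte = np.linspace(-1.8, 1.8, 30)[:, None]
        mean, _ = gpr.predict(model, Xte)
        resid = np.sin(1.5 * Xte[:, 0]) - mean
        r2 = 1 - np.var(resid) / np.var(np.sin(1.5 * Xte[:, 0]))
        assert r2 > 0.99

    def test_evidence_never_below_initial(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        y = X[:, 0] - 2 * X[:, 2] + rng.normal(0, 0.1, 25)
        init = gpr._default_init(X, y - y.mean())
        model = gpr.fit(X, y, init=init, restarts=2, seed=1)
        assert model.log_evidence >= gpr.log_marginal_likelihood(X, y, init) - 1e-8

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] ** 2 + rng.normal(0, 0.05, 20)
        a = gpr.fit(X, y, restarts=3, seed=7)
        b = gpr.fit(X, y, restarts=3, seed=7)
        assert a.hyperparams.sigma_s2 == b.hyperparams.sigma_s2
        assert np.array_equal(a.hyperparams.lengthscales, b.hyperparams.lengthscales)

    def test_agrees_with_independent_library_implementation(self):
        """Cross-check against sklearn's GP (RBF+White, same model family):
        with each engine's own trained hyperparameters, held-out predictions
        should agree closely on smooth data."""
        sk = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        rng = np.random.default_rng(6)
        X = rng.uniform(-2, 2, size=(50, 2))
        y = np.sin(X[:, 0]) * np.cos(X[:, 1])
        ours = gpr.fit(X, y, restarts=3, seed=0)
        kern = ConstantKernel(1.0) * RBF([1.0, 1.0]) + WhiteKernel(1e-5)
        theirs = sk.GaussianProcessRegressor(kernel=kern, random_state=0).fit(X, y)
        Xte = rng.uniform(-1.5, 1.5, size=(40, 2))
        mean_ours, _ = gpr.predict(ours, Xte)
        mean_theirs = theirs.predict(Xte)
        truth = np.sin(Xte[:, 0]) * np.cos(Xte[:, 1])
        assert np.sqrt(np.mean((mean_ours - truth) ** 2)) < 0.05
        assert np.sqrt(np.mean((mean_ours - mean_theirs) ** 2)) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            gpr.fit(np.array([[0.0]]), np.array([1.0]))

    def test_model_archive_roundtrip(self, toy_instance, tmp_path):
        X, y, hp = toy_instance
        model = gpr.refit_solve(X, y, hp)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = gpr.GPRModel.load(path)
        xs = np.array([0.4, 0.4])
        assert gpr.predict(loaded, xs)[0] == pytest.approx(gpr.predict(model, xs)[0])


class TestKFoldCV:
    def test_partition_covers_each_sample_once(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        out = gpr.kfold_cv(X, y, k=5, seed=0)
        # pooled predictions exist for every sample (each tested exactly once)
        assert out["predictions"].shape == y.shape
        assert np.all(np.isfinite(out["predictions"]))

    def test_loo_limit_and_k_bounds(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 1))
        y = 2 * X[:, 0]
        out = gpr.kfold_cv(X, y, k=8, seed=0)
        assert out["predictions"].shape == (8,)
        with pytest.raises(ValueError):
            gpr.kfold_cv(X, y, k=9, seed=0)

    def test_pooled_rmse_beats_data_std_on_learnable_data(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(-2, 2, size=(40, 1))
        y = np.sin(X[:, 0])
        out = gpr.kfold_cv(X, y, k=5, seed=1)
        assert out["pooled"].rmse < np.std(y)
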