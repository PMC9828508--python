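import numpy as np
import pytest

from atomgpr import gpr
from atomgpr.alf import cyclic_mask
from atomgpr.gpr import (Hyperparameters, IllConditionedModelError,
                         covariance_matrix, fit, kernel, kernel_matrix,
                         log_marginal_likelihood, predict, predict_many)


def dense_reference(X, y, theta, mask, nugget):
    """Literal dense-matrix evaluation of likelihood, prediction mean and
    ordinary-kriging variance.  Independent oracle: no shared code paths
    with the package beyond the kernel definition re-derived by loops."""
    n, ndim = X.shape

    def k(a, b):
        s = 0.0
        for d in range(ndim):
            r = a[d] - b[d]
            if mask[d]:
                r = (r + np.pi) % (2 * np.pi) - np.pi
            s += theta.theta[d] * r * r
        return np.exp(-s)

    R = np.array([[k(X[i], X[j]) for j in range(n)] for i in range(n)])
    R = R + nugget * np.eye(n)
    Rinv = np.linalg.inv(R)
    mu = y.mean()
    resid = y - mu
    ll = (-0.5 * resid @ Rinv @ resid
          - 0.5 * np.linalg.slogdet(R)[1]
          - 0.5 * n * np.log(2 * np.pi))
    sigma2 = resid @ Rinv @ resid / n

    def pred(x_star):
        r = np.array([k(x_star, X[i]) for i in range(n)])
        mean = mu + r @ Rinv @ resid
        ones = np.ones(n)
        var = sigma2 * (1 - r @ Rinv @ r
                        + (1 - ones @ Rinv @ r) ** 2 / (ones @ Rinv @ ones))
        return mean, var

    return ll, pred


def _instance(rng, n, ndim):
    mask = cyclic_mask(ndim)
    X = rng.uniform(-2, 2, (n, ndim))
    y = np.sin(X).sum(axis=1) + 0.05 * rng.standard_normal(n)
    theta = Hyperparameters(rng.uniform(0.1, 3.0, ndim))
    return X, y, theta, mask


class TestKernel:
    def test_identical_points_give_one(self, rng):
        x = rng.uniform(size=4)
        theta = Hyperparameters(rng.uniform(0.1, 2.0, 4))
        assert kernel(x, x, theta, cyclic_mask(4)) == pytest.approx(1.0)

    def test_zero_theta_gives_one_everywhere(self, rng):
        theta = Hyperparameters(np.zeros(3))
        a, b = rng.uniform(-5, 5, (2, 3))
        assert kernel(a, b, theta, cyclic_mask(3)) == pytest.approx(1.0)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(np.array([0.5, -0.1]))

    def test_matches_scalar_loop_oracle(self, rng):
        mask = cyclic_mask(3)
        theta = Hyperparameters(rng.uniform(0.1, 3.0, 3))
        for _ in range(20):
            a = rng.uniform(-4, 4, 3)
            b = rng.uniform(-4, 4, 3)
            expected = 1.0
            s = 0.0
            for d in range(3):
                r = a[d] - b[d]
                if mask[d]:
                    r = (r + np.pi) % (2 * np.pi) - np.pi
                s += theta.theta[d] * r * r
            expected = np.exp(-s)
            assert kernel(a, b, theta, mask) == pytest.approx(expected,
                                                              rel=1e-12)
            assert 0 < kernel(a, b, theta, mask) <= 1

    def test_matches_sklearn_rbf_on_noncyclic_dims(self, rng):
        """Cross-check against an established RBF implementation: with no
        cyclic dims and isotropic theta, k = exp(-theta r^2) equals the
        sklearn RBF with length_scale 1/sqrt(2 theta)."""
        sklearn_kernels = pytest.importorskip("sklearn.gaussian_process.kernels")
        th = 0.7
        theta = Hyperparameters(np.full(4, th))
        mask = np.zeros(4, dtype=bool)
        X = rng.uniform(-2, 2, (6, 4))
        ours = kernel_matrix(X, X, theta, mask)
        ref = sklearn_kernels.RBF(length_scale=1 / np.sqrt(2 * th))(X)
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestCovarianceMatrix:
    def test_single_point(self):
        fac = covariance_matrix(np.zeros((1, 2)), Hyperparameters(np.ones(2)),
                                np.zeros(2, dtype=bool), nugget=0.0)
        assert fac.logdet() == pytest.approx(0.0)

    def test_duplicate_points_need_nugget(self, rng):
        X = np.vstack([np.ones(3), np.ones(3), rng.uniform(size=3)])
        theta = Hyperparameters(np.ones(3))
        mask = np.zeros(3, dtype=bool)
        # with a nugget the factorization succeeds (possibly escalated)
        fac = covariance_matrix(X, theta, mask, nugget=1e-10)
        assert fac.nugget <= gpr.NUGGET_CEILING

    def test_solve_matches_dense_inverse(self, rng):
        X, y, theta, mask = _instance(rng, 40, 4)
        fac = covariance_matrix(X, theta, mask, 1e-10)
        R = kernel_matrix(X, X, theta, mask) + fac.nugget * np.eye(40)
        b = rng.standard_normal(40)
        np.testing.assert_allclose(fac.solve(b), np.linalg.inv(R) @ b,
                                   rtol=1e-8, atol=1e-10)


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        ll = log_marginal_likelihood(np.zeros((1, 2)), np.array([3.7]),
                                     Hyperparameters(np.ones(2)),
                                     np.zeros(2, dtype=bool), nugget=1e-12)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-6)

    def test_constant_outputs_zero_quadratic_term(self, rng):
        X = rng.uniform(size=(6, 2))
        theta = Hyperparameters(rng.uniform(0.5, 2.0, 2))
        mask = np.zeros(2, dtype=bool)
        ll = log_marginal_likelihood(X, np.full(6, 2.5), theta, mask)
        fac = covariance_matrix(X, theta, mask)
        expected = -0.5 * fac.logdet() - 3 * np.log(2 * np.pi)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_constant_shift(self, rng):
        X, y, theta, mask = _instance(rng, 10, 3)
        a = log_marginal_likelihood(X, y, theta, mask)
        b = log_marginal_likelihood(X, y + 100.0, theta, mask)
        assert b == pytest.approx(a, rel=1e-9)

    def test_matches_dense_oracle(self, rng):
        for n in (8, 25, 50):
            X, y, theta, mask = _instance(rng, n, 3)
            nugget = 1e-10
            ll = log_marginal_likelihood(X, y, theta, mask, nugget)
            ref, _ = dense_reference(X, y, theta, mask, nugget)
            assert ll == pytest.approx(ref, rel=1e-8)


class TestFitPredict:
    def test_single_point_model(self):
        m = fit(np.zeros((1, 3)), np.array([4.2]), Hyperparameters(np.ones(3)),
                np.zeros(3, dtype=bool))
        assert m.mu == pytest.approx(4.2)
        np.testing.assert_allclose(m.weights, [0.0], atol=1e-9)
        p = predict(m, np.zeros(3))
        assert p.mean == pytest.approx(4.2)

    def test_constant_outputs_zero_weights(self, rng):
        X = rng.uniform(size=(8, 2))
        m = fit(X, np.full(8, 1.5), Hyperparameters(np.ones(2)),
                np.zeros(2, dtype=bool))
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-9)

    def test_weights_solve_the_linear_system(self, rng):
        X, y, theta, mask = _instance(rng, 20, 4)
        m = fit(X, y, theta, mask)
        R = kernel_matrix(X, X, theta, mask) + m.nugget * np.eye(20)
        np.testing.assert_allclose(R @ m.weights, y - m.mu, atol=1e-8)

    def test_interpolates_training_data_with_zero_variance(self, rng):
        X, y, theta, mask = _instance(rng, 15, 3)
        m = fit(X, y, theta, mask)
        tol = 10 * np.sqrt(m.nugget) * max(1.0, np.abs(y).max())
        for i in range(15):
            p = predict(m, X[i])
            assert abs(p.mean - y[i]) < tol
            assert p.variance < tol

    def test_dimension_mismatch_rejected(self, rng):
        X, y, theta, mask = _instance(rng, 5, 3)
        with pytest.raises(ValueError):
            predict(fit(X, y, theta, mask), np.zeros(4))

    def test_mean_and_variance_match_dense_oracle(self, rng):
        for n in (10, 30, 50):
            X, y, theta, mask = _instance(rng, n, 3)
            nugget = 1e-10
            m = fit(X, y, theta, mask, nugget)
            _, oracle_pred = dense_reference(X, y, theta, mask, m.nugget)
            for _ in range(5):
                x_star = rng.uniform(-2, 2, 3)
                p = predict(m, x_star)
                mean_ref, var_ref = oracle_pred(x_star)
                assert p.mean == pytest.approx(mean_ref, rel=1e-8, abs=1e-10)
                assert p.variance == pytest.approx(max(var_ref, 0.0),
                                                   rel=1e-6, abs=1e-10)

    def test_batched_prediction_agrees_with_scalar_path(self, rng):
        X, y, theta, mask = _instance(rng, 12, 3)
        m = fit(X, y, theta, mask)
        Xs = rng.uniform(-2, 2, (7, 3))
        means, vars_ = predict_many(m, Xs)
        for i in range(7):
            p = predict(m, Xs[i])
            assert means[i] == pytest.approx(p.mean, rel=1e-12)
            assert vars_[i] == pytest.approx(p.variance, rel=1e-9, abs=1e-12)

    def test_far_field_variance_limit(self):
        """With large theta, a far query decorrelates from all training
        points (r -> 0) and the variance approaches the closed-form limit
        sigma2 * (1 + 1/(1'R^-1 1))."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (10, 2))
        y = rng.standard_normal(10)
        theta = Hyperparameters(np.full(2, 3.0))
        mask = np.zeros(2, dtype=bool)
        m = fit(X, y, theta, mask)
        ones = np.ones(10)
        limit = m.sigma2 * (1 + 1 / (ones @ m.factor.solve(ones)))
        p = predict(m, np.array([500.0, -500.0]))
        assert p.variance == pytest.approx(limit, rel=1e-6)

    def test_model_json_round_trip(self, tmp_path, rng):
        X, y, theta, mask = _instance(rng, 9, 3)
        m = fit(X, y, theta, mask, atom_label="O1", alf_triple=(0, 1, 2))
        p = tmp_path / "model.json"
        m.save(p)
        back = gpr.GPRModel.load(p)
        x_star = rng.uniform(-1, 1, 3)
        assert predict(back, x_star).mean == pytest.approx(
            predict(m, x_star).mean, rel=1e-12)
        assert back.atom_label == "O1" and back.alf_triple == (0, 1, 2)
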