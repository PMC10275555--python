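import math

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from sleeparousal import (
    GWOConfig,
    KernelParams,
    ValidationError,
    cv_error,
    fit_svm,
    load_model,
    predict,
    rbf_kernel,
    save_model,
    tune_hyperparameters,
)
from sleeparousal.classifier import rbf_gram


def qp_oracle(X, y, params, n_iters=200_000):
    """Projected-gradient ascent on the C-SVC dual.

    Maximise ``sum a_i - 0.5 a' Q a`` with ``Q = y y' * K`` subject to
    ``0 <= a <= C`` and ``sum a_i y_i = 0``.  The feasible-set projection
    solves, by bisection over the equality multiplier, the exact Euclidean
    projection onto box-intersect-hyperplane.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    K = rbf_gram(X, X, params)
    Q = (y[:, None] * y[None, :]) * K
    C = params.C

    def project(v):
        def shifted(lam):
            return np.clip(v - lam * y, 0.0, C)

        lo, hi = -1e6, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if shifted(mid) @ y > 0:
                lo = mid
            else:
                hi = mid
        return shifted(0.5 * (lo + hi))

    a = project(np.zeros(len(y)))
    step = 1.0 / max(np.linalg.eigvalsh(Q).max(), 1e-12)
    for _ in range(n_iters):
        grad = 1.0 - Q @ a
        a = project(a + step * grad)
    return a


@pytest.fixture(scope="module")
def blobs():
    X, yb = make_blobs(n_samples=200, centers=2, cluster_std=1.2, random_state=0)
    return X, np.where(yb == 1, 1, -1)


class TestKernel:
    def test_zero_distance_is_one(self):
        p = KernelParams(C=1.0, gamma=2.0)
        assert rbf_kernel(np.array([1.0, 2.0]), np.array([1.0, 2.0]), p) == 1.0

    def test_distance_two_sigma_squared(self):
        p = KernelParams(C=1.0, gamma=0.5)  # sigma = 2
        x = np.zeros(1)
        x_j = np.array([math.sqrt(2.0) * p.sigma])
        assert rbf_kernel(x, x_j, p) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_gamma_sigma_conversion_pinned(self):
        p = KernelParams(C=1.0, gamma=4.0)
        assert p.sigma == 0.25
        assert p.gamma_eff == pytest.approx(4.0**2 / 2.0)
        assert p.gamma_eff == pytest.approx(1.0 / (2.0 * p.sigma**2))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError):
            rbf_kernel(np.zeros(2), np.zeros(3), KernelParams(C=1, gamma=1))

    def test_gram_matrix_positive_semidefinite(self, rng):
        X = rng.standard_normal((10, 4))
        gram = rbf_gram(X, X, KernelParams(C=1, gamma=1.5))
        np.testing.assert_allclose(gram, gram.T)
        assert np.linalg.eigvalsh(gram).min() >= -1e-10


class TestFitPredict:
    def test_separable_pair(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1, 1])
        model = fit_svm(X, y, KernelParams(C=10.0, gamma=1.0), standardize=False)
        _, decision = predict(model, X)
        assert decision[0] < 0 < decision[1]

    def test_dual_matches_projected_gradient_oracle(self):
        X = np.array([[-2.0], [-1.5], [-0.4], [0.3], [1.1], [2.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        params = KernelParams(C=5.0, gamma=1.0)
        model = fit_svm(X, y, params, standardize=False, tol=1e-8)
        a = qp_oracle(X, y, params)
        dual_full = np.zeros(len(y))
        sv_idx = [int(np.argmin(np.abs(X[:, 0] - v))) for v in model.support_vectors[:, 0]]
        dual_full[sv_idx] = model.dual_coef
        np.testing.assert_allclose(dual_full, a * y, atol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kkt_constraints_on_random_fits(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 3))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(30) > 0, 1, -1)
        if np.unique(y).size < 2:
            pytest.skip("degenerate draw")
        params = KernelParams(C=3.0, gamma=2.0)
        model = fit_svm(X, y, params)
        assert abs(model.dual_coef.sum()) < 1e-8
        assert np.all(np.abs(model.dual_coef) <= params.C + 1e-9)

    def test_training_accuracy_separable_large_c(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0.0, 0.5, (50, 2)), rng.normal(6.0, 0.5, (50, 2))])
        y = np.array([-1] * 50 + [1] * 50)
        model = fit_svm(X, y, KernelParams(C=100.0, gamma=5.0))
        pred, _ = predict(model, X)
        assert np.mean(pred == y) == 1.0

    def test_duplicating_non_support_point_is_invariant(self, blobs):
        X, y = blobs
        params = KernelParams(C=10.0, gamma=3.0)
        model = fit_svm(X, y, params, standardize=False)
        sv_set = {tuple(v) for v in model.support_vectors}
        non_sv = next(i for i in range(len(y)) if tuple(X[i]) not in sv_set)
        X2 = np.vstack([X, X[non_sv]])
        y2 = np.concatenate([y, [y[non_sv]]])
        model2 = fit_svm(X2, y2, params, standardize=False)
        probe = X[:20]
        _, d1 = predict(model, probe)
        _, d2 = predict(model2, probe)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_predict_deterministic(self, blobs):
        X, y = blobs
        model = fit_svm(X, y, KernelParams(C=10.0, gamma=2.0))
        _, d1 = predict(model, X)
        _, d2 = predict(model, X)
        np.testing.assert_array_equal(d1, d2)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_svm(np.zeros((4, 2)), np.ones(4), KernelParams(C=1, gamma=1))

    def test_feature_dim_mismatch_rejected(self, blobs):
        X, y = blobs
        model = fit_svm(X, y, KernelParams(C=1.0, gamma=1.0))
        with pytest.raises(ValidationError):
            predict(model, np.zeros((2, 5)))

    def test_model_file_round_trip(self, tmp_path, blobs):
        X, y = blobs
        model = fit_svm(X, y, KernelParams(C=7.0, gamma=2.5))
        save_model(model, str(tmp_path / "model"))
        loaded = load_model(str(tmp_path / "model"))
        _, d1 = predict(model, X)
        _, d2 = predict(loaded, X)
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        assert loaded.params.C == 7.0 and loaded.params.gamma == 2.5


class TestTuning:
    def test_tuned_parameters_separate_blobs(self, blobs):
        X, y = blobs
        result = tune_hyperparameters(
            X, y, folds=5,
            gwo_cfg=GWOConfig(bounds=((1, 50), (1, 30)), pop_size=10,
                              n_iters=15, n_restarts=1, seed=0),
            repetitions=2, seed=0,
        )
        assert result.cv_error <= 0.05
        assert 1.0 <= result.best_params.C <= 50.0
        assert 1.0 <= result.best_params.gamma <= 30.0
        assert len(result.repetitions) == 2

    def test_deterministic_given_seed(self, blobs):
        X, y = blobs
        kwargs = dict(
            folds=4,
            gwo_cfg=GWOConfig(bounds=((1, 50), (1, 30)), pop_size=6,
                              n_iters=5, n_restarts=1, seed=0),
            repetitions=2, seed=3,
        )
        r1 = tune_hyperparameters(X, y, **kwargs)
        r2 = tune_hyperparameters(X, y, **kwargs)
        assert r1.best_params == r2.best_params
        assert r1.cv_error == r2.cv_error

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).standard_normal((12, 2))
        y = np.array([1] * 3 + [-1] * 9)
        with pytest.raises(ValidationError):
            tune_hyperparameters(X, y, folds=5)

    def test_cv_error_uses_training_fold_standardisation(self, blobs):
        X, y = blobs
        err = cv_error(X, y, KernelParams(C=10.0, gamma=2.0), folds=5, seed=0)
        assert 0.0 <= err <= 1.0
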