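"""Kernel-Fisher discriminant: statistics, eigenproblem, classification."""

import numpy as np
import pytest
from scipy.stats import shapiro
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from spikespace.decoder import (
    class_statistics,
    classify,
    fit_kernel_discriminant,
    gram_matrix,
    majority_vote,
    observations_from_tensor,
    orthogonalize,
    project,
    select_lambda,
)
from spikespace.state_space import feature_map
from conftest import random_tensor


def two_blobs(sep=3.0, n=40, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(size=(n, d)) + sep / 2, rng.normal(size=(n, d)) - sep / 2]
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestGram:
    def test_single_zero_vector(self):
        assert gram_matrix(np.zeros((1, 3)), np.zeros((1, 3)), 2) == np.zeros((1, 1))

    def test_order_one_is_linear_gram(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(gram_matrix(X, X, 1), X @ X.T, atol=1e-12)

    def test_equals_explicit_feature_products(self):
        X = np.random.default_rng(1).normal(size=(30, 4))
        Phi = feature_map(X, 3)
        assert np.allclose(gram_matrix(X, X, 3), Phi @ Phi.T, atol=1e-8)


class TestClassStatistics:
    def test_single_observation_per_class_has_zero_scatter(self):
        X, _ = two_blobs(n=1)
        K = gram_matrix(X, X, 2)
        _, _, N, _, _ = class_statistics(K, np.array(["a", "b"]))
        assert np.allclose(N, 0.0, atol=1e-8)

    def test_class_means_are_column_averages(self):
        X, y = two_blobs(n=5)
        K = gram_matrix(X, X, 2)
        mu, m, N, classes, counts = class_statistics(K, y)
        assert np.allclose(mu[:, 0], K[:, y == "a"].mean(axis=1))
        assert np.allclose(m, mu.mean(axis=1))

    def test_within_class_scatter_matches_direct_sum(self):
        X, y = two_blobs(n=6, seed=3)
        K = gram_matrix(X, X, 2)
        mu, _, N, classes, counts = class_statistics(K, y)
        direct = np.zeros_like(N)
        for yi, c in enumerate(classes):
            cols = K[:, y == c]
            direct += (cols - mu[:, [yi]]) @ (cols - mu[:, [yi]]).T
        # K K^T - sum_y l_y mu mu^T is the scatter of kernel columns
        assert np.allclose(N, direct, atol=1e-8)

    def test_empty_class_rejected(self):
        K = np.eye(4)
        with pytest.raises(ValueError):
            class_statistics(K, np.array(["a"] * 4))


class TestFit:
    def test_order_one_equals_classical_lda(self):
        for seed in range(5):
            X, y = two_blobs(seed=seed)
            Xt, yt = two_blobs(seed=seed + 100)
            K = gram_matrix(X, X, 1)
            model = fit_kernel_discriminant(K, y, 0.0, theta=1, X_train=X)
            f_new = project(model, Xt)
            pred, _ = classify(model, f_new)
            lda = LinearDiscriminantAnalysis().fit(X, y)
            # projections collinear with the LDA axis, accuracy equal
            r = np.corrcoef(f_new[:, 0], lda.decision_function(Xt))[0, 1]
            assert abs(r) > 1 - 1e-6
            assert abs((pred == yt).mean() - lda.score(Xt, yt)) <= 0.02

    def test_permuted_labels_decode_at_chance(self):
        rng = np.random.default_rng(7)
        accs = []
        for rep in range(5):
            X = rng.normal(size=(80, 4))
            y = np.repeat(["a", "b", "c", "d"], 20)
            y = rng.permutation(y)
            K = gram_matrix(X, X, 2)
            model = fit_kernel_discriminant(K, y, 0.1, theta=2)
            Xt = rng.normal(size=(200, 4))
            pred, _ = classify(model, gram_matrix(Xt, X, 2) @ model.A)
            accs.append(np.mean(pred == rng.permutation(np.repeat(["a", "b", "c", "d"], 50))))
        assert abs(np.mean(accs) - 0.25) < 0.08

    def test_rank_bound_on_eigenvalues(self):
        X, y = two_blobs(n=20)
        K = gram_matrix(X, X, 2)
        model = fit_kernel_discriminant(K, y, 0.05, theta=2)
        assert model.A.shape[1] == 1  # c - 1 columns
        assert model.eigenvalues[0] > 0

    def test_lambda_range_enforced(self):
        X, y = two_blobs(n=5)
        K = gram_matrix(X, X, 1)
        with pytest.raises(ValueError):
            fit_kernel_discriminant(K, y, 0.9)

    def test_fisher_criterion_beats_random_directions(self):
        X, y = two_blobs(n=30, sep=2.0, seed=11)
        K = gram_matrix(X, X, 2)
        mu, m, N, classes, counts = class_statistics(K, y)
        dmu = mu - m[:, None]
        M = dmu @ dmu.T
        model = fit_kernel_discriminant(K, y, 0.1, theta=2)
        B = N + 0.1 * K + model.jitter * np.eye(len(K))

        def ratio(a):
            return (a @ M @ a) / (a @ B @ a)

        best = ratio(model.A[:, 0])
        rng = np.random.default_rng(0)
        rand = max(ratio(rng.normal(size=len(K))) for _ in range(1000))
        assert best >= rand

    def test_projected_classes_pass_normality_check(self):
        """Gaussian classes stay Gaussian after the (theta=1) projection."""
        X, y = two_blobs(n=100, sep=2.5, seed=2)
        K = gram_matrix(X, X, 1)
        model = fit_kernel_discriminant(K, y, 0.01, theta=1)
        for c in ("a", "b"):
            p = shapiro(model.F[y == c, 0]).pvalue
            assert p > 1e-3


class TestOrthogonalize:
    def three_class_model(self, seed=0, theta=2):
        rng = np.random.default_rng(seed)
        X = np.concatenate(
            [rng.normal(size=(25, 3)) + mu for mu in ([2, 0, 0], [0, 2, 0], [0, 0, 2])]
        )
        y = np.repeat(["a", "b", "c"], 25)
        K = gram_matrix(X, X, theta)
        return fit_kernel_discriminant(K, y, 0.05, theta=theta, X_train=X), K

    def test_projections_become_orthogonal(self):
        model, K = self.three_class_model()
        model = orthogonalize(model)
        F_hat = K @ model.A_orth
        off = F_hat.T @ F_hat
        norms = np.sqrt(np.diag(off))
        assert abs(off[0, 1]) < 1e-8 * norms[0] * norms[1]

    def test_two_classes_single_column(self):
        X, y = two_blobs(n=10)
        K = gram_matrix(X, X, 1)
        model = orthogonalize(fit_kernel_discriminant(K, y, 0.05, theta=1))
        assert model.A_orth.shape[1] == 1

    def test_span_preserved(self):
        model, K = self.three_class_model(seed=5)
        model = orthogonalize(model)
        F, F_hat = K @ model.A, K @ model.A_orth
        # each orthogonalized column is a combination of the originals
        resid = F_hat - F @ np.linalg.lstsq(F, F_hat, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8


class TestProjectClassify:
    def test_training_projection_reproduced(self):
        X, y = two_blobs()
        K = gram_matrix(X, X, 2)
        model = fit_kernel_discriminant(K, y, 0.1, theta=2, X_train=X)
        assert np.allclose(project(model, X), model.F, atol=1e-8)

    def test_duplicate_rows_duplicate_projections(self):
        X, y = two_blobs()
        model = fit_kernel_discriminant(gram_matrix(X, X, 2), y, 0.1, theta=2, X_train=X)
        F = project(model, np.vstack([X[:1], X[:1]]))
        assert np.allclose(F[0], F[1])

    def test_class_mean_wins_with_shared_covariance(self):
        X, y = two_blobs(sep=4.0)
        model = fit_kernel_discriminant(gram_matrix(X, X, 1), y, 0.0, theta=1, X_train=X)
        model.class_covs[:] = np.eye(1)
        pred, post = classify(model, model.class_means[0:1])
        assert pred[0] == model.classes[0]
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_identical_class_models_give_uniform_posteriors(self):
        X, y = two_blobs()
        model = fit_kernel_discriminant(gram_matrix(X, X, 1), y, 0.0, theta=1)
        model.class_means[:] = 0.0
        model.class_covs[:] = np.eye(1)
        _, post = classify(model, np.array([[0.7]]))
        assert np.allclose(post, 0.5)

    def test_1d_two_gaussian_boundary_matches_closed_form(self):
        # equal variances: the likelihood-ratio boundary is the midpoint
        X, y = two_blobs(sep=3.0, n=200, d=1, seed=4)
        model = fit_kernel_discriminant(gram_matrix(X, X, 1), y, 0.0, theta=1, X_train=X)
        mu = model.class_means[:, 0]
        sd = np.sqrt(model.class_covs[:, 0, 0])
        # crossing point of the two Gaussians (solve quadratic in f)
        a = 1 / sd[1] ** 2 - 1 / sd[0] ** 2
        b = 2 * (mu[0] / sd[0] ** 2 - mu[1] / sd[1] ** 2)
        c = mu[1] ** 2 / sd[1] ** 2 - mu[0] ** 2 / sd[0] ** 2 + 2 * np.log(sd[1] / sd[0])
        roots = np.roots([a, b, c]) if abs(a) > 1e-12 else np.array([-c / b])
        root = roots[np.argmin(np.abs(roots - mu.mean()))]
        eps = 1e-6
        lo, _ = classify(model, np.array([[root - eps]]))
        hi, _ = classify(model, np.array([[root + eps]]))
        assert lo[0] != hi[0]  # the prediction flips exactly at the boundary


class TestLambdaSelection:
    def test_single_point_grid(self):
        X, y = two_blobs()
        g = np.repeat(np.arange(len(X)), 1)
        assert select_lambda(X, y, g, 1, np.array([0.3])) == 0.3

    def test_ties_break_toward_larger_lambda(self):
        # widely separable classes: every lambda achieves zero error
        rng = np.random.default_rng(1)
        n_tr, nb = 40, 2
        y_trial = np.array(["a", "b"] * (n_tr // 2))
        X = rng.normal(size=(n_tr * nb, 3)) + np.repeat(
            np.where(y_trial == "a", 8.0, -8.0), nb
        )[:, None]
        lam = select_lambda(
            X, np.repeat(y_trial, nb), np.repeat(np.arange(n_tr), nb), 1,
            np.array([0.0, 0.25, 0.5]),
        )
        assert lam == 0.5

    def test_empty_grid_rejected(self):
        X, y = two_blobs()
        with pytest.raises(ValueError):
            select_lambda(X, y, np.arange(len(X)), 1, np.array([]))

    def test_selection_minimizes_the_validation_curve(self):
        """The returned λ attains the minimum causally validated error
        (recomputed here independently), with ties toward larger λ."""
        from spikespace.decoder import _mean_category_error

        rng = np.random.default_rng(6)
        n_tr, nb, theta = 40, 4, 4
        X = rng.normal(size=(n_tr * nb, 6)) * 0.4
        y_trial = np.array(["a", "b"] * (n_tr // 2))
        y = np.repeat(y_trial, nb)
        X[y == "a"] += 0.1
        groups = np.repeat(np.arange(n_tr), nb)
        grid = np.array([0.0, 0.1, 0.5])
        lam = select_lambda(X, y, groups, theta, grid)

        half = n_tr // 2
        fit = groups < half
        K_fit = gram_matrix(X[fit], X[fit], theta)
        K_val = gram_matrix(X[~fit], X[fit], theta)
        truth = dict(zip(groups[~fit], y[~fit]))
        curve = {}
        for g in grid:
            model = fit_kernel_discriminant(K_fit, y[fit], g, theta=theta)
            pred, _ = classify(model, K_val @ model.A)
            curve[g] = _mean_category_error(
                majority_vote(pred, groups[~fit]), truth
            )
        best = min(curve.values())
        assert curve[lam] == best
        assert lam == max(g for g in grid if curve[g] == best)


class TestObservations:
    def test_flattening_shapes_and_order(self):
        rt = random_tensor(n_units=2, n_bins=3, n_trials=4)
        X, y, groups = observations_from_tensor(rt, np.array(["a", "b", "a", "b"]))
        assert X.shape == (12, 2)
        assert np.array_equal(groups, np.repeat(np.arange(4), 3))
        assert np.allclose(X[0], rt.values[:, 0, 0])
        assert np.allclose(X[5], rt.values[:, 2, 1])

    def test_majority_vote_flags_ties(self):
        out = majority_vote(np.array(["a", "b", "a", "b"]), np.array([0, 0, 1, 1]))
        assert out["tie"].iloc[0]  # 1-1 within each group
        out2 = majority_vote(np.array(["a", "a", "b"]), np.zeros(3, int))
        assert out2["prediction"].iloc[0] == "a" and not out2["tie"].iloc[0]
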