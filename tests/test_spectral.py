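import numpy as np
import pytest
import scipy.linalg

from imfid.spectral import (embed, fit_kernel, fit_linear, gaussian_kernel,
                            graph_responses, knn_graph)


class TestKnnGraph:
    def test_basic_properties(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((16, 8))
        g = knn_graph(X, 5)
        np.testing.assert_array_equal(g.W, g.W.T)
        assert np.all(np.diag(g.W) == 0)
        counts = (g.W > 0).sum(axis=1)
        assert np.all(counts >= 5) and np.all(counts <= 15)
        np.testing.assert_allclose(g.D, g.W.sum(axis=0))  # column-sum oracle

    def test_collinear_three_points(self):
        X = np.array([[0.0], [1.0], [2.0]])
        g = knn_graph(X, 1)
        assert g.W[0, 1] > 0 and g.W[1, 2] > 0
        assert g.W[0, 2] == 0

    def test_p_too_large(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((4, 2)), 4)

    def test_scale_equivariance_binary_weights(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        g1 = knn_graph(X, 3)
        g2 = knn_graph(1000.0 * X, 3)
        np.testing.assert_array_equal(g1.W, g2.W)

    def test_heat_weights_decay_with_distance(self):
        X = np.vstack([np.zeros((5, 2)) + np.random.default_rng(2).normal(0, .01, (5, 2)),
                       [[10.0, 0.0]]])
        g = knn_graph(X, 2, weight="heat")
        # outlier's edges are far weaker than in-cloud edges
        assert g.W[5].max() < 1e-4 * g.W[:5, :5].max()


class TestGraphResponses:
    def test_eigen_residual(self):
        rng = np.random.default_rng(3)
        g = knn_graph(rng.standard_normal((25, 4)), 4)
        V, lam = graph_responses(g, 3)
        for m in range(3):
            r = g.W @ V[:, m] - lam[m] * g.D * V[:, m]
            assert np.linalg.norm(r) < 1e-8 * max(np.linalg.norm(V[:, m]), 1)

    def test_matches_dense_generalized_eigensolve(self):
        rng = np.random.default_rng(4)
        g = knn_graph(rng.standard_normal((30, 6)), 5)
        V, lam = graph_responses(g, 2)
        # brute-force oracle on the full generalized problem
        lam_all = scipy.linalg.eigvals(np.diag(1 / g.D) @ g.W)
        lam_all = np.sort(np.real(lam_all))[::-1]
        np.testing.assert_allclose(lam, lam_all[1:3], atol=1e-8)

    def test_two_cliques_bisection(self):
        N = 10
        W = np.zeros((N, N))
        W[:5, :5] = 1.0
        W[5:, 5:] = 1.0
        np.fill_diagonal(W, 0)
        W[4, 5] = W[5, 4] = 0.1  # weak bridge
        from imfid.spectral import AffinityGraph
        g = AffinityGraph(W=W, D=W.sum(axis=0), p=4)
        V, _ = graph_responses(g, 1)
        assert np.all(np.sign(V[:5, 0]) == np.sign(V[0, 0]))
        assert np.all(np.sign(V[5:, 0]) == -np.sign(V[0, 0]))

    def test_laplacian_scheme_isolates_weak_vertex(self):
        X = np.vstack([np.random.default_rng(5).normal(0, 0.1, (8, 2)),
                       [[50.0, 0.0]]])
        g = knn_graph(X, 3, weight="heat")
        V, lam = graph_responses(g, 1, scheme="laplacian")
        assert np.abs(V[8, 0]) > 5 * np.abs(V[:8, 0]).max()


class TestFitLinear:
    def test_interpolation_when_overparameterized(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 40))  # more features than samples
        v = rng.standard_normal((10, 2))
        model = fit_linear(X, v, alpha=0.0, beta=0.0)
        np.testing.assert_allclose(embed(model, X), v, atol=1e-6)

    def test_ridge_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 8))
        v = rng.standard_normal(30)
        alpha = 0.5
        model = fit_linear(X, v, alpha=alpha)
        oracle = np.linalg.solve(X.T @ X + alpha * np.eye(8), X.T @ v)
        np.testing.assert_allclose(model.coefficients[:, 0], oracle, atol=1e-8)

    def test_large_l1_zeroes_all_coefficients(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 6))
        v = rng.standard_normal(20)
        beta = 1e3 * np.max(np.abs(2 * X.T @ v))
        model = fit_linear(X, v, beta=beta)
        np.testing.assert_array_equal(model.coefficients, 0.0)

    def test_lasso_sparsity_intermediate(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 10))
        v = X[:, 0] + 0.1 * rng.standard_normal(40)
        model = fit_linear(X, v, alpha=0.0, beta=5.0)
        a = model.coefficients[:, 0]
        assert np.sum(a == 0.0) >= 1  # some exact zeros
        assert np.abs(a[0]) > 0.5     # the informative feature survives

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.eye(3), np.ones(3), alpha=-1.0)


class TestFitKernel:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 5))
        v = rng.standard_normal((12, 2))
        model = fit_kernel(X, v, alpha=0.0, eta=1.0)
        np.testing.assert_allclose(embed(model, X), v, atol=1e-6)

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 4))
        v = rng.standard_normal(20)
        alpha, eta = 0.01, 2.0
        model = fit_kernel(X, v, alpha=alpha, eta=eta)
        K = gaussian_kernel(X, X, eta)
        oracle = np.linalg.solve(K + alpha * np.eye(20), v)
        np.testing.assert_allclose(model.coefficients[:, 0], oracle, atol=1e-8)

    def test_huge_width_does_not_blow_up(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((10, 3))
        v = rng.standard_normal(10)
        model = fit_kernel(X, v, alpha=0.0, eta=1e8)
        assert np.all(np.isfinite(embed(model, X)))

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            fit_kernel(np.eye(4), np.ones(4), eta=0.0)


class TestEmbed:
    def test_identity_projection(self):
        from imfid.spectral import EmbeddingModel
        A = np.zeros((5, 2))
        A[0, 0] = A[1, 1] = 1.0
        model = EmbeddingModel(responses=np.zeros((3, 2)), coefficients=A,
                               mode="linear")
        X = np.random.default_rng(13).standard_normal((7, 5))
        np.testing.assert_array_equal(embed(model, X), X[:, :2])

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(14)
        model = fit_kernel(rng.standard_normal((8, 4)), rng.standard_normal(8))
        with pytest.raises(ValueError):
            embed(model, rng.standard_normal((3, 5)))


def test_separation_of_distant_clouds():
    """First embedding coordinate splits two 10-sigma-separated Gaussian
    clouds with zero overlap."""
    for seed in range(50):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (10, 3)),
                       rng.normal([10, 0, 0], 1, (10, 3))])
        g = knn_graph(X, 4)
        V, _ = graph_responses(g, 1)
        a, b = V[:10, 0], V[10:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
               max(b.min(), a.min()) > min(b.max(), a.max())
        assert (a.max() < b.min()) or (b.max() < a.min())
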