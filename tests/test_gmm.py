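import math

import numpy as np
import pytest

from imfid.gmm import (GMMParams, em_epsilon, em_fit, gmm_cluster, mdl_value,
                       merge_step, ml_classify, n_free_params)


def two_cluster_data(seed, sep=10.0, per=8, M=2):
    rng = np.random.default_rng(seed)
    a = rng.normal(np.zeros(M), 1, (per, M))
    b = rng.normal(np.r_[sep, np.zeros(M - 1)], 1, (per, M))
    return a, b, np.vstack([a, b])


class TestMDLValue:
    def test_single_point_closed_form(self):
        M = 2
        omega = GMMParams(pi=[1.0], mu=np.zeros((1, M)), Sigma=np.eye(M)[None])
        Z = np.zeros((1, M))
        data_term = (M / 2) * math.log(2 * math.pi)
        penalty = 0.5 * n_free_params(1, M) * math.log(1 * M)
        assert mdl_value(Z, omega) == pytest.approx(data_term + penalty, abs=1e-10)

    def test_duplicate_component_only_raises_penalty(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((30, 2))
        one = GMMParams(pi=[1.0], mu=Z.mean(0)[None], Sigma=np.cov(Z.T)[None])
        dup = GMMParams(pi=[0.5, 0.5], mu=np.repeat(Z.mean(0)[None], 2, 0),
                        Sigma=np.repeat(np.cov(Z.T)[None], 2, 0))
        extra = 0.5 * (n_free_params(2, 2) - n_free_params(1, 2)) * math.log(60)
        assert mdl_value(Z, dup) == pytest.approx(mdl_value(Z, one) + extra, abs=1e-8)

    def test_matches_bruteforce_loglik(self):
        from scipy.stats import multivariate_normal
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((50, 2))
        omega = GMMParams(pi=[0.3, 0.7], mu=[[0, 0], [1, 1]],
                          Sigma=[np.eye(2), 2 * np.eye(2)])
        dens = (0.3 * multivariate_normal([0, 0], np.eye(2)).pdf(Z)
                + 0.7 * multivariate_normal([1, 1], 2 * np.eye(2)).pdf(Z))
        oracle = -np.sum(np.log(dens)) + 0.5 * n_free_params(2, 2) * math.log(100)
        assert mdl_value(Z, omega) == pytest.approx(oracle, rel=1e-10)


def test_em_epsilon_printed_formula():
    # M=2, N=16: 0.01 * 6 * log(32)
    assert em_epsilon(16, 2) == pytest.approx(0.01 * 6 * math.log(32), rel=1e-12)
    assert em_epsilon(16, 2) == pytest.approx(0.2079, abs=5e-4)


class TestEMFit:
    def test_two_point_fixed_point(self):
        Z = np.array([[0.0, 0.0]] * 3 + [[5.0, 5.0]] * 5)
        init = GMMParams(pi=[0.5, 0.5], mu=[[0, 0], [5, 5]],
                         Sigma=[np.eye(2) * 0.1, np.eye(2) * 0.1])
        omega = em_fit(Z, init)
        order = np.argsort(omega.mu[:, 0])
        np.testing.assert_allclose(omega.mu[order], [[0, 0], [5, 5]], atol=1e-6)
        np.testing.assert_allclose(np.sort(omega.pi), [3 / 8, 5 / 8], atol=1e-6)

    def test_mdl_never_increases_from_init(self):
        for seed in range(20):
            a, b, Z = two_cluster_data(seed, sep=4.0)
            init = GMMParams(pi=[0.5, 0.5], mu=Z[[0, -1]],
                             Sigma=[np.cov(Z.T), np.cov(Z.T)])
            fitted = em_fit(Z, init)
            assert mdl_value(Z, fitted) <= mdl_value(Z, init) + 1e-6

    def test_priors_stay_normalized(self):
        _, _, Z = two_cluster_data(3)
        init = GMMParams(pi=[0.2, 0.8], mu=Z[[0, -1]],
                         Sigma=[np.eye(2), np.eye(2)])
        omega = em_fit(Z, init)
        assert omega.pi.sum() == pytest.approx(1.0, abs=1e-10)


class TestMergeStep:
    def test_identical_components_merge_to_same(self):
        Z = np.random.default_rng(0).standard_normal((20, 2))
        omega = GMMParams(pi=[0.5, 0.5], mu=[[1, 2], [1, 2]],
                          Sigma=[np.eye(2), np.eye(2)])
        merged = merge_step(Z, omega)
        assert merged.c == 1
        np.testing.assert_allclose(merged.mu[0], [1, 2], atol=1e-12)
        np.testing.assert_allclose(merged.Sigma[0], np.eye(2), atol=1e-12)

    def test_coincident_pair_is_chosen(self):
        Z = np.random.default_rng(1).standard_normal((20, 2))
        omega = GMMParams(pi=[0.4, 0.4, 0.2],
                          mu=[[0, 0], [0, 0], [50, 50]],
                          Sigma=[np.eye(2)] * 3)
        merged = merge_step(Z, omega)
        assert merged.c == 2
        assert any(np.allclose(mu, [50, 50]) for mu in merged.mu)

    def test_moment_matched_pooling_oracle(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((10, 2))
        mu1, mu2 = np.array([0.0, 0.0]), np.array([3.0, 1.0])
        S1, S2 = np.eye(2), np.diag([2.0, 0.5])
        omega = GMMParams(pi=[0.3, 0.7], mu=[mu1, mu2], Sigma=[S1, S2])
        merged = merge_step(Z, omega)
        mu_m = 0.3 * mu1 + 0.7 * mu2
        S_m = (0.3 * (S1 + np.outer(mu1 - mu_m, mu1 - mu_m))
               + 0.7 * (S2 + np.outer(mu2 - mu_m, mu2 - mu_m)))
        np.testing.assert_allclose(merged.mu[0], mu_m, atol=1e-10)
        np.testing.assert_allclose(merged.Sigma[0], S_m, atol=1e-10)

    def test_single_component_rejected(self):
        omega = GMMParams(pi=[1.0], mu=[[0, 0]], Sigma=[np.eye(2)])
        with pytest.raises(ValueError):
            merge_step(np.zeros((4, 2)), omega)


class TestGMMCluster:
    def test_two_separated_gaussians_recovered(self):
        a, b, Z = two_cluster_data(0, sep=10.0)
        res = gmm_cluster(Z, 2)
        assert res.c_hat == 2
        truth = np.r_[np.zeros(8, int), np.ones(8, int)]
        est = res.labels - 1
        agree = max(np.mean(est == truth), np.mean(est == 1 - truth))
        assert agree == 1.0
        # fitted means sit on the empirical cluster means
        emp = np.vstack([a.mean(0), b.mean(0)])
        mus = res.omega_hat.mu
        d = min(max(np.linalg.norm(mus[0] - emp[0]), np.linalg.norm(mus[1] - emp[1])),
                max(np.linalg.norm(mus[0] - emp[1]), np.linalg.norm(mus[1] - emp[0])))
        assert d < 0.5

    def test_single_gaussian_selects_one_cluster(self):
        Z = np.random.default_rng(7).normal(0, 1, (16, 2))
        res = gmm_cluster(Z, 2)
        assert res.c_hat == 1
        assert np.all(res.labels == 1)

    def test_c0_one_is_trivial(self):
        Z = np.random.default_rng(8).normal(0, 1, (10, 2))
        res = gmm_cluster(Z, 1)
        assert res.c_hat == 1 and np.all(res.labels == 1)

    def test_c_hat_is_argmin_of_trace(self):
        _, _, Z = two_cluster_data(4)
        res = gmm_cluster(Z, 3)
        assert res.c_hat == min(res.mdl_by_c, key=lambda c: (res.mdl_by_c[c], c))

    def test_permutation_invariance(self):
        _, _, Z = two_cluster_data(5)
        perm = np.random.default_rng(9).permutation(len(Z))
        r1 = gmm_cluster(Z, 2)
        r2 = gmm_cluster(Z[perm], 2)
        assert r1.c_hat == r2.c_hat
        # identical partition up to label names
        p1 = r1.labels[np.argsort(np.arange(len(Z)))]
        agree = np.mean((r2.labels == r2.labels[0]) == (r1.labels[perm] == r1.labels[perm][0]))
        assert agree == 1.0


class TestMLClassify:
    def test_tie_broken_by_lowest_index(self):
        omega = GMMParams(pi=[0.5, 0.5], mu=[[0, 0], [0, 0]],
                          Sigma=[np.eye(2), np.eye(2)])
        labels = ml_classify(np.zeros((1, 2)), omega)
        assert labels[0] == 1

    def test_symmetric_boundary(self):
        omega = GMMParams(pi=[0.5, 0.5], mu=[[-5.0], [5.0]],
                          Sigma=[np.eye(1), np.eye(1)])
        assert ml_classify(np.array([[0.1]]), omega)[0] == 2
        assert ml_classify(np.array([[-0.1]]), omega)[0] == 1

    def test_matches_density_oracle(self):
        from scipy.stats import multivariate_normal
        rng = np.random.default_rng(10)
        Z = rng.standard_normal((40, 2)) * 3
        omega = GMMParams(pi=[0.2, 0.8], mu=[[0, 0], [2, 2]],
                          Sigma=[np.eye(2), np.diag([0.5, 2.0])])
        d1 = 0.2 * multivariate_normal([0, 0], np.eye(2)).pdf(Z)
        d2 = 0.8 * multivariate_normal([2, 2], np.diag([0.5, 2.0])).pdf(Z)
        oracle = np.where(d1 >= d2, 1, 2)
        np.testing.assert_array_equal(ml_classify(Z, omega), oracle)
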