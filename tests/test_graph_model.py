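import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, kstest, multivariate_normal, norm

from subcox import (
    GraphHyper,
    Hyperparameters,
    block_gibbs_update_precision,
    edge_conditional_between,
    edge_conditional_within,
    expression_log_likelihood,
    precision_prior_logpdf,
)
from subcox.graph_model import GraphState


@pytest.fixture
def hyper():
    return GraphHyper(nu0=0.1, nu1=10.0, lam=1.0, pi_G=0.02)


class TestExpressionLikelihood:
    def test_identity_zero_row(self):
        assert expression_log_likelihood(np.zeros((1, 3)), np.eye(3)) == 0.0

    def test_scalar_case(self):
        np.testing.assert_allclose(
            expression_log_likelihood(np.array([[1.0]]), np.array([[2.0]])),
            0.5 * np.log(2) - 1.0,
        )

    def test_matches_dense_mvn_up_to_constant(self):
        rng = np.random.default_rng(0)
        p, n = 3, 5
        A = rng.standard_normal((p, p))
        omega = A @ A.T + p * np.eye(p)
        X = rng.standard_normal((n, p))
        dense = multivariate_normal(np.zeros(p), np.linalg.inv(omega)).logpdf(X).sum()
        const = -0.5 * n * p * np.log(2 * np.pi)
        np.testing.assert_allclose(
            expression_log_likelihood(X, omega), dense - const, atol=1e-9
        )

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            expression_log_likelihood(np.zeros((2, 2)), -np.eye(2))


class TestPrecisionPrior:
    def test_identity_empty_graph(self, hyper):
        p = 3
        expected = (
            p * (np.log(0.5) - 0.5)
            + 3 * norm.logpdf(0.0, scale=hyper.nu0)
        )
        np.testing.assert_allclose(
            precision_prior_logpdf(np.eye(p), np.zeros((p, p)), hyper), expected
        )

    def test_edge_flip_changes_by_density_ratio(self, hyper):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 3))
        omega = A @ A.T + 3 * np.eye(3)
        G0 = np.zeros((3, 3), dtype=int)
        G1 = G0.copy()
        G1[0, 1] = G1[1, 0] = 1
        delta = precision_prior_logpdf(omega, G1, hyper) - precision_prior_logpdf(
            omega, G0, hyper
        )
        np.testing.assert_allclose(
            delta,
            norm.logpdf(omega[0, 1], scale=hyper.nu1)
            - norm.logpdf(omega[0, 1], scale=hyper.nu0),
        )

    def test_non_pd_is_minus_inf(self, hyper):
        assert precision_prior_logpdf(-np.eye(2), np.zeros((2, 2)), hyper) == -np.inf


class TestEdgeConditionals:
    def test_within_at_zero(self, hyper):
        p = edge_conditional_within(0.0, 0, 0, hyper, b1=1.0)
        odds = (0.02 / 0.98) * (0.1 / 10.0)
        np.testing.assert_allclose(p, odds / (1 + odds), rtol=1e-10)
        assert abs(p - 2.04e-4) < 1e-5

    def test_selected_endpoints_boost_odds(self, hyper):
        p0 = edge_conditional_within(0.5, 0, 0, hyper, b1=1.0)
        p1 = edge_conditional_within(0.5, 1, 1, hyper, b1=1.0)
        odds0, odds1 = p0 / (1 - p0), p1 / (1 - p1)
        np.testing.assert_allclose(odds1 / odds0, np.exp(2.0), rtol=1e-9)

    def test_large_omega_forces_edge(self, hyper):
        assert edge_conditional_within(3.0, 0, 0, hyper, b1=1.0) > 0.999

    def test_between_values(self, hyper):
        np.testing.assert_allclose(edge_conditional_between(0, 1, hyper, 1.0), 0.02)
        p = edge_conditional_between(1, 1, hyper, 1.0)
        np.testing.assert_allclose(p, 1 / (1 + np.exp(3.8918 - 2)), atol=1e-4)
        np.testing.assert_allclose(edge_conditional_between(1, 1, hyper, 0.0), 0.02)

    def test_within_matches_joint_enumeration(self, hyper):
        """p(g_ij=1|.) from the closed form equals the brute-force ratio of
        the unnormalized joint p(Omega|G) p(G) p(gamma|G) over g in {0,1}."""
        from subcox.selection_priors import mrf_log_prior_unnormalized

        rng = np.random.default_rng(4)
        sel = Hyperparameters(a=-2.0, b1=0.7, b2=1.1)
        p = 3
        A = rng.standard_normal((p, p))
        omega = A @ A.T + p * np.eye(p)
        gamma = np.array([[1, 1, 0]])
        base = np.zeros((p, p), dtype=int)
        base[0, 2] = base[2, 0] = 1
        for i, j in [(0, 1), (1, 2)]:
            logw = {}
            for gval in (0, 1):
                G = base.copy()
                G[i, j] = G[j, i] = gval
                graph = GraphState(within=G[None, :, :], between={})
                n_edges = G[np.triu_indices(p, 1)].sum()
                logw[gval] = (
                    precision_prior_logpdf(omega, G, hyper)
                    + n_edges * np.log(hyper.pi_G)
                    + (p * (p - 1) // 2 - n_edges) * np.log(1 - hyper.pi_G)
                    + mrf_log_prior_unnormalized(gamma, graph, sel)
                )
            brute = 1.0 / (1.0 + np.exp(logw[0] - logw[1]))
            closed = edge_conditional_within(
                omega[i, j], gamma[0, i], gamma[0, j], hyper, sel.b1
            )
            np.testing.assert_allclose(closed, brute, atol=1e-10)

    def test_between_matches_joint_enumeration(self, hyper):
        from subcox.selection_priors import mrf_log_prior_unnormalized

        sel = Hyperparameters(a=-2.0, b1=0.7, b2=1.4)
        p = 2
        gamma = np.array([[1, 0], [1, 1]])
        for i in range(p):
            logw = {}
            for gval in (0, 1):
                between = {(0, 1): np.array([0, 0])}
                between[(0, 1)][i] = gval
                graph = GraphState(within=np.zeros((2, p, p), dtype=int),
                                   between=between)
                logw[gval] = (
                    gval * np.log(hyper.pi_G)
                    + (1 - gval) * np.log(1 - hyper.pi_G)
                    + mrf_log_prior_unnormalized(gamma, graph, sel)
                )
            brute = 1.0 / (1.0 + np.exp(logw[0] - logw[1]))
            closed = edge_conditional_between(gamma[0, i], gamma[1, i], hyper, sel.b2)
            np.testing.assert_allclose(closed, brute, atol=1e-10)


class TestBlockGibbs:
    def test_scalar_conjugate_closed_form(self, hyper):
        """p=1: the sampler must draw from Gamma(n/2 + 1, (S + lam)/2)."""
        rng = np.random.default_rng(5)
        n, S = 20, np.array([[37.5]])
        draws = np.array([
            block_gibbs_update_precision(S, n, np.zeros((1, 1)), np.eye(1), hyper, rng)[0, 0]
            for _ in range(5000)
        ])
        res = kstest(draws, gamma_dist(a=n / 2 + 1, scale=2 / (S[0, 0] + 1)).cdf)
        assert res.pvalue > 0.01

    def test_recovers_known_precision(self, hyper):
        rng = np.random.default_rng(6)
        p, n = 5, 500
        omega_true = np.eye(p)
        omega_true[0, 1] = omega_true[1, 0] = 0.5
        omega_true[2, 3] = omega_true[3, 2] = -0.4
        sigma = np.linalg.inv(omega_true)
        X = rng.multivariate_normal(np.zeros(p), sigma, size=n)
        S = X.T @ X
        omega = np.eye(p)
        G = np.zeros((p, p), dtype=int)
        iu = np.triu_indices(p, 1)
        total = np.zeros((p, p))
        n_keep = 0
        for sweep in range(500):
            omega = block_gibbs_update_precision(S, n, G, omega, hyper, rng)
            prob = edge_conditional_within(omega[iu], 0, 0, hyper, b1=0.0)
            g = (rng.random(len(prob)) < prob).astype(int)
            G = np.zeros((p, p), dtype=int)
            G[iu] = g
            G = G + G.T
            if sweep >= 100:
                total += omega
                n_keep += 1
        post_mean = total / n_keep
        for i in range(p):
            for j in range(p):
                if omega_true[i, j] != 0:
                    assert abs(post_mean[i, j] - omega_true[i, j]) < 0.15 * abs(
                        omega_true[i, j]
                    ) + 0.05
                else:
                    assert abs(post_mean[i, j]) < 0.15

    def test_stays_symmetric_pd(self, hyper):
        rng = np.random.default_rng(7)
        p, n = 6, 30
        X = rng.standard_normal((n, p))
        S = X.T @ X
        G = rng.integers(0, 2, (p, p))
        G = np.triu(G, 1)
        G = G + G.T
        omega = np.eye(p)
        for _ in range(1000):
            omega = block_gibbs_update_precision(S, n, G, omega, hyper, rng)
            np.testing.assert_allclose(omega, omega.T, atol=1e-12)
            assert np.linalg.eigvalsh(omega).min() > 0
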