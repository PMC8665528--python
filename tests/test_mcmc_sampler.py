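import numpy as np
import pytest

from subcox import ChainConfig, Hyperparameters, MultiSubgroupData, run_chain
from subcox.cox_likelihood import build_time_partition
from subcox.data_io import SubgroupDataset
from subcox.mcmc_sampler import (
    _update_gamma,
    initialize,
    joint_flip_move,
    update_beta,
    update_h,
)
from subcox.posterior_inference import batch_means_se

from conftest import make_dataset


def tiny_data(p=3, n=20, seed=0, null_covariates=False):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, p)) if null_covariates else rng.standard_normal((n, p))
    time = rng.exponential(1.0, n) + 0.05
    event = (rng.random(n) < 0.6).astype(int)
    event[:2] = 1
    sg = SubgroupDataset(X, time, event, "A")
    return MultiSubgroupData([sg], [f"g{i}" for i in range(p)])


class TestInitialize:
    def test_empty_model_and_reproducibility(self, small_multi):
        hyper = Hyperparameters()
        s1 = initialize(small_multi, hyper, np.random.default_rng(11))
        s2 = initialize(small_multi, hyper, np.random.default_rng(11))
        np.testing.assert_array_equal(s1.beta, s2.beta)
        assert (s1.gamma == 0).all()
        assert np.abs(s1.beta).max() <= 0.02
        np.testing.assert_array_equal(s1.omega[0], np.eye(small_multi.p))
        assert not s1.graph.within.any()
        assert all((h > 0).all() for h in s1.h)


class TestUpdateH:
    def test_matches_stated_gamma(self):
        # one event, three censored in I_1, a0=2, dH*=0.5 -> Gamma(2, rate 5)
        ds = make_dataset([0.5, 0.6, 0.7, 1.0], [0, 0, 0, 1], X=np.zeros((4, 1)))
        grouped = build_time_partition(ds)
        assert grouped.J == 2
        hyper = Hyperparameters()
        state = initialize(
            MultiSubgroupData([ds], ["g"]), hyper, np.random.default_rng(0)
        )
        priors = [(np.array([1.0, 0.8]), 2.0)]
        rng = np.random.default_rng(1)
        draws = np.empty((20_000, 2))
        for k in range(len(draws)):
            update_h(state, [grouped], [np.ones(4)], priors, rng)
            draws[k] = state.h[0]
        np.testing.assert_allclose(draws[:, 0].mean(), 2 / 5, atol=0.01)
        np.testing.assert_allclose(draws[:, 0].var(), 2 / 25, atol=0.005)
        # empty final interval: posterior equals the prior Gamma(0.8, 2)
        np.testing.assert_allclose(draws[:, 1].mean(), 0.4, atol=0.01)
        assert (draws > 0).all()


class TestUpdateBeta:
    def test_flat_likelihood_samples_spike_prior(self):
        """With all-zero covariates the likelihood is constant in beta, so the
        MH chain must sample the prior: sd(beta) ~ tau under gamma=0."""
        data = tiny_data(p=1, n=5, null_covariates=True)
        hyper = Hyperparameters()
        grouped = [build_time_partition(data[0])]
        state = initialize(data, hyper, np.random.default_rng(2))
        scales = np.full((1, 1), 0.05)
        accepted = np.zeros((1, 1))
        rng = np.random.default_rng(3)
        draws = np.empty(20_000)
        for k in range(len(draws)):
            update_beta(state, grouped, [data[0].covariates], hyper, scales,
                        accepted, rng)
            draws[k] = state.beta[0, 0]
        assert abs(draws.std() - hyper.tau) / hyper.tau < 0.1
        rate = accepted[0, 0] / len(draws)
        assert 0.0 < rate < 1.0

    def test_zero_step_always_accepted(self):
        data = tiny_data(p=2, n=10, seed=4)
        hyper = Hyperparameters()
        grouped = [build_time_partition(data[0])]
        state = initialize(data, hyper, np.random.default_rng(5))
        before = state.beta.copy()
        accepted = np.zeros((1, 2))
        # zero proposal scale => proposal == current => ratio 1 => accept
        update_beta(state, grouped, [data[0].covariates], hyper,
                    np.zeros((1, 2)), accepted, np.random.default_rng(6))
        np.testing.assert_array_equal(state.beta, before)
        assert accepted.sum() == 2


class TestGammaCalibration:
    def test_flat_likelihood_bernoulli_prior_level(self):
        """Against all-zero covariates the chain's stationary inclusion
        frequency must sit at the Bernoulli prior level pi_gamma."""
        data = tiny_data(p=2, n=10, null_covariates=True)
        cfg = ChainConfig(variant="subgroup", n_iter=6000, burn_in=1000, seed=8,
                          hyper=Hyperparameters(pi_gamma=0.1))
        chain = run_chain(data, cfg)
        trace = chain.gamma_samples[1000:].mean(axis=(1, 2))
        se = batch_means_se(trace)
        assert abs(trace.mean() - 0.1) < 3 * se + 0.01


class TestDetailedBalance:
    def test_gamma_marginal_matches_quadrature(self):
        """Fixed-h Gibbs over (beta, gamma) on a 2-gene, 10-patient instance:
        the chain's P(gamma_1 = 1) must match brute-force enumeration over
        gamma with beta integrated by Gauss-Hermite quadrature."""
        rng = np.random.default_rng(9)
        n, p = 10, 2
        X = rng.standard_normal((n, p))
        time = np.r_[np.full(5, 1.0), [0.4, 0.5, 0.6, 0.7, 0.8]]
        event = np.r_[np.ones(5), np.zeros(5)].astype(int)
        ds = SubgroupDataset(X, time, event, "A")
        data = MultiSubgroupData([ds], ["g1", "g2"])
        grouped = build_time_partition(ds)
        h = np.array([0.7, 0.5])
        hyper = Hyperparameters(pi_gamma=0.3, tau=0.0375, c=20.0)

        def loglik(b1, b2):
            e = np.exp(X[:, 0] * b1 + X[:, 1] * b2)
            out = -h[0] * e[event == 0].sum()
            out += np.log1p(-np.exp(-h[0] * e[event == 1])).sum()
            return out

        # enumeration oracle: 2D Gauss-Hermite per gamma configuration
        nodes, weights = np.polynomial.hermite.hermgauss(80)
        post = {}
        for g1 in (0, 1):
            for g2 in (0, 1):
                v1 = hyper.c * hyper.tau if g1 else hyper.tau
                v2 = hyper.c * hyper.tau if g2 else hyper.tau
                b1g = np.sqrt(2) * v1 * nodes
                b2g = np.sqrt(2) * v2 * nodes
                L = np.array([[np.exp(loglik(a, b)) for b in b2g] for a in b1g])
                integral = weights @ L @ weights / np.pi
                prior = (hyper.pi_gamma if g1 else 1 - hyper.pi_gamma) * (
                    hyper.pi_gamma if g2 else 1 - hyper.pi_gamma
                )
                post[(g1, g2)] = prior * integral
        z = sum(post.values())
        p_true = (post[(1, 0)] + post[(1, 1)]) / z

        state = initialize(data, hyper, np.random.default_rng(10))
        state.h[0] = h.copy()
        scales = np.full((1, p), 0.1)
        accepted = np.zeros((1, p))
        rng2 = np.random.default_rng(11)
        n_iter, burn = 40_000, 2_000
        g1_trace = np.empty(n_iter)
        for it in range(n_iter):
            _update_gamma(state, hyper, use_mrf=False, rng=rng2)
            joint_flip_move(state, [grouped], [X], hyper, False, rng2)
            update_beta(state, [grouped], [X], hyper, scales, accepted, rng2)
            g1_trace[it] = state.gamma[0, 0]
        est = g1_trace[burn:].mean()
        se = batch_means_se(g1_trace[burn:], n_batches=30)
        assert abs(est - p_true) < 3 * se + 0.01


class TestRunChain:
    def test_smoke_and_bit_reproducibility(self):
        data = tiny_data(p=6, n=30, seed=12)
        cfg = ChainConfig(variant="coxbvs_sl", n_iter=40, burn_in=10, seed=13)
        c1 = run_chain(data, cfg)
        c2 = run_chain(data, cfg)
        assert np.isfinite(c1.loglik).all()
        np.testing.assert_array_equal(c1.beta_samples, c2.beta_samples)
        np.testing.assert_array_equal(c1.gamma_samples, c2.gamma_samples)
        np.testing.assert_array_equal(c1.within_samples, c2.within_samples)

    def test_variant_structure(self, small_multi):
        cfg = ChainConfig(variant="pooled", n_iter=30, burn_in=5, seed=1)
        pooled = run_chain(small_multi, cfg)
        assert pooled.S == 1 and pooled.labels == ["pooled"]
        assert pooled.within_samples is None
        cfg2 = ChainConfig(variant="sub_struct", n_iter=30, burn_in=5, seed=1)
        ss = run_chain(small_multi, cfg2)
        assert ss.between_samples is not None and not ss.between_samples.any()
        cfg3 = ChainConfig(variant="coxbvs_sl", n_iter=30, burn_in=5, seed=1)
        full = run_chain(small_multi, cfg3)
        assert full.between_samples.shape == (30, 1, small_multi.p)

    def test_acceptance_rates_bounded(self):
        data = tiny_data(p=4, n=25, seed=14)
        chain = run_chain(data, ChainConfig(variant="subgroup", n_iter=200,
                                            burn_in=50, seed=15))
        assert ((chain.acceptance_rate >= 0) & (chain.acceptance_rate <= 1)).all()
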