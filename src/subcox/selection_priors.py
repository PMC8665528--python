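"""Variable-selection priors.

Coefficients carry a two-component normal spike-and-slab mixture gated by
binary indicators gamma. The indicators themselves carry either a Markov
random field prior linked to the graph,

    p(gamma | G) ~ exp( a 1'gamma + b gamma' G gamma ),

which rewards the joint inclusion of graph neighbours, or (for the baseline
Subgroup/Pooled variants) independent Bernoulli(pi_gamma) priors. The MRF
reward is split: b1 weighs within-subgroup gene-gene edges and b2 weighs
same-gene edges across subgroups; b1 = b2 recovers the single-b prior.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .data_io import Hyperparameters
from .graph_model import GraphState

__all__ = [
    "spike_slab_logpdf",
    "mrf_log_prior_unnormalized",
    "gamma_conditional_prob",
    "mrf_neighbour_sum",
    "bernoulli_log_prior",
]


def spike_slab_logpdf(beta, gamma, hyper: Hyperparameters):
    """log N(beta | 0, tau^2) if gamma = 0, log N(beta | 0, (c tau)^2) if 1.
    Vectorized over beta/gamma."""
    sd = np.where(np.asarray(gamma) == 1, hyper.c * hyper.tau, hyper.tau)
    return norm.logpdf(np.asarray(beta), scale=sd)


def mrf_log_prior_unnormalized(
    gamma: np.ndarray, graph: GraphState, hyper: Hyperparameters
) -> float:
    """a * (#selected) + b1 * sum_s gamma_s' G_ss gamma_s
    + b2 * 2 * sum_{r<s} sum_i g_rs,ii gamma_ri gamma_si.

    Quadratic forms run over symmetric adjacencies, so every undirected edge
    with both endpoints selected contributes twice. The (intractable)
    normalizing constant is omitted; with fixed a, b it cancels from every
    Gibbs ratio.
    """
    gamma = np.asarray(gamma, dtype=float)
    out = hyper.a * float(gamma.sum())
    for s in range(graph.S):
        out += hyper.b1 * float(gamma[s] @ graph.within[s] @ gamma[s])
    for (r, s), g in graph.between.items():
        out += hyper.b2 * 2.0 * float(np.sum(g * gamma[r] * gamma[s]))
    return out


def mrf_neighbour_sum(
    s: int, i: int, gamma: np.ndarray, graph: GraphState, hyper: Hyperparameters
) -> float:
    """The exponent a + 2 b1 sum_{j!=i} gamma_sj g_ss,ij
    + 2 b2 sum_{r!=s} gamma_ri g_rs,ii of the MRF full conditional."""
    e = hyper.a + 2.0 * hyper.b1 * float(graph.within[s, i] @ gamma[s])
    for (r, q), g in graph.between.items():
        if r == s:
            e += 2.0 * hyper.b2 * float(g[i] * gamma[q, i])
        elif q == s:
            e += 2.0 * hyper.b2 * float(g[i] * gamma[r, i])
    return e


def gamma_conditional_prob(
    s: int,
    i: int,
    gamma: np.ndarray,
    graph: GraphState,
    beta_si: float | None,
    hyper: Hyperparameters,
) -> float:
    """Full-conditional inclusion probability of gamma_{s,i}.

    With ``beta_si`` given, combines the MRF conditional with the
    spike-and-slab density of the current coefficient:
    w1 = N(beta|0,(c tau)^2) exp(a + 2b.(neighbour sums)), w0 = N(beta|0,tau^2),
    returning w1/(w0+w1). With ``beta_si=None`` (prior-only mode) the normal
    factors are dropped and the plain MRF conditional is returned.
    """
    e = mrf_neighbour_sum(s, i, gamma, graph, hyper)
    if beta_si is None:
        log_odds = e
    else:
        log_odds = (
            e
            + norm.logpdf(beta_si, scale=hyper.c * hyper.tau)
            - norm.logpdf(beta_si, scale=hyper.tau)
        )
    return float(1.0 / (1.0 + np.exp(-log_odds)))


def bernoulli_log_prior(gamma: np.ndarray, hyper: Hyperparameters) -> float:
    """Independent Bernoulli(pi_gamma) log-prior over all indicators."""
    gamma = np.asarray(gamma, dtype=float)
    k = float(gamma.sum())
    m = float(gamma.size)
    return k * np.log(hyper.pi_gamma) + (m - k) * np.log1p(-hyper.pi_gamma)
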