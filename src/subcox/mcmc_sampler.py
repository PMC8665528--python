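"""Block Gibbs / Metropolis-Hastings sampler for the joint subgroup model.

Each iteration sweeps, in this fixed order:

1. per subgroup: one column sweep of the block Gibbs sampler for Omega_ss;
2. all graph indicators G (within-subgroup edges, then same-gene
   cross-subgroup edges) from their Bernoulli full conditionals;
3. all selection indicators gamma, sequentially, from the MRF (or Bernoulli)
   full conditional combined with the spike-and-slab density of the current
   coefficient, followed by one add/delete Metropolis sweep that proposes
   (gamma_si, beta_si) jointly (a mixing accelerator that leaves the
   posterior invariant; see :func:`joint_flip_move`);
4. all coefficients beta via per-coefficient random-walk Metropolis-Hastings,
   with a windowed adaptive proposal scale frozen after burn-in;
5. all baseline increments h from their (approximate) gamma full
   conditionals.

Model variants: ``coxbvs_sl`` (full model), ``sub_struct`` (cross-subgroup
edges fixed empty), ``subgroup`` (independent Bernoulli selection prior, no
graph), ``pooled`` (subgroups merged, Bernoulli prior, no graph). A single
seeded RNG stream drives every draw, so chains are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logit
from scipy.stats import norm

from .cox_likelihood import (
    BaselineHyper,
    GroupedSurvival,
    build_time_partition,
    baseline_increment_prior,
    fit_weibull_baseline,
    grouped_log_likelihood_fast,
    risk_minus_failure_sums,
)
from .data_io import Hyperparameters, MultiSubgroupData, SubgroupDataset
from .graph_model import (
    GraphHyper,
    GraphState,
    block_gibbs_update_precision,
    edge_conditional_between,
    edge_conditional_within,
)
from .selection_priors import mrf_neighbour_sum

__all__ = ["ModelState", "ChainConfig", "ChainResult", "initialize",
           "update_beta", "update_h", "run_chain", "VARIANTS"]

VARIANTS = ("coxbvs_sl", "sub_struct", "subgroup", "pooled")


@dataclass
class ModelState:
    """One MCMC state."""

    gamma: np.ndarray  # (S, p) in {0,1}
    beta: np.ndarray  # (S, p)
    h: list[np.ndarray]  # per subgroup, length J_s, positive
    graph: GraphState
    omega: np.ndarray  # (S, p, p) symmetric PD


@dataclass
class ChainConfig:
    variant: str = "coxbvs_sl"
    n_iter: int = 20_000
    burn_in: int = 10_000
    seed: int = 0
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    adapt_window: int = 100
    initial_scale: float = 0.1
    beta_substeps: int = 3

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")


@dataclass
class ChainResult:
    """Post-initialization samples of one chain plus metadata.

    ``h_samples[s]`` has shape (n_iter, J_s); ``within_samples`` stores the
    upper triangle of each G_ss; ``loglik`` is the per-iteration Cox
    log-likelihood summed over subgroups.
    """

    variant: str
    seed: int
    n_iter: int
    burn_in: int
    labels: list[str]
    gene_names: list[str]
    gamma_samples: np.ndarray  # (n_iter, S, p)
    beta_samples: np.ndarray  # (n_iter, S, p)
    h_samples: list[np.ndarray]
    within_samples: np.ndarray | None  # (n_iter, S, p(p-1)/2)
    between_samples: np.ndarray | None  # (n_iter, n_pairs, p)
    loglik: np.ndarray  # (n_iter,)
    acceptance_rate: np.ndarray  # (S, p)
    boundaries: list[np.ndarray]
    baseline: list[BaselineHyper]
    hyper: Hyperparameters

    @property
    def S(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        return len(self.gene_names)

    def post_burnin(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.burn_in:]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            variant=self.variant,
            seed=self.seed,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            labels=np.array(self.labels),
            gene_names=np.array(self.gene_names),
            gamma_samples=self.gamma_samples,
            beta_samples=self.beta_samples,
            loglik=self.loglik,
            acceptance_rate=self.acceptance_rate,
            baseline=np.array([[b.a0, b.eta, b.kappa] for b in self.baseline]),
            **{f"h_{s}": h for s, h in enumerate(self.h_samples)},
            **{f"bnd_{s}": b for s, b in enumerate(self.boundaries)},
        )


def initialize(
    data: MultiSubgroupData, hyper: Hyperparameters, rng: np.random.Generator
) -> ModelState:
    """Empty starting model: no edges, identity precision, no variable
    selected, beta ~ U[-0.02, 0.02], h ~ Gamma(1, 1)."""
    S, p = data.S, data.p
    beta = rng.uniform(-0.02, 0.02, size=(S, p))
    h = []
    for sg in data.subgroups:
        grouped = build_time_partition(sg)
        h.append(rng.gamma(1.0, 1.0, size=grouped.J))
    return ModelState(
        gamma=np.zeros((S, p), dtype=np.uint8),
        beta=beta,
        h=h,
        graph=GraphState.empty(S, p),
        omega=np.broadcast_to(np.eye(p), (S, p, p)).copy(),
    )


def _bernoulli_log_odds_beta(beta_si: float, hyper: Hyperparameters) -> float:
    return (
        logit(hyper.pi_gamma)
        + norm.logpdf(beta_si, scale=hyper.c * hyper.tau)
        - norm.logpdf(beta_si, scale=hyper.tau)
    )


def _update_gamma(
    state: ModelState, hyper: Hyperparameters, use_mrf: bool, rng: np.random.Generator
) -> None:
    S, p = state.gamma.shape
    u = rng.random((S, p))
    for s in range(S):
        for i in range(p):
            if use_mrf:
                e = mrf_neighbour_sum(s, i, state.gamma, state.graph, hyper)
                log_odds = (
                    e
                    + norm.logpdf(state.beta[s, i], scale=hyper.c * hyper.tau)
                    - norm.logpdf(state.beta[s, i], scale=hyper.tau)
                )
            else:
                log_odds = _bernoulli_log_odds_beta(state.beta[s, i], hyper)
            state.gamma[s, i] = u[s, i] < 1.0 / (1.0 + np.exp(-log_odds))


def _update_graph(
    state: ModelState,
    hyper: Hyperparameters,
    graph_hyper: GraphHyper,
    include_between: bool,
    rng: np.random.Generator,
) -> None:
    S, p = state.gamma.shape
    iu = np.triu_indices(p, k=1)
    for s in range(S):
        prob = edge_conditional_within(
            state.omega[s][iu], state.gamma[s][iu[0]], state.gamma[s][iu[1]],
            graph_hyper, hyper.b1,
        )
        g = (rng.random(len(prob)) < prob).astype(np.uint8)
        W = np.zeros((p, p), dtype=np.uint8)
        W[iu] = g
        state.graph.within[s] = W + W.T
    for (r, s), _ in state.graph.between.items():
        if include_between:
            prob = edge_conditional_between(
                state.gamma[r], state.gamma[s], graph_hyper, hyper.b2
            )
            state.graph.between[(r, s)] = (rng.random(p) < prob).astype(np.uint8)
        else:
            state.graph.between[(r, s)] = np.zeros(p, dtype=np.uint8)


def joint_flip_move(
    state: ModelState,
    grouped_list: list[GroupedSurvival],
    X_list: list[np.ndarray],
    hyper: Hyperparameters,
    use_mrf: bool,
    rng: np.random.Generator,
) -> None:
    """Add/delete Metropolis move on (gamma_si, beta_si) pairs (in-place).

    For each coefficient, propose flipping the indicator and drawing the
    coefficient fresh from the proposed mixture component. Because the
    proposal equals the prior component, the acceptance ratio reduces to the
    likelihood ratio times the conditional prior odds of the flip. The move
    leaves the posterior invariant; it exists purely to speed mixing across
    the spike/slab modes, which a random walk crosses only rarely.
    """
    S, p = state.beta.shape
    for s in range(S):
        X, grouped = X_list[s], grouped_list[s]
        lp = X @ state.beta[s]
        exp_lp = np.exp(lp)
        cur_ll = grouped_log_likelihood_fast(grouped, state.h[s], exp_lp)
        noise = rng.standard_normal(p)
        us = np.log(rng.random(p))
        for i in range(p):
            new_gamma = 1 - state.gamma[s, i]
            sd_new = hyper.c * hyper.tau if new_gamma == 1 else hyper.tau
            prop = sd_new * noise[i]
            lp_prop = lp + X[:, i] * (prop - state.beta[s, i])
            exp_lp_prop = np.exp(lp_prop)
            prop_ll = grouped_log_likelihood_fast(grouped, state.h[s], exp_lp_prop)
            if use_mrf:
                e = mrf_neighbour_sum(s, i, state.gamma, state.graph, hyper)
            else:
                e = float(logit(hyper.pi_gamma))
            # log prior odds of the proposed indicator value vs the current one
            log_prior_odds = e if new_gamma == 1 else -e
            if us[i] < prop_ll - cur_ll + log_prior_odds:
                state.gamma[s, i] = new_gamma
                state.beta[s, i] = prop
                lp, exp_lp, cur_ll = lp_prop, exp_lp_prop, prop_ll


def update_beta(
    state: ModelState,
    grouped_list: list[GroupedSurvival],
    X_list: list[np.ndarray],
    hyper: Hyperparameters,
    scales: np.ndarray,
    accepted: np.ndarray,
    rng: np.random.Generator,
    substeps: int = 1,
) -> list[np.ndarray]:
    """One random-walk MH sweep over all coefficients (in-place).

    The acceptance ratio multiplies the grouped-likelihood ratio by the
    spike-and-slab prior ratio at the current indicator. ``substeps`` inner MH
    steps are taken per coefficient per sweep (the target is unchanged; extra
    substeps counter the slow ratcheting of spike-and-slab random walks).
    Returns the cached exp(beta'x) per subgroup for downstream updates;
    ``accepted`` counts acceptances in units of full sweeps.
    """
    S, p = state.beta.shape
    exp_lps = []
    for s in range(S):
        X, grouped = X_list[s], grouped_list[s]
        lp = X @ state.beta[s]
        exp_lp = np.exp(lp)
        cur_ll = grouped_log_likelihood_fast(grouped, state.h[s], exp_lp)
        steps = rng.standard_normal((substeps, p))
        us = np.log(rng.random((substeps, p)))
        for i in range(p):
            sd = hyper.c * hyper.tau if state.gamma[s, i] == 1 else hyper.tau
            for k in range(substeps):
                prop = state.beta[s, i] + scales[s, i] * steps[k, i]
                lp_prop = lp + X[:, i] * (prop - state.beta[s, i])
                exp_lp_prop = np.exp(lp_prop)
                prop_ll = grouped_log_likelihood_fast(grouped, state.h[s], exp_lp_prop)
                log_ratio = (
                    prop_ll - cur_ll
                    + norm.logpdf(prop, scale=sd)
                    - norm.logpdf(state.beta[s, i], scale=sd)
                )
                if us[k, i] < log_ratio:
                    state.beta[s, i] = prop
                    lp, exp_lp, cur_ll = lp_prop, exp_lp_prop, prop_ll
                    accepted[s, i] += 1.0 / substeps
        exp_lps.append(exp_lp)
    return exp_lps


def update_h(
    state: ModelState,
    grouped_list: list[GroupedSurvival],
    exp_lps: list[np.ndarray],
    priors: list[tuple[np.ndarray, float]],
    rng: np.random.Generator,
) -> None:
    """Draw every baseline increment from its gamma full conditional:
    shape = a0 dH* + d_g, rate = a0 + sum_{R_g - D_g} exp(beta'x)."""
    for s, grouped in enumerate(grouped_list):
        shapes, rate0 = priors[s]
        shape = shapes + grouped.event_counts
        rate = rate0 + risk_minus_failure_sums(grouped, exp_lps[s])
        state.h[s] = rng.gamma(shape, 1.0 / rate)


def _prepare_data(data: MultiSubgroupData, variant: str) -> MultiSubgroupData:
    if variant != "pooled" or data.S == 1:
        return data
    merged = SubgroupDataset(
        covariates=np.vstack([sg.covariates for sg in data.subgroups]),
        time=np.concatenate([sg.time for sg in data.subgroups]),
        event=np.concatenate([sg.event for sg in data.subgroups]),
        subgroup_id="pooled",
    )
    return MultiSubgroupData([merged], data.gene_names)


def run_chain(data: MultiSubgroupData, config: ChainConfig) -> ChainResult:
    """Run one MCMC chain on standardized training data."""
    data = _prepare_data(data, config.variant)
    S, p = data.S, data.p
    hyper = config.hyper
    use_graph = config.variant in ("coxbvs_sl", "sub_struct")
    include_between = config.variant == "coxbvs_sl"
    rng = np.random.default_rng(config.seed)

    grouped_list = [build_time_partition(sg) for sg in data.subgroups]
    X_list = [sg.covariates for sg in data.subgroups]
    S_mats = [X.T @ X for X in X_list]
    baseline = [fit_weibull_baseline(sg, a0=hyper.a0) for sg in data.subgroups]
    priors = [
        baseline_increment_prior(grouped_list[s], baseline[s]) for s in range(S)
    ]
    graph_hyper = GraphHyper.from_hyper(hyper, p) if use_graph else None

    state = initialize(data, hyper, rng)
    scales = np.full((S, p), config.initial_scale)
    accepted = np.zeros((S, p))
    window_accepted = np.zeros((S, p))

    n_within = p * (p - 1) // 2
    pairs = list(combinations(range(S), 2))
    iu = np.triu_indices(p, k=1)
    gamma_samples = np.empty((config.n_iter, S, p), dtype=np.uint8)
    beta_samples = np.empty((config.n_iter, S, p))
    h_samples = [np.empty((config.n_iter, g.J)) for g in grouped_list]
    within_samples = (
        np.empty((config.n_iter, S, n_within), dtype=np.uint8) if use_graph else None
    )
    between_samples = (
        np.empty((config.n_iter, len(pairs), p), dtype=np.uint8) if use_graph else None
    )
    loglik = np.empty(config.n_iter)

    for it in range(config.n_iter):
        if use_graph:
            for s in range(S):
                state.omega[s] = block_gibbs_update_precision(
                    S_mats[s], data[s].n, state.graph.within[s], state.omega[s],
                    graph_hyper, rng,
                )
            _update_graph(state, hyper, graph_hyper, include_between, rng)
        _update_gamma(state, hyper, use_mrf=use_graph, rng=rng)
        joint_flip_move(state, grouped_list, X_list, hyper, use_graph, rng)
        before = accepted.copy()
        exp_lps = update_beta(
            state, grouped_list, X_list, hyper, scales, accepted, rng,
            substeps=config.beta_substeps,
        )
        window_accepted += accepted - before
        update_h(state, grouped_list, exp_lps, priors, rng)

        # windowed scale adaptation, frozen after burn-in
        if (it + 1) % config.adapt_window == 0 and it < config.burn_in:
            rate = window_accepted / config.adapt_window
            scales *= np.where(rate > 0.44, 1.1, np.where(rate < 0.23, 0.9, 1.0))
            window_accepted[:] = 0.0

        gamma_samples[it] = state.gamma
        beta_samples[it] = state.beta
        for s in range(S):
            h_samples[s][it] = state.h[s]
        if use_graph:
            for s in range(S):
                within_samples[it, s] = state.graph.within[s][iu]
            for k, pr in enumerate(pairs):
                between_samples[it, k] = state.graph.between[pr]
        loglik[it] = sum(
            grouped_log_likelihood_fast(grouped_list[s], state.h[s], exp_lps[s])
            for s in range(S)
        )
        if not np.isfinite(loglik[it]):
            raise FloatingPointError(
                f"non-finite log-likelihood at iteration {it}; state dumped: "
                f"beta={state.beta!r}, h={state.h!r}"
            )

    return ChainResult(
        variant=config.variant,
        seed=config.seed,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        labels=data.labels,
        gene_names=data.gene_names,
        gamma_samples=gamma_samples,
        beta_samples=beta_samples,
        h_samples=h_samples,
        within_samples=within_samples,
        between_samples=between_samples,
        loglik=loglik,
        acceptance_rate=accepted / config.n_iter,
        boundaries=[g.boundaries for g in grouped_list],
        baseline=baseline,
        hyper=hyper,
    )
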