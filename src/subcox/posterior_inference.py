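"""Posterior summaries, variable selection rules and chain diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc_sampler import ChainResult

__all__ = [
    "PosteriorSummary",
    "summarize",
    "select_by_model_size",
    "median_probability_model",
    "bma_top_models",
    "summary_table",
    "autocorrelation",
    "running_mean",
    "batch_means_se",
]


@dataclass
class PosteriorSummary:
    """Empirical posterior summaries over post-burn-in iterations.

    Conditional summaries (restricted to iterations with gamma=1) are NaN for
    variables never selected; ``ever_selected`` flags them.
    """

    labels: list[str]
    gene_names: list[str]
    selection_prob: np.ndarray  # (S, p)
    marginal_mean_beta: np.ndarray
    marginal_sd_beta: np.ndarray
    conditional_mean_beta: np.ndarray
    conditional_sd_beta: np.ndarray
    ever_selected: np.ndarray  # (S, p) bool
    mean_model_size: np.ndarray  # (S,)
    mean_h: list[np.ndarray]


def summarize(chain: ChainResult, burn_in: int | None = None) -> PosteriorSummary:
    """Selection probabilities and coefficient summaries from one chain."""
    burn_in = chain.burn_in if burn_in is None else burn_in
    if not 0 <= burn_in < chain.n_iter:
        raise ValueError("require 0 <= burn_in < n_iter")
    g = chain.gamma_samples[burn_in:]  # (T, S, p)
    b = chain.beta_samples[burn_in:]
    sel = g.mean(axis=0)
    sel_count = g.sum(axis=0)
    ever = sel_count > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cond_mean = np.where(ever, (b * g).sum(axis=0) / sel_count, np.nan)
        cond_sq = np.where(ever, (b**2 * g).sum(axis=0) / sel_count, np.nan)
    cond_sd = np.sqrt(np.maximum(cond_sq - cond_mean**2, 0.0))
    return PosteriorSummary(
        labels=chain.labels,
        gene_names=chain.gene_names,
        selection_prob=sel,
        marginal_mean_beta=b.mean(axis=0),
        marginal_sd_beta=b.std(axis=0),
        conditional_mean_beta=cond_mean,
        conditional_sd_beta=cond_sd,
        ever_selected=ever,
        mean_model_size=g.sum(axis=2).mean(axis=0),
        mean_h=[h[burn_in:].mean(axis=0) for h in chain.h_samples],
    )


def select_by_model_size(summary: PosteriorSummary) -> list[np.ndarray]:
    """Mean-model-size rule: per subgroup, round the mean number of included
    variables half-to-even to m* and take the m* genes with the highest
    selection probability (ties broken by gene index)."""
    out = []
    for s in range(len(summary.labels)):
        m_star = int(np.round(summary.mean_model_size[s]))
        order = np.lexsort((np.arange(len(summary.gene_names)),
                            -summary.selection_prob[s]))
        out.append(np.sort(order[:m_star]))
    return out


def median_probability_model(
    summary: PosteriorSummary,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Median probability model: genes with selection probability strictly
    above 0.5; their coefficients are the marginal posterior means, all other
    coefficients 0."""
    selected = [np.flatnonzero(summary.selection_prob[s] > 0.5)
                for s in range(len(summary.labels))]
    coeffs = np.zeros_like(summary.marginal_mean_beta)
    for s, idx in enumerate(selected):
        coeffs[s, idx] = summary.marginal_mean_beta[s, idx]
    return selected, coeffs


def bma_top_models(
    chain: ChainResult,
    n_models: int = 100,
    burn_in: int | None = None,
    by: str = "models",
) -> np.ndarray:
    """Approximate model-averaged coefficients.

    ``by="models"``: rank the distinct gamma configurations visited after
    burn-in by the maximum joint log-likelihood attained, keep the top
    ``n_models``, and average beta over all iterations that belong to them.
    ``by="iterations"``: average beta over the ``n_models`` individual
    iterations with the largest log-likelihood.
    """
    burn_in = chain.burn_in if burn_in is None else burn_in
    g = chain.gamma_samples[burn_in:]
    b = chain.beta_samples[burn_in:]
    ll = chain.loglik[burn_in:]
    if by == "iterations":
        keep = np.argsort(ll)[::-1][:n_models]
        return b[keep].mean(axis=0)
    if by != "models":
        raise ValueError("by must be 'models' or 'iterations'")
    flat = g.reshape(len(g), -1)
    _, inverse = np.unique(flat, axis=0, return_inverse=True)
    n_distinct = inverse.max() + 1
    best_ll = np.full(n_distinct, -np.inf)
    np.maximum.at(best_ll, inverse, ll)
    if n_distinct < n_models:
        warnings.warn(
            f"only {n_distinct} distinct models visited (< {n_models}); using all"
        )
        n_models = n_distinct
    top = np.argsort(best_ll)[::-1][:n_models]
    mask = np.isin(inverse, top)
    return b[mask].mean(axis=0)


def summary_table(summary: PosteriorSummary) -> pd.DataFrame:
    """Per-gene CSV-ready table of posterior summaries and selections."""
    msize_sel = select_by_model_size(summary)
    mpm_sel, _ = median_probability_model(summary)
    rows = []
    for s, label in enumerate(summary.labels):
        for i, gene in enumerate(summary.gene_names):
            rows.append({
                "subgroup": label,
                "gene": gene,
                "selection_prob": summary.selection_prob[s, i],
                "marginal_mean": summary.marginal_mean_beta[s, i],
                "marginal_sd": summary.marginal_sd_beta[s, i],
                "conditional_mean": summary.conditional_mean_beta[s, i],
                "conditional_sd": summary.conditional_sd_beta[s, i],
                "selected_msize": i in msize_sel[s],
                "selected_mpm": i in mpm_sel[s],
            })
    return pd.DataFrame(rows)


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Empirical autocorrelation of a scalar trace at lags 0..max_lag."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    denom = float(x @ x)
    if denom == 0:
        return np.r_[1.0, np.zeros(min(max_lag, n - 1))]
    return np.array([x[: n - k] @ x[k:] / denom for k in range(min(max_lag, n - 1) + 1)])


def running_mean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.cumsum(x) / np.arange(1, len(x) + 1)


def batch_means_se(x: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the mean of a (correlated) trace via
    non-overlapping batch means."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    if m < 2:
        raise ValueError("trace too short for the requested number of batches")
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
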