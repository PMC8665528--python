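"""Joint graph and per-subgroup precision matrices.

The graph spans p*S nodes: within each subgroup an arbitrary undirected graph
over the p genes (adjacency ``G_ss``), and between any two subgroups only
same-gene edges (a diagonal block, stored as a length-p indicator vector per
subgroup pair). Each within-subgroup precision matrix carries a continuous
spike-and-slab prior: off-diagonal entries are normal with sd nu0 (edge
absent) or nu1 (edge present), diagonals are exponential, restricted to the
positive-definite cone. Sampling uses a column-wise block Gibbs sweep that
preserves positive definiteness by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import linalg
from scipy.special import expit, logit
from scipy.stats import norm

from .data_io import Hyperparameters

__all__ = [
    "GraphState",
    "GraphHyper",
    "expression_log_likelihood",
    "precision_prior_logpdf",
    "edge_conditional_within",
    "edge_conditional_between",
    "block_gibbs_update_precision",
    "edge_probability_table",
]


@dataclass
class GraphHyper:
    """Hyperparameters of the precision/graph prior."""

    nu0: float = 0.1
    nu1: float = 10.0
    lam: float = 1.0
    pi_G: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.nu0 < self.nu1:
            raise ValueError("require 0 < nu0 < nu1")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.pi_G < 1:
            raise ValueError("pi_G must lie in (0,1)")

    @classmethod
    def from_hyper(cls, hyper: Hyperparameters, p: int) -> "GraphHyper":
        return cls(
            nu0=hyper.nu0, nu1=hyper.nu1, lam=hyper.lam, pi_G=hyper.resolve_pi_G(p)
        )


@dataclass
class GraphState:
    """Edge indicators: ``within[s]`` is a symmetric zero-diagonal p x p binary
    matrix; ``between[(r, s)]`` (r < s) is a length-p binary vector of
    same-gene cross-subgroup edges."""

    within: np.ndarray  # (S, p, p) uint8
    between: dict[tuple[int, int], np.ndarray]

    def __post_init__(self) -> None:
        self.within = np.asarray(self.within)
        for s in range(self.within.shape[0]):
            W = self.within[s]
            if not np.array_equal(W, W.T) or np.diagonal(W).any():
                raise ValueError(f"within[{s}] must be symmetric with zero diagonal")

    @classmethod
    def empty(cls, S: int, p: int) -> "GraphState":
        return cls(
            within=np.zeros((S, p, p), dtype=np.uint8),
            between={
                (r, s): np.zeros(p, dtype=np.uint8) for r, s in combinations(range(S), 2)
            },
        )

    @property
    def S(self) -> int:
        return self.within.shape[0]

    @property
    def p(self) -> int:
        return self.within.shape[1]


def _chol_or_none(omega: np.ndarray):
    try:
        return np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        return None


def expression_log_likelihood(X: np.ndarray, omega: np.ndarray) -> float:
    """Multivariate-normal log-likelihood of a subgroup's expression matrix,
    (n/2) logdet(Omega) - tr(S Omega)/2 with S = X'X; the -(np/2) log(2 pi)
    constant is omitted."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L = _chol_or_none(omega)
    if L is None:
        raise ValueError("precision matrix is not positive definite")
    n = X.shape[0]
    logdet = 2.0 * float(np.sum(np.log(np.diagonal(L))))
    S = X.T @ X
    return 0.5 * n * logdet - 0.5 * float(np.trace(S @ omega))


def precision_prior_logpdf(
    omega: np.ndarray, G_ss: np.ndarray, hyper: GraphHyper
) -> float:
    """Log-density (unnormalized) of the spike-and-slab precision prior:
    N(omega_ij | 0, nu_{g_ij}^2) over i<j plus Exp(lam/2) on the diagonal;
    -inf outside the positive-definite cone."""
    if _chol_or_none(omega) is None:
        return -np.inf
    p = omega.shape[0]
    iu = np.triu_indices(p, k=1)
    sd = np.where(np.asarray(G_ss)[iu] == 1, hyper.nu1, hyper.nu0)
    out = float(np.sum(norm.logpdf(omega[iu], scale=sd)))
    rate = hyper.lam / 2.0
    diag = np.diagonal(omega)
    out += float(np.sum(np.log(rate) - rate * diag))
    return out


def edge_conditional_within(omega_ij, gamma_i, gamma_j, hyper: GraphHyper, b1: float):
    """Posterior inclusion probability of a within-subgroup edge given the
    corresponding precision entry and the selection indicators of its
    endpoints: odds = pi_G N(w|0,nu1^2) exp(2 b1 gi gj) / [(1-pi_G) N(w|0,nu0^2)].
    Vectorized over its arguments."""
    la = (
        np.log(hyper.pi_G)
        + norm.logpdf(omega_ij, scale=hyper.nu1)
        + 2.0 * b1 * np.asarray(gamma_i) * np.asarray(gamma_j)
    )
    lb = np.log1p(-hyper.pi_G) + norm.logpdf(omega_ij, scale=hyper.nu0)
    return expit(la - lb)


def edge_conditional_between(gamma_ri, gamma_si, hyper: GraphHyper, b2: float):
    """Posterior inclusion probability of a same-gene cross-subgroup edge:
    expit(logit(pi_G) + 2 b2 g_ri g_si). No precision entry exists for
    cross-subgroup pairs. Vectorized."""
    return expit(logit(hyper.pi_G) + 2.0 * b2 * np.asarray(gamma_ri) * np.asarray(gamma_si))


def block_gibbs_update_precision(
    S_mat: np.ndarray,
    n: int,
    G_ss: np.ndarray,
    omega: np.ndarray,
    hyper: GraphHyper,
    rng: np.random.Generator,
) -> np.ndarray:
    """One full column sweep of the block Gibbs sampler for Omega | G, X.

    For each column j (with S = X'X): the off-diagonal block is drawn from
    N(-C s_12, C) with C = [(s_jj + lam) Omega11^{-1} + diag(nu_g^{-2})]^{-1},
    and v = omega_jj - u' Omega11^{-1} u from Gamma(n/2 + 1, (s_jj + lam)/2).
    The update is a diffeomorphism of the PD cone, so the output stays PD.
    """
    omega = np.array(omega, dtype=float)
    p = omega.shape[0]
    if p == 1:
        omega[0, 0] = rng.gamma(n / 2.0 + 1.0, 2.0 / (S_mat[0, 0] + hyper.lam))
        return omega
    nu2 = np.where(np.asarray(G_ss) == 1, hyper.nu1**2, hyper.nu0**2)
    for j in range(p):
        idx = np.delete(np.arange(p), j)
        O11 = omega[np.ix_(idx, idx)]
        O11_chol = linalg.cho_factor(O11, lower=True)
        inv_O11 = linalg.cho_solve(O11_chol, np.eye(p - 1))
        s_jj = S_mat[j, j]
        C_inv = (s_jj + hyper.lam) * inv_O11 + np.diag(1.0 / nu2[idx, j])
        try:
            L = np.linalg.cholesky(C_inv)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"Cholesky failure in column {j}; omega=\n{omega}"
            ) from exc
        mean = -linalg.cho_solve((L, True), S_mat[idx, j])
        u = mean + linalg.solve_triangular(L.T, rng.standard_normal(p - 1), lower=False)
        v = rng.gamma(n / 2.0 + 1.0, 2.0 / (s_jj + hyper.lam))
        omega[idx, j] = omega[j, idx] = u
        omega[j, j] = v + float(u @ inv_O11 @ u)
    return omega


def edge_probability_table(
    within_prob: np.ndarray,
    between_prob: dict[tuple[int, int], np.ndarray],
    gene_names: list[str],
    labels: list[str],
):
    """Long-format table of posterior edge probabilities
    (subgroup_pair, gene_i, gene_j, probability)."""
    import pandas as pd

    rows = []
    S, p, _ = within_prob.shape
    for s in range(S):
        for i, j in combinations(range(p), 2):
            rows.append(
                (f"{labels[s]}-{labels[s]}", gene_names[i], gene_names[j],
                 float(within_prob[s, i, j]))
            )
    for (r, s), probs in between_prob.items():
        for i in range(p):
            rows.append(
                (f"{labels[r]}-{labels[s]}", gene_names[i], gene_names[i],
                 float(probs[i]))
            )
    return pd.DataFrame(
        rows, columns=["subgroup_pair", "gene_i", "gene_j", "probability"]
    )
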