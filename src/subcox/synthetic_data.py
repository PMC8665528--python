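"""Synthetic-data engine: block-structured expression, Weibull survival
calibrated from Kaplan-Meier survival probabilities, and plasmode resampling.

Two study designs are generated:

* gene-panel design: two subgroups sharing one multivariate-normal expression
  distribution (unit variances; partial correlations of magnitude 0.5 inside
  three 3-gene blocks among the first nine genes) with subgroup-specific
  effect vectors (1,1,1,-1,-1,-1,0,...) and (0,0,0,-1,-1,-1,1,1,1,0,...), and
  Weibull event/censoring times whose (eta, kappa) are calibrated so the
  marginal survival hits 57%/42% (subgroup 1) and 75%/62% (subgroup 2) at 3
  and 5 years;
* plasmode design: rows of a supplied (real) expression matrix are split into
  two equal subgroups, keeping the empirical correlation structure, while the
  survival outcome is simulated from chosen effects (the bundled 20-protein
  effect pattern groups proteins by phosphorylation site so related columns
  share effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MultiSubgroupData, SubgroupDataset

__all__ = [
    "ScenarioConfig",
    "KMCalibration",
    "COHORT_CALIBRATIONS",
    "block_precision_sigma",
    "simulate_expression",
    "calibrate_weibull_from_km",
    "simulate_survival",
    "scenario_I_effects",
    "make_scenario_I",
    "scenario_II_effects",
    "fabricate_protein_matrix",
    "make_plasmode",
]


@dataclass
class KMCalibration:
    """Two Kaplan-Meier anchor points S(t1)=S1, S(t2)=S2 with t1 < t2."""

    t1: float
    t2: float
    S1: float
    S2: float

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2:
            raise ValueError("require 0 < t1 < t2")
        if not 0 < self.S2 < self.S1 < 1:
            raise ValueError("require 0 < S2 < S1 < 1")


#: 3- and 5-year survival anchors of the two calibration cohorts.
COHORT_CALIBRATIONS = (
    KMCalibration(t1=3.0, t2=5.0, S1=0.57, S2=0.42),
    KMCalibration(t1=3.0, t2=5.0, S1=0.75, S2=0.62),
)


@dataclass
class ScenarioConfig:
    """Study conditions of the gene-panel design (two subgroups)."""

    p: int = 20
    n_per_subgroup: int = 100
    rho: float = 0.5
    seed: int = 0
    effects: np.ndarray | None = None  # default: scenario_I_effects(p)
    calibrations: tuple[KMCalibration, KMCalibration] = COHORT_CALIBRATIONS
    blocks: list[list[int]] = field(
        default_factory=lambda: [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
    )


def block_precision_sigma(
    p: int,
    blocks: list[list[int]],
    rho: float = 0.5,
    precision_sign: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured precision and covariance with unit variances.

    Within each block the standardized precision has off-diagonals
    ``precision_sign * rho`` (the partial correlation is the negative of
    that); all other off-diagonals are 0. Sigma is the inverse rescaled to
    diag(Sigma) = 1 and Omega recomputed consistently, which leaves the
    partial correlations unchanged. Note: requesting partial correlations of
    exactly +0.5 in a 3-block (precision off-diagonal -0.5) is singular and
    raises.
    """
    seen: set[int] = set()
    for blk in blocks:
        if seen & set(blk):
            raise ValueError("blocks must be disjoint")
        seen |= set(blk)
        if max(blk) >= p:
            raise ValueError("block index out of range")
    omega = np.eye(p)
    for blk in blocks:
        for i in blk:
            for j in blk:
                if i != j:
                    omega[i, j] = precision_sign * rho
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals.min() <= 1e-10:
        raise ValueError(
            f"requested precision is not positive definite (min eigenvalue "
            f"{eigvals.min():.3g}); e.g. a 3-block with off-diagonal -0.5 "
            f"(partial correlation +0.5) has eigenvalue 0"
        )
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diagonal(sigma))
    sigma = sigma / np.outer(d, d)
    omega = np.linalg.inv(sigma)
    return omega, sigma


def simulate_expression(
    sigma: np.ndarray, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n i.i.d. multivariate-normal rows with mean 0 and covariance sigma."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, sigma.shape[0])) @ L.T


def calibrate_weibull_from_km(cal: KMCalibration) -> tuple[float, float]:
    """Exact two-point inversion of S(t) = exp(-eta t^kappa).

    kappa = log(log S1 / log S2) / log(t1 / t2), eta = -log(S1) / t1^kappa.
    """
    kappa = np.log(np.log(cal.S1) / np.log(cal.S2)) / np.log(cal.t1 / cal.t2)
    eta = -np.log(cal.S1) / cal.t1**kappa
    return float(eta), float(kappa)


def simulate_survival(
    X: np.ndarray,
    beta: np.ndarray,
    eta: float,
    kappa: float,
    seed: int | np.random.Generator,
    censoring: str = "covariate_free",
    cens_eta: float | None = None,
    cens_kappa: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull event and censoring times by inverse-transform sampling.

    T = (-log U / (eta exp(x beta)))^(1/kappa). Censoring times come from a
    Weibull with the same (eta, kappa) unless overridden; by default the
    censoring draw omits the covariate term (non-informative censoring),
    ``censoring="covariate_matched"`` includes it. Returns (observed time,
    event indicator).
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    lp = X @ np.asarray(beta, dtype=float)
    n = len(lp)
    ce = eta if cens_eta is None else cens_eta
    ck = kappa if cens_kappa is None else cens_kappa
    T = (-np.log(rng.random(n)) / (eta * np.exp(lp))) ** (1.0 / kappa)
    if censoring == "covariate_free":
        C = (-np.log(rng.random(n)) / ce) ** (1.0 / ck)
    elif censoring == "covariate_matched":
        C = (-np.log(rng.random(n)) / (ce * np.exp(lp))) ** (1.0 / ck)
    else:
        raise ValueError("censoring must be 'covariate_free' or 'covariate_matched'")
    event = (T <= C).astype(int)
    return np.minimum(T, C), event


def scenario_I_effects(p: int) -> np.ndarray:
    """True effect vectors of the gene-panel design: genes 1-3 and 7-9 are
    subgroup-specific, genes 4-6 share one effect, the rest is noise."""
    if p < 9:
        raise ValueError("need p >= 9")
    beta = np.zeros((2, p))
    beta[0, 0:3] = 1.0
    beta[0, 3:6] = -1.0
    beta[1, 3:6] = -1.0
    beta[1, 6:9] = 1.0
    return beta


def _simulate_subgroups(
    sigma: np.ndarray,
    effects: np.ndarray,
    weibulls: list[tuple[float, float]],
    n: int,
    rng: np.random.Generator,
    censoring: str,
) -> MultiSubgroupData:
    subgroups = []
    for s in range(effects.shape[0]):
        X = simulate_expression(sigma, n, rng)
        eta, kappa = weibulls[s]
        time, event = simulate_survival(X, effects[s], eta, kappa, rng, censoring)
        subgroups.append(
            SubgroupDataset(covariates=X, time=time, event=event, subgroup_id=f"S{s+1}")
        )
    p = sigma.shape[0]
    return MultiSubgroupData(subgroups, [f"gene{i+1}" for i in range(p)])


def make_scenario_I(
    config: ScenarioConfig, censoring: str = "covariate_free"
) -> tuple[MultiSubgroupData, MultiSubgroupData, dict]:
    """Generate one train/test replicate of the gene-panel design.

    Both subgroups share the block-structured covariance; survival follows the
    per-cohort calibrated Weibulls. Returns (train, test, truth) where truth
    records the effects, precision/covariance and Weibull parameters.
    """
    rng = np.random.default_rng(config.seed)
    effects = (
        scenario_I_effects(config.p) if config.effects is None
        else np.asarray(config.effects, dtype=float)
    )
    omega, sigma = block_precision_sigma(config.p, config.blocks, config.rho)
    weibulls = [calibrate_weibull_from_km(c) for c in config.calibrations]
    train = _simulate_subgroups(
        sigma, effects, weibulls, config.n_per_subgroup, rng, censoring
    )
    test = _simulate_subgroups(
        sigma, effects, weibulls, config.n_per_subgroup, rng, censoring
    )
    truth = {"effects": effects, "omega": omega, "sigma": sigma, "weibull": weibulls}
    return train, test, truth


#: Bundled 20-protein effect pattern: groups of phospho-sites/isoforms of the
#: same protein share an effect so that they can learn from each other.
_PROTEIN_EFFECTS = [
    ("Akt", 2.0, 0.0),
    ("Akt_pS473", 2.0, 0.0),
    ("Akt_pT308", 2.0, 0.0),
    ("EGFR", 0.0, 2.0),
    ("EGFR_pY1068", 0.0, 2.0),
    ("EGFR_pY1173", 0.0, 2.0),
    ("AMPK_alpha", -1.5, 1.5),
    ("Annexin.1", 1.5, -1.5),
    ("GSK3.alpha.beta", -2.0, -2.0),
    ("GSK3.alpha.beta_pS21_S9", -2.0, -2.0),
    ("GSK3_pS9", -2.0, -2.0),
    ("X14.3.3_beta", 0.0, 0.0),
    ("X14.3.3_epsilon", 0.0, 0.0),
    ("X14.3.3_zeta", 0.0, 0.0),
    ("X4E.BP1", 0.0, 0.0),
    ("X4E.BP1_pS65", 0.0, 0.0),
    ("X4E.BP1_pT37T46", 0.0, 0.0),
    ("X4E.BP1_pT70", 0.0, 0.0),
    ("X53BP1", 0.0, 0.0),
    ("A.Raf_pS299", 0.0, 0.0),
]

#: Column groups sharing a latent factor in the fabricated matrix.
_PROTEIN_GROUPS = [[0, 1, 2], [3, 4, 5], [8, 9, 10], [11, 12, 13], [14, 15, 16, 17]]


def scenario_II_effects() -> tuple[list[str], np.ndarray]:
    """Protein names and the 2 x 20 effect matrix of the plasmode design."""
    names = [row[0] for row in _PROTEIN_EFFECTS]
    beta = np.array([[row[1] for row in _PROTEIN_EFFECTS],
                     [row[2] for row in _PROTEIN_EFFECTS]])
    return names, beta


def fabricate_protein_matrix(n: int = 212, seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a real 20-protein expression matrix.

    Columns belonging to the same protein (isoforms/phospho-sites) load on a
    shared latent factor (correlations ~0.6 within groups) on top of
    independent noise, emulating the correlation structure of phospho-protein
    panels. Purely synthetic; no real measurements.
    """
    rng = np.random.default_rng(seed)
    names, _ = scenario_II_effects()
    p = len(names)
    X = rng.standard_normal((n, p))
    for grp in _PROTEIN_GROUPS:
        factor = rng.standard_normal(n)
        for j in grp:
            X[:, j] = np.sqrt(0.6) * factor + np.sqrt(0.4) * X[:, j]
    return pd.DataFrame(X, columns=names,
                        index=[f"sample{i+1}" for i in range(n)])


def make_plasmode(
    expression: pd.DataFrame,
    effects: np.ndarray | None = None,
    weibulls: list[tuple[float, float]] | None = None,
    cens_weibulls: list[tuple[float, float]] | None = None,
    seed: int = 0,
) -> MultiSubgroupData:
    """Plasmode design: keep a real expression matrix, simulate the outcome.

    Rows are randomly split into two equal subgroups (deterministic given
    ``seed``); survival is simulated per subgroup from the supplied Weibull
    parameters (default: the two cohort calibrations) with the given effects
    (default: the bundled 20-protein pattern when the columns match it).
    """
    if expression.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 columns")
    rng = np.random.default_rng(seed)
    n = len(expression)
    perm = rng.permutation(n)
    half = n // 2
    groups = [np.sort(perm[:half]), np.sort(perm[half:])]
    if effects is None:
        names, effects = scenario_II_effects()
        if list(expression.columns) != names:
            raise ValueError(
                "default effects require the bundled 20-protein column layout; "
                "pass `effects` explicitly"
            )
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (2, expression.shape[1]):
        raise ValueError("effects must have shape (2, n_columns)")
    if weibulls is None:
        weibulls = [calibrate_weibull_from_km(c) for c in COHORT_CALIBRATIONS]
    subgroups = []
    for s, idx in enumerate(groups):
        X = expression.iloc[idx].to_numpy(dtype=float)
        eta, kappa = weibulls[s]
        ce, ck = (eta, kappa) if cens_weibulls is None else cens_weibulls[s]
        time, event = simulate_survival(
            X, effects[s], eta, kappa, rng, cens_eta=ce, cens_kappa=ck
        )
        subgroups.append(
            SubgroupDataset(
                covariates=X, time=time, event=event, subgroup_id=f"S{s+1}",
                patient_ids=[str(expression.index[i]) for i in idx],
            )
        )
    return MultiSubgroupData(subgroups, list(expression.columns))
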