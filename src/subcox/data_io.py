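"""Tabular input/output, standardization, stratified splitting and configuration.

Survival tables are delimited text (comma or tab, autodetected) with columns
``id, time, status, subgroup``; covariate tables have an ``id`` column followed
by one column per gene. Patient ids are treated as strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SubgroupDataset",
    "MultiSubgroupData",
    "StandardizationParams",
    "Hyperparameters",
    "CASE_STUDY_PRESET",
    "load_multi_subgroup",
    "write_multi_subgroup",
    "standardize",
    "apply_standardization",
    "stratified_split",
    "load_config",
]


@dataclass
class SubgroupDataset:
    """Covariates and right-censored survival outcome for one patient subgroup."""

    covariates: np.ndarray  # (n_s, p) continuous
    time: np.ndarray  # (n_s,) strictly positive observed times
    event: np.ndarray  # (n_s,) 1 = event, 0 = right-censored
    subgroup_id: str
    patient_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.covariates.shape[0]
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError(f"subgroup {self.subgroup_id!r}: inconsistent row counts")
        if np.isnan(self.covariates).any() or np.isnan(self.time).any():
            raise ValueError(f"subgroup {self.subgroup_id!r}: missing values")
        if (self.time <= 0).any():
            bad = np.flatnonzero(self.time <= 0)
            raise ValueError(
                f"subgroup {self.subgroup_id!r}: non-positive time at rows {bad.tolist()}"
            )
        if not np.isin(self.event, [0, 1]).all():
            bad = np.flatnonzero(~np.isin(self.event, [0, 1]))
            raise ValueError(
                f"subgroup {self.subgroup_id!r}: status not in {{0,1}} at rows {bad.tolist()}"
            )

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]


@dataclass
class MultiSubgroupData:
    """Ordered collection of subgroups sharing one gene panel."""

    subgroups: list[SubgroupDataset]
    gene_names: list[str]

    def __post_init__(self) -> None:
        p = len(self.gene_names)
        labels = [sg.subgroup_id for sg in self.subgroups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate subgroup labels: {labels}")
        for sg in self.subgroups:
            if sg.p != p:
                raise ValueError(
                    f"subgroup {sg.subgroup_id!r} has {sg.p} columns, expected {p}"
                )

    @property
    def S(self) -> int:
        return len(self.subgroups)

    @property
    def p(self) -> int:
        return len(self.gene_names)

    @property
    def labels(self) -> list[str]:
        return [sg.subgroup_id for sg in self.subgroups]

    def __getitem__(self, s: int) -> SubgroupDataset:
        return self.subgroups[s]


@dataclass
class StandardizationParams:
    """Per-column location/scale learned on training data."""

    means: np.ndarray
    sds: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if (self.sds <= 0).any():
            bad = [self.gene_names[i] for i in np.flatnonzero(self.sds <= 0)]
            raise ValueError(f"zero-variance columns: {bad}")


@dataclass
class Hyperparameters:
    """Fixed hyperparameters of the model.

    a0       weight of the parametric guess in the gamma-process baseline prior
    tau, c   spike sd and slab inflation of the coefficient mixture prior
    a, b1, b2  MRF prior: sparsity offset, within- and between-subgroup edge reward
    nu0, nu1 spike/slab sds for off-diagonal precision entries
    lam      rate parameter (times 1/2) of the exponential prior on precision diagonals
    pi_G     prior edge-inclusion probability (None -> 2/(p-1) at fit time)
    pi_gamma Bernoulli prior inclusion probability (Subgroup/Pooled variants)
    """

    a0: float = 2.0
    tau: float = 0.0375
    c: float = 20.0
    a: float = -4.0
    b1: float = 1.0
    b2: float = 1.0
    nu0: float = 0.1
    nu1: float = 10.0
    lam: float = 1.0
    pi_G: float | None = None
    pi_gamma: float = 0.02

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.tau <= 0 or self.lam <= 0:
            raise ValueError("a0, tau and lam must be positive")
        if self.c <= 1:
            raise ValueError("c must exceed 1")
        if self.b1 < 0 or self.b2 < 0:
            raise ValueError("b1 and b2 must be non-negative")
        if not 0 < self.nu0 < self.nu1:
            raise ValueError("require 0 < nu0 < nu1")
        if self.pi_G is not None and not 0 < self.pi_G < 1:
            raise ValueError("pi_G must lie in (0,1)")
        if not 0 < self.pi_gamma < 1:
            raise ValueError("pi_gamma must lie in (0,1)")

    def resolve_pi_G(self, p: int) -> float:
        # default 2/(p-1) targets a mean of ~2 neighbours per node; clipped so
        # tiny panels still give a valid probability
        return self.pi_G if self.pi_G is not None else min(0.5, 2.0 / (p - 1))


#: Hyperparameter preset used for protein-panel plasmode analyses.
CASE_STUDY_PRESET = Hyperparameters(
    a=-1.75, b1=0.5, b2=0.5, nu0=0.6, nu1=360.0, pi_gamma=0.2
)


def _read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype={"id": str})


def load_multi_subgroup(table_path, covariate_path) -> MultiSubgroupData:
    """Load a survival table and a covariate table keyed by patient id."""
    surv = _read_table(table_path)
    required = {"id", "time", "status", "subgroup"}
    if not required.issubset(surv.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    cov = _read_table(covariate_path)
    if cov.columns[0] != "id":
        raise ValueError("covariate table must start with an 'id' column")
    cov = cov.set_index("id")
    if cov.isna().any().any():
        raise ValueError("covariate table contains missing values")
    missing = set(surv["id"]) - set(cov.index)
    if missing:
        raise ValueError(f"ids without covariate rows: {sorted(missing)}")
    gene_names = list(cov.columns)

    subgroups = []
    for label, grp in surv.groupby("subgroup", sort=True):
        bad = grp.loc[~grp["status"].isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"non-binary status for ids {bad['id'].tolist()} (subgroup {label!r})"
            )
        subgroups.append(
            SubgroupDataset(
                covariates=cov.loc[grp["id"]].to_numpy(dtype=float),
                time=grp["time"].to_numpy(dtype=float),
                event=grp["status"].to_numpy(dtype=int),
                subgroup_id=str(label),
                patient_ids=grp["id"].tolist(),
            )
        )
    return MultiSubgroupData(subgroups=subgroups, gene_names=gene_names)


def write_multi_subgroup(data: MultiSubgroupData, table_path, covariate_path) -> None:
    """Inverse of :func:`load_multi_subgroup` (round-trip safe)."""
    rows, covs = [], []
    for sg in data.subgroups:
        ids = sg.patient_ids or [f"{sg.subgroup_id}_{m}" for m in range(sg.n)]
        for m, pid in enumerate(ids):
            rows.append((pid, sg.time[m], sg.event[m], sg.subgroup_id))
        covs.append(pd.DataFrame(sg.covariates, index=ids, columns=data.gene_names))
    pd.DataFrame(rows, columns=["id", "time", "status", "subgroup"]).to_csv(
        table_path, index=False
    )
    pd.concat(covs).rename_axis("id").to_csv(covariate_path)


def _fit_params(X: np.ndarray, gene_names: list[str]) -> StandardizationParams:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if (sds <= 0).any():
        bad = [gene_names[i] for i in np.flatnonzero(sds <= 0)]
        raise ValueError(f"zero-variance columns: {bad}")
    return StandardizationParams(means=means, sds=sds, gene_names=gene_names)


def standardize(
    data: MultiSubgroupData, mode: Literal["per_subgroup", "pooled"] = "per_subgroup"
) -> tuple[MultiSubgroupData, dict[str, StandardizationParams]]:
    """Scale training covariates to mean 0 / sample sd 1 (denominator n-1).

    Returns the scaled data and the learned parameters per scope ("pooled" or
    one entry per subgroup label), for re-use on test data via
    :func:`apply_standardization`.
    """
    if mode == "pooled":
        X = np.vstack([sg.covariates for sg in data.subgroups])
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to standardize")
        params = {"pooled": _fit_params(X, data.gene_names)}
    elif mode == "per_subgroup":
        params = {}
        for sg in data.subgroups:
            if sg.n < 2:
                raise ValueError(f"subgroup {sg.subgroup_id!r}: need >= 2 rows")
            params[sg.subgroup_id] = _fit_params(sg.covariates, data.gene_names)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return apply_standardization(data, params), params


def apply_standardization(
    data: MultiSubgroupData, params: dict[str, StandardizationParams]
) -> MultiSubgroupData:
    """Apply previously learned (training) location/scale to `data`."""
    out = []
    for sg in data.subgroups:
        pr = params["pooled"] if "pooled" in params else params[sg.subgroup_id]
        out.append(
            SubgroupDataset(
                covariates=(sg.covariates - pr.means) / pr.sds,
                time=sg.time,
                event=sg.event,
                subgroup_id=sg.subgroup_id,
                patient_ids=sg.patient_ids,
            )
        )
    return MultiSubgroupData(subgroups=out, gene_names=data.gene_names)


def stratified_split(
    data: MultiSubgroupData, train_fraction: float, seed: int
) -> tuple[MultiSubgroupData, MultiSubgroupData]:
    """Split into train/test preserving (subgroup x event) strata proportions."""
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must lie in (0, 1]")
    if train_fraction == 1.0:
        warnings.warn("train_fraction is 1.0; the test set will be empty")
    rng = np.random.default_rng(seed)
    train_sgs, test_sgs = [], []
    for sg in data.subgroups:
        tr_idx: list[int] = []
        te_idx: list[int] = []
        for ev in (0, 1):
            stratum = np.flatnonzero(sg.event == ev)
            if len(stratum) < 2:
                raise ValueError(
                    f"stratum (subgroup={sg.subgroup_id!r}, event={ev}) has "
                    f"{len(stratum)} members; need >= 2"
                )
            perm = rng.permutation(stratum)
            n_train = int(round(train_fraction * len(stratum)))
            tr_idx.extend(perm[:n_train])
            te_idx.extend(perm[n_train:])
        for idx, dest in ((sorted(tr_idx), train_sgs), (sorted(te_idx), test_sgs)):
            dest.append(
                SubgroupDataset(
                    covariates=sg.covariates[idx],
                    time=sg.time[idx],
                    event=sg.event[idx],
                    subgroup_id=sg.subgroup_id,
                    patient_ids=[sg.patient_ids[i] for i in idx]
                    if sg.patient_ids
                    else None,
                )
            )
    return (
        MultiSubgroupData(train_sgs, data.gene_names),
        MultiSubgroupData(test_sgs, data.gene_names),
    )


def load_config(path) -> dict:
    """Load a flat YAML configuration; hyperparameter keys become a
    :class:`Hyperparameters` under key ``"hyper"``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    hyper_keys = set(Hyperparameters.__dataclass_fields__)
    hyper = Hyperparameters(**{k: v for k, v in raw.items() if k in hyper_keys})
    cfg = {k: v for k, v in raw.items() if k not in hyper_keys}
    cfg["hyper"] = hyper
    return cfg
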