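import numpy as np
import pytest

from subcox import MultiSubgroupData, SubgroupDataset


@pytest.fixture
def toy_tables(tmp_path):
    """Two-subgroup, four-patient survival + covariate CSVs."""
    surv = tmp_path / "surv.csv"
    cov = tmp_path / "cov.csv"
    surv.write_text(
        "id,time,status,subgroup\n"
        "p1,2.0,1,A\np2,5.0,0,A\np3,1.5,1,B\np4,3.0,1,B\n"
    )
    cov.write_text(
        "id,g1,g2\np1,0.1,1.0\np2,-0.2,2.0\np3,0.3,3.0\np4,0.4,4.0\n"
    )
    return surv, cov


def make_dataset(time, event, X=None, label="A", seed=0):
    time = np.asarray(time, dtype=float)
    if X is None:
        X = np.random.default_rng(seed).standard_normal((len(time), 2))
    return SubgroupDataset(
        covariates=np.asarray(X, dtype=float),
        time=time,
        event=np.asarray(event, dtype=int),
        subgroup_id=label,
    )


@pytest.fixture
def small_multi():
    rng = np.random.default_rng(42)
    sgs = []
    for label in ("A", "B"):
        n = 30
        X = rng.standard_normal((n, 3))
        time = rng.exponential(2.0, n) + 0.01
        event = rng.integers(0, 2, n)
        event[:4] = [0, 0, 1, 1]  # ensure both strata populated
        sgs.append(SubgroupDataset(X, time, event, label))
    return MultiSubgroupData(sgs, ["g1", "g2", "g3"])
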