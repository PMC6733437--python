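import numpy as np
import pandas as pd
import pytest

from crcrisk.cohort import PROTEINS
from crcrisk.synthetic import default_crc_like_config, generate_cohort


def make_cohort(times, events, proteins=None, **clinical) -> pd.DataFrame:
    """Small hand-built cohort frame with valid schema."""
    n = len(times)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)]})
    X = np.asarray(proteins, float) if proteins is not None \
        else rng.uniform(1, 50, size=(n, 5))
    for j, p in enumerate(PROTEINS):
        df[p] = X[:, j]
    df["os_time"] = np.asarray(times, float)
    df["event"] = np.asarray(events, int)
    for k, v in clinical.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def crc_like_cohort() -> pd.DataFrame:
    """One default synthetic cohort (n=134), shared across tests."""
    return generate_cohort(default_crc_like_config(seed=1))


@pytest.fixture(scope="session")
def structured_cohort() -> pd.DataFrame:
    """Larger synthetic cohort with a strong protein-driven hazard."""
    return generate_cohort(default_crc_like_config(seed=7, n=400))


def naive_efron_loglik(beta, X, times, events) -> float:
    """Independent loop implementation of the Efron partial log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(times):
        X = X.T
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for ut in np.unique(times[events == 1]):
        dead = (times == ut) & (events == 1)
        risk = times >= ut
        d = int(dead.sum())
        ll += eta[dead].sum()
        sR = w[risk].sum()
        sD = w[dead].sum()
        for j in range(d):
            ll -= np.log(sR - (j / d) * sD)
    return float(ll)
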