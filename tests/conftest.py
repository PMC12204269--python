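import numpy as np
import pandas as pd
import pytest

from parity_gxe.simcohort import SimConfig, simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_samples=600,
        n_variants=120,
        n_blocks=12,
        ld_rho=0.8,
        n_causal=30,
        h2_by_stratum={"first": 0.3, "later": 0.3},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(DosageMatrix, SimulatedCohort) reused across read-only tests."""
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_genotypes(small_sim):
    return small_sim[0]


def ols_oracle(y, X):
    """Independent normal-equations + t-CDF reference for every OLS fit.

    Solves X'X b = X'y directly and computes coefficient SEs from
    sigma2 (X'X)^-1 with sigma2 = RSS/(n-p); p-values from the exact t
    distribution.  Deliberately naive: no QR, no projections.
    """
    from scipy import stats

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, pvals, df


def clean_registry(n=10, gd=280.0, bw=3500.0, parity=None):
    """Minimal well-formed registry frame for filter tests."""
    parity = np.zeros(n, dtype=int) if parity is None else np.asarray(parity)
    return pd.DataFrame(
        {
            "mother_id": [f"M{i}" for i in range(n)],
            "child_id": [f"M{i}-C1" for i in range(n)],
            "delivery_order": parity + 1,
            "parity": parity,
            "gestational_duration": gd,
            "birth_weight": bw + 10.0 * np.arange(n),  # non-degenerate SD
            "sex": "female",
            "maternal_age": 30.0,
            "chip": "chipA",
            "art": False,
            "plurality": 1,
            "malformation": False,
            "perinatal_death": False,
            "death_first_year": False,
            "spontaneous_onset": True,
        }
    )
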