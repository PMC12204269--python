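"""SNP x parity interaction tests with Bonferroni control.

The model is the GWAS regression augmented with a binary environment
indicator (0 = first pregnancy, 1 = later pregnancies) and its product with
the dosage:

    y ~ 1 + g + env + g*env + C

The reported test is the two-sided t test of the g*env coefficient.  With no
covariates the interaction coefficient equals the difference of the two
stratum-specific slopes exactly.  The same code path serves candidate-variant
mode (a handful of previously known loci, per-phenotype Bonferroni) and
genome-wide mode; only the multiplicity denominator differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import CollinearityError, MIN_MAC, _covariate_basis, _project_out
from .simcohort import DosageMatrix

FAMILY_ALPHA = 0.05


@dataclass
class InteractionFit:
    beta_snp: float
    beta_env: float
    beta_inter: float
    se_inter: float
    p_inter: float
    n: int


def fit_interaction(
    y: np.ndarray,
    g: np.ndarray,
    env: np.ndarray,
    C: np.ndarray | None = None,
) -> InteractionFit:
    """OLS of y on [1, g, env, g*env, C]; reports the g*env coefficient."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    env = np.asarray(env, dtype=float)
    n = y.size
    if np.all(env == env[0]):
        raise CollinearityError("environment indicator is constant")
    C = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    X = np.column_stack([np.ones(n), g, env, g * env, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            "interaction design is rank deficient "
            "(constant dosage, constant env, or collinear covariates)"
        )
    k = X.shape[1] - 1
    df = n - k - 1
    if df < 1:
        raise ValueError("too few samples for the interaction model")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se3 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    if se3 == 0.0:
        p3 = 1.0 if beta[3] == 0 else 0.0
    else:
        p3 = float(2.0 * stats.t.sf(abs(beta[3] / se3), df))
    return InteractionFit(
        beta_snp=float(beta[1]),
        beta_env=float(beta[2]),
        beta_inter=float(beta[3]),
        se_inter=se3,
        p_inter=max(p3, np.finfo(float).tiny),
        n=n,
    )


def run_interaction_scan(
    y: np.ndarray,
    g: DosageMatrix,
    env: np.ndarray,
    C: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
    family_alpha: float = FAMILY_ALPHA,
) -> tuple[pd.DataFrame, float]:
    """Interaction test for every variant (or a candidate list).

    Vectorised via Frisch-Waugh: y, g and g*env are residualised on
    [1, env, C] once, then each variant needs only a 2x2 solve.  Returns the
    per-variant table and the Bonferroni threshold family_alpha / n_tests
    over the tested (non-degenerate) variants.
    """
    y = np.asarray(y, dtype=float)
    env = np.asarray(env, dtype=float)
    n = y.size
    if np.all(env == env[0]):
        raise CollinearityError("environment indicator is constant")
    C = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    gm = g if variant_ids is None else g.subset_variants(variant_ids)
    G = gm.dosages.astype(np.float64)
    GE = G * env[:, None]
    k = 3 + C.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError("too few samples for the interaction model")

    Z = np.column_stack([env, C])
    Q = _covariate_basis(Z)
    y_r = _project_out(Q, y[:, None])[:, 0]
    G_r = _project_out(Q, G)
    GE_r = _project_out(Q, GE)

    a11 = np.einsum("ij,ij->j", G_r, G_r)
    a22 = np.einsum("ij,ij->j", GE_r, GE_r)
    a12 = np.einsum("ij,ij->j", G_r, GE_r)
    b1 = G_r.T @ y_r
    b2 = GE_r.T @ y_r
    yy = float(y_r @ y_r)

    det = a11 * a22 - a12**2
    mac = np.minimum(G.sum(axis=0), 2 * n - G.sum(axis=0))
    # testable: enough copies of the minor allele in both env groups
    mac0 = np.minimum(G[env == 0].sum(axis=0), 2 * (env == 0).sum() - G[env == 0].sum(axis=0))
    mac1 = np.minimum(G[env == 1].sum(axis=0), 2 * (env == 1).sum() - G[env == 1].sum(axis=0))
    ok = (mac >= MIN_MAC) & (det > 1e-10 * np.maximum(a11 * a22, 1e-300)) & (mac0 >= 1) & (mac1 >= 1)

    m = G.shape[1]
    beta_g = np.full(m, np.nan)
    beta_env = np.full(m, np.nan)
    beta_ge = np.full(m, np.nan)
    se_ge = np.full(m, np.nan)
    p_ge = np.full(m, np.nan)
    beta_g[ok] = (a22[ok] * b1[ok] - a12[ok] * b2[ok]) / det[ok]
    beta_ge[ok] = (a11[ok] * b2[ok] - a12[ok] * b1[ok]) / det[ok]
    rss = yy - (beta_g[ok] * b1[ok] + beta_ge[ok] * b2[ok])
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se_ge[ok] = np.sqrt(sigma2 * a11[ok] / det[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_ge[ok] / se_ge[ok]
    p_ge[ok] = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)

    # env main effect: Z-block coefficients of the full model are
    # (X0'X0)^-1 X0' (y - g*beta_g - g.env*beta_ge), with X0 = [1, env, C]
    X0 = np.column_stack([np.ones(n), Z])
    A = np.linalg.solve(X0.T @ X0, X0.T)  # (k0, n)
    a_env = A[1]
    beta_env[ok] = (a_env @ y) - (a_env @ G[:, ok]) * beta_g[ok] - (
        a_env @ GE[:, ok]
    ) * beta_ge[ok]

    out = gm.variants[["chrom", "pos", "id"]].copy()
    out["beta_snp"] = beta_g
    out["beta_env"] = beta_env
    out["beta_inter"] = beta_ge
    out["se_inter"] = se_ge
    out["p_inter"] = p_ge
    out["n"] = n
    out["reason"] = np.where(ok, "", "low_mac")
    n_tests = int(ok.sum())
    alpha_bonf = family_alpha / n_tests if n_tests else np.nan
    return out, alpha_bonf


def bonferroni(
    p_values: pd.Series | dict[str, float], family_alpha: float = FAMILY_ALPHA
) -> tuple[float, list[str]]:
    """Family-wise control: alpha_bonf = family_alpha / n_tests; ids with
    p strictly below the threshold are significant."""
    s = pd.Series(p_values, dtype=float)
    if len(s) == 0:
        raise ValueError("empty p-value set: n_tests must be >= 1")
    alpha_bonf = family_alpha / len(s)
    hits = s.index[s < alpha_bonf].tolist()
    return alpha_bonf, hits
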