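"""LD scores and LD-score regression: SNP heritability and cross-stratum
genetic correlation with block-jackknife standard errors.

The LD score of variant j is ell_j = sum over variants k within a base-pair
window (same chromosome, self included) of the squared dosage correlation
r2_jk; with ``adjusted=True`` each cross term uses the finite-sample
bias-corrected estimator r2 - (1 - r2)/(n - 2) (the self term stays exactly
1).  Scores here are computed from the analysed genotypes over a kb window
rather than taken from an external reference panel.

Heritability regression: with chi2_j = (beta_j / se_j)^2,

    E[chi2_j] = N h2 ell_j / M + intercept,

fit by weighted least squares with the heteroskedasticity weights
w_j = 1 / [max(ell_j, 1) (1 + N h2_1 ell_j / M)^2], where h2_1 comes from an
unweighted first pass.  Cross-stratum genetic covariance uses the product of
the two z-scores:

    E[z_aj z_bj] = sqrt(N_a N_b) gencov ell_j / M + intercept,

and rg = gencov / sqrt(h2_a h2_b).  Uncertainty is a delete-one-block
jackknife over contiguous, equal-count position blocks; for rg the full ratio
is recomputed for every deleted block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import align_effect_alleles
from .simcohort import DosageMatrix

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_N_BLOCKS = 20


@dataclass
class LdScores:
    table: pd.DataFrame  # columns: id, chrom, pos, ell
    window_bp: int
    adjusted: bool


@dataclass
class LdscFit:
    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_blocks: int
    M: int
    N: float
    h2_out_of_range: bool = False


@dataclass
class RgFit:
    gencov: float
    rg: float | None
    se_rg: float | None
    intercept: float
    fit_a: LdscFit
    fit_b: LdscFit
    n_blocks: int
    M: int
    reason: str = ""


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------


def compute_ld_scores(
    g: DosageMatrix, window_bp: int = DEFAULT_WINDOW_BP, adjusted: bool = True
) -> LdScores:
    """Windowed sum of squared dosage correlations, self term included.

    Zero-variance variants contribute (and receive) cross terms of 0; their
    own score is the self term 1.
    """
    n = g.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to compute LD scores")
    var = g.variants
    ell = np.ones(g.n_variants)  # self term

    D = g.dosages.astype(np.float64)
    sd = D.std(axis=0)
    Z = np.zeros_like(D)
    ok = sd > 0
    Z[:, ok] = (D[:, ok] - D[:, ok].mean(axis=0)) / sd[ok]

    for chrom, idx in var.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = var.loc[idx, "pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        Zc = Z[:, idx]
        m = len(idx)
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        chunk = 256
        contrib = np.zeros(m)
        for start in range(0, m, chunk):
            stop = min(start + chunk, m)
            wlo, whi = lo[start:stop].min(), hi[start:stop].max()
            R = (Zc[:, start:stop].T @ Zc[:, wlo:whi]) / n
            r2 = R**2
            if adjusted:
                r2 = r2 - (1.0 - r2) / (n - 2)
            for j in range(start, stop):
                row = r2[j - start, lo[j] - wlo : hi[j] - wlo]
                # exclude the self column; the self term is fixed at 1
                self_col = j - wlo
                s = row.sum() - r2[j - start, self_col]
                contrib[j] = s
        ell[idx] += contrib
    out = var[["id", "chrom", "pos"]].copy()
    out["ell"] = ell
    return LdScores(table=out, window_bp=int(window_bp), adjusted=bool(adjusted))


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------


def _wls_line(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: float | None = None
) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept).

    With ``intercept`` given, the intercept is constrained to that value and
    only the slope is estimated (regression of y - intercept through the
    origin).
    """
    if intercept is not None:
        slope = float((w * x * (y - intercept)).sum() / (w * x**2).sum())
        return slope, float(intercept)
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    sxy = (w * (x - mx) * (y - my)).sum()
    slope = sxy / sxx
    return float(slope), float(my - slope * mx)


def _position_blocks(table: pd.DataFrame, n_blocks: int) -> np.ndarray:
    """Block label per variant: contiguous equal-count blocks in (chrom, pos)
    order."""
    order = table.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    labels = np.empty(len(table), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_blocks)):
        labels[chunk] = b
    return labels


def _resolve_blocks(M: int, n_blocks: int) -> int:
    # auto-scale so blocks stay <= M/10 variants-per-block-wise; a set too
    # small to support even 2 such blocks cannot give a jackknife
    n_blocks = min(n_blocks, M // 10)
    if n_blocks < 2:
        raise ValueError(
            f"only {M} variants: too few for a block jackknife; reduce n_blocks"
        )
    return n_blocks


def _jackknife(theta_blocks: np.ndarray) -> float:
    b = len(theta_blocks)
    return float(np.sqrt((b - 1) / b * np.sum((theta_blocks - theta_blocks.mean()) ** 2)))


def _merge_scores(sumstats: pd.DataFrame, scores: LdScores) -> pd.DataFrame:
    df = sumstats.merge(scores.table[["id", "ell"]], on="id", how="inner")
    df = df.loc[df["beta"].notna() & df["se"].notna() & (df["se"] > 0)]
    return df.reset_index(drop=True)


def fit_h2(
    sumstats: pd.DataFrame,
    scores: LdScores,
    N: float,
    M: int | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    weighted: bool = True,
    constrain_intercept: bool = False,
) -> LdscFit:
    """SNP heritability by LD-score regression of chi2 on ell.

    ``constrain_intercept=True`` fixes the intercept at its no-confounding
    value of 1 (appropriate for clean simulations; sharpens the slope).
    """
    df = _merge_scores(sumstats, scores)
    M = int(M if M is not None else len(df))
    if M < 1 or N <= 0:
        raise ValueError("M and N must be positive")
    n_blocks = _resolve_blocks(len(df), n_blocks)
    chi2 = (df["beta"] / df["se"]).to_numpy() ** 2
    ell = df["ell"].to_numpy(dtype=float)
    fixed = 1.0 if constrain_intercept else None

    slope1, _ = _wls_line(ell, chi2, np.ones_like(ell), intercept=fixed)
    if weighted:
        h2_1 = max(slope1 * M / N, 0.0)
        w = 1.0 / (np.maximum(ell, 1.0) * (1.0 + N * h2_1 * ell / M) ** 2)
    else:
        w = np.ones_like(ell)

    slope, intercept = _wls_line(ell, chi2, w, intercept=fixed)
    h2 = slope * M / N

    labels = _position_blocks(df, n_blocks)
    h2_b = np.empty(n_blocks)
    int_b = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = labels != b
        s_b, i_b = _wls_line(ell[keep], chi2[keep], w[keep], intercept=fixed)
        h2_b[b] = s_b * M / N
        int_b[b] = i_b
    return LdscFit(
        h2=float(h2),
        intercept=float(intercept),
        se_h2=_jackknife(h2_b),
        se_intercept=_jackknife(int_b),
        n_blocks=n_blocks,
        M=M,
        N=float(N),
        h2_out_of_range=not (0.0 <= h2 <= 1.0),
    )


def fit_rg(
    sumstats_a: pd.DataFrame,
    sumstats_b: pd.DataFrame,
    scores: LdScores,
    N_a: float,
    N_b: float,
    M: int | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    weighted: bool = True,
    constrain_intercept: bool = False,
) -> RgFit:
    """Cross-stratum genetic covariance and correlation.

    ``constrain_intercept=True`` fixes the chi2 intercepts at 1 and the
    cross-trait intercept at 0 (valid for disjoint, unconfounded samples).

    Effect alleles of b are aligned to a (betas sign-flipped on mismatch)
    before forming the z-score products.  rg is undefined (returned with a
    reason) when either heritability estimate is <= 0.
    """
    b_aligned = align_effect_alleles(sumstats_b, sumstats_a)
    a = _merge_scores(sumstats_a, scores)
    b = _merge_scores(b_aligned, scores)
    df = a.merge(b[["id", "beta", "se"]], on="id", suffixes=("_a", "_b"), how="inner")
    M = int(M if M is not None else len(df))
    n_blocks = _resolve_blocks(len(df), n_blocks)

    za = (df["beta_a"] / df["se_a"]).to_numpy()
    zb = (df["beta_b"] / df["se_b"]).to_numpy()
    ell = df["ell"].to_numpy(dtype=float)
    zz = za * zb
    scale = np.sqrt(N_a * N_b)

    fa = fit_h2(sumstats_a, scores, N=N_a, M=M, n_blocks=n_blocks,
                weighted=weighted, constrain_intercept=constrain_intercept)
    fb = fit_h2(sumstats_b, scores, N=N_b, M=M, n_blocks=n_blocks,
                weighted=weighted, constrain_intercept=constrain_intercept)
    fixed = 0.0 if constrain_intercept else None

    slope1, _ = _wls_line(ell, zz, np.ones_like(ell), intercept=fixed)
    if weighted:
        # all first-pass estimates unweighted, and the intercept (+1) kept in
        # the covariance term, so that identical inputs give weights exactly
        # proportional to the chi2 weights (hence rg = 1 exactly)
        gc1 = slope1 * M / scale
        ha1 = max(_unweighted_slope(ell, za**2) * M / N_a, 0.0)
        hb1 = max(_unweighted_slope(ell, zb**2) * M / N_b, 0.0)
        var_zz = (1.0 + N_a * ha1 * ell / M) * (1.0 + N_b * hb1 * ell / M) + (
            scale * gc1 * ell / M + 1.0
        ) ** 2
        w = 1.0 / (np.maximum(ell, 1.0) * var_zz)
    else:
        w = np.ones_like(ell)

    slope, intercept = _wls_line(ell, zz, w, intercept=fixed)
    gencov = slope * M / scale

    if fa.h2 <= 0 or fb.h2 <= 0:
        return RgFit(
            gencov=float(gencov),
            rg=None,
            se_rg=None,
            intercept=float(intercept),
            fit_a=fa,
            fit_b=fb,
            n_blocks=n_blocks,
            M=M,
            reason="non-positive heritability estimate; rg undefined",
        )
    rg = gencov / np.sqrt(fa.h2 * fb.h2)

    # jackknife the full ratio functional per deleted block
    chi2a = za**2
    chi2b = zb**2
    labels = _position_blocks(df, n_blocks)
    # per-trait weights consistent with fit_h2's two-pass scheme
    wa = _h2_weights(ell, chi2a, N_a, M) if weighted else np.ones_like(ell)
    wb = _h2_weights(ell, chi2b, N_b, M) if weighted else np.ones_like(ell)
    rg_b = np.empty(n_blocks)
    for blk in range(n_blocks):
        keep = labels != blk
        s_gc, _ = _wls_line(ell[keep], zz[keep], w[keep], intercept=fixed)
        s_a, _ = _wls_line(ell[keep], chi2a[keep], wa[keep],
                           intercept=1.0 if constrain_intercept else None)
        s_b, _ = _wls_line(ell[keep], chi2b[keep], wb[keep],
                           intercept=1.0 if constrain_intercept else None)
        gc_k = s_gc * M / scale
        h2a_k = s_a * M / N_a
        h2b_k = s_b * M / N_b
        if h2a_k > 0 and h2b_k > 0:
            rg_b[blk] = gc_k / np.sqrt(h2a_k * h2b_k)
        else:
            # degenerate deleted-block denominator: contribute the point
            # estimate (no deviation) rather than an exploding ratio
            rg_b[blk] = rg
    return RgFit(
        gencov=float(gencov),
        rg=float(rg),
        se_rg=_jackknife(rg_b),
        intercept=float(intercept),
        fit_a=fa,
        fit_b=fb,
        n_blocks=n_blocks,
        M=M,
    )


def _unweighted_slope(x: np.ndarray, y: np.ndarray) -> float:
    return _wls_line(x, y, np.ones_like(x))[0]


def _h2_weights(ell: np.ndarray, chi2: np.ndarray, N: float, M: int) -> np.ndarray:
    slope1, _ = _wls_line(ell, chi2, np.ones_like(ell))
    h2_1 = max(slope1 * M / N, 0.0)
    return 1.0 / (np.maximum(ell, 1.0) * (1.0 + N * h2_1 * ell / M) ** 2)
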