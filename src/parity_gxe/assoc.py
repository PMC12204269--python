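"""Per-SNP association scans, locus clumping, effect comparison, LD proxies.

Association is covariate-adjusted ordinary least squares, one variant at a
time: y ~ 1 + g + C.  For genome-wide scans the covariates are projected out
once (Frisch-Waugh), which is algebraically identical to the full per-variant
fit but runs as a handful of matrix products.  p-values come from the exact
t distribution with n - k - 1 degrees of freedom (k = model columns excluding
the intercept), not the normal approximation.

Lead loci are formed greedily: the smallest-p genome-wide-significant variant
becomes a lead and absorbs every significant variant within the radius on the
same chromosome; ties on p break by (chrom, pos).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simcohort import DosageMatrix

GENOME_WIDE_ALPHA = 5e-8
CLUMP_RADIUS_BP = 1_500_000
PROXY_WINDOW_BP = 550_000
PROXY_MIN_R2 = 0.3
MIN_MAC = 5  # below this a variant is reported as non-testable


class CollinearityError(np.linalg.LinAlgError):
    """The regression design is rank deficient."""


# ---------------------------------------------------------------------------
# single-variant fit
# ---------------------------------------------------------------------------


def fit_snp(
    y: np.ndarray, g: np.ndarray, C: np.ndarray | None = None
) -> tuple[float, float, float, int]:
    """OLS of y on [1, g, C]; returns (beta_g, se, two-sided p, n)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    C = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    X = np.column_stack([np.ones(n), g, C])
    k = X.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"too few samples (n={n}) for {k} model columns")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _rank_deficient_column(X)
        raise CollinearityError(f"design is rank deficient (column {bad})")
    beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k - 1
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    if se == 0.0:
        p = 1.0 if beta[1] == 0 else 0.0
    else:
        t = beta[1] / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return float(beta[1]), se, max(p, np.finfo(float).tiny), n


def _rank_deficient_column(X: np.ndarray) -> int:
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
            return j
    return X.shape[1] - 1


def _project_out(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residual of the columns of A after regression on the span of Q."""
    return A - Q @ (Q.T @ A)


def _covariate_basis(C: np.ndarray) -> np.ndarray:
    n = C.shape[0]
    X0 = np.column_stack([np.ones(n), C])
    Q, R = np.linalg.qr(X0)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * diag.max()):
        raise CollinearityError("covariate matrix is rank deficient")
    return Q


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------


def run_gwas(
    y: np.ndarray,
    g: DosageMatrix,
    C: np.ndarray | None = None,
    stratum: str = "all",
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant covariate-adjusted OLS scan over a DosageMatrix.

    ``mask`` restricts to a sample subset (the stratum); effect-allele
    frequency is computed in the analysed samples.  Variants with minor
    allele count below ``MIN_MAC`` (or constant after masking) are reported
    with beta/se/p missing and ``reason = "low_mac"``.

    Returns a REGENIE-like summary-statistics frame with columns
    chrom, pos, id, effect_allele, other_allele, eaf, beta, se, p, n,
    stratum, reason.
    """
    y = np.asarray(y, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        y = y[mask]
        G = g.dosages[mask].astype(np.float64)
        C = None if C is None else np.asarray(C, dtype=float)[mask]
    else:
        G = g.dosages.astype(np.float64)
    n = y.size
    if n == 0:
        raise ValueError("no overlapping samples for this stratum")
    C = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    k = 1 + C.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough samples for the covariate model")

    Q = _covariate_basis(C)
    y_res = _project_out(Q, y[:, None])[:, 0]
    G_res = _project_out(Q, G)

    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    yy = float(y_res @ y_res)

    eaf = G.mean(axis=0) / 2.0
    mac = np.minimum(G.sum(axis=0), 2 * n - G.sum(axis=0))
    testable = (mac >= MIN_MAC) & (gg > 1e-12 * n)

    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    p = np.full(G.shape[1], np.nan)
    t_ok = testable
    beta[t_ok] = gy[t_ok] / gg[t_ok]
    rss = yy - beta[t_ok] ** 2 * gg[t_ok]
    rss = np.maximum(rss, 0.0)
    se[t_ok] = np.sqrt(rss / df / gg[t_ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[t_ok] / se[t_ok]
    p[t_ok] = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)

    out = g.variants[["chrom", "pos", "id"]].copy()
    out["effect_allele"] = g.variants["alt"].to_numpy()
    out["other_allele"] = g.variants["ref"].to_numpy()
    out["eaf"] = eaf
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["stratum"] = stratum
    out["reason"] = np.where(testable, "", "low_mac")
    return out


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


@dataclass
class Locus:
    """A lead variant and the significant variants it absorbs."""

    lead: str
    lead_p: float
    chrom: str
    pos: int
    members: list[str] = field(default_factory=list)
    radius: int = CLUMP_RADIUS_BP


def clump_leads(
    res: pd.DataFrame,
    threshold: float = GENOME_WIDE_ALPHA,
    radius: int = CLUMP_RADIUS_BP,
) -> list[Locus]:
    """Greedy distance clumping of genome-wide-significant variants."""
    sig = res.loc[res["p"].notna() & (res["p"] < threshold)].copy()
    if len(sig) == 0:
        return []
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(sig), dtype=bool)
    loci: list[Locus] = []
    chrom = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy()
    for i in range(len(sig)):
        if assigned[i]:
            continue
        near = (~assigned) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= radius)
        members = sig.loc[near].sort_values(["chrom", "pos"])["id"].tolist()
        loci.append(
            Locus(
                lead=sig.at[i, "id"],
                lead_p=float(sig.at[i, "p"]),
                chrom=str(chrom[i]),
                pos=int(pos[i]),
                members=members,
                radius=int(radius),
            )
        )
        assigned |= near
    return loci


# ---------------------------------------------------------------------------
# cross-stratum effect comparison
# ---------------------------------------------------------------------------


def align_effect_alleles(res: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Flip betas (and eaf) in ``res`` so effect alleles match ``ref``."""
    merged = res.merge(
        ref[["id", "effect_allele", "other_allele"]],
        on="id",
        suffixes=("", "_ref"),
        how="inner",
    )
    flipped = (merged["effect_allele"] == merged["other_allele_ref"]) & (
        merged["other_allele"] == merged["effect_allele_ref"]
    )
    out = merged.copy()
    out.loc[flipped, "beta"] = -out.loc[flipped, "beta"]
    if "eaf" in out.columns:
        out.loc[flipped, "eaf"] = 1.0 - out.loc[flipped, "eaf"]
    out.loc[flipped, ["effect_allele", "other_allele"]] = out.loc[
        flipped, ["effect_allele_ref", "other_allele_ref"]
    ].to_numpy()
    return out.drop(columns=["effect_allele_ref", "other_allele_ref"])


def effect_correlation(
    res_first: pd.DataFrame, res_later: pd.DataFrame, variant_ids: list[str]
) -> tuple[float | None, float | None, str]:
    """Pearson r and sign concordance of per-variant betas across strata.

    Effect alleles are aligned (sign-flipping mismatched rows) before
    comparing.  Returns (r, concordance, reason); fewer than 3 usable
    variants yields (None, None, reason).
    """
    later = align_effect_alleles(res_later, res_first)
    a = res_first.set_index("id")["beta"]
    b = later.set_index("id")["beta"]
    ids = [v for v in variant_ids if v in a.index and v in b.index]
    x = a.loc[ids].to_numpy(dtype=float)
    z = b.loc[ids].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(z)
    x, z = x[ok], z[ok]
    if x.size < 3:
        return None, None, "fewer than 3 variants with estimates in both strata"
    r = float(np.corrcoef(x, z)[0, 1])
    concordance = float(np.mean(np.sign(x) == np.sign(z)))
    return r, concordance, ""


def match_leads(
    leads_a: list["Locus"],
    leads_b: list["Locus"],
    g: DosageMatrix,
    min_r2: float = 0.85,
    window_bp: int = PROXY_WINDOW_BP,
) -> list[tuple[str, str, float]]:
    """Pair lead variants across two stratum scans that tag the same signal.

    Two leads match when they are the same variant (r2 = 1) or when their
    dosage r2 within the search window exceeds ``min_r2``.  Greedy on
    descending r2; each lead used at most once.  Returns
    (lead_a, lead_b, r2) triples.
    """
    ids = {v: j for j, v in enumerate(g.variants["id"])}
    pos = g.variants["pos"].to_numpy()
    chrom = g.variants["chrom"].to_numpy()
    cand: list[tuple[float, str, str]] = []
    for la in leads_a:
        for lb in leads_b:
            if la.lead == lb.lead:
                cand.append((1.0, la.lead, lb.lead))
                continue
            ja, jb = ids.get(la.lead), ids.get(lb.lead)
            if ja is None or jb is None:
                continue
            if chrom[ja] != chrom[jb] or abs(int(pos[ja]) - int(pos[jb])) > window_bp:
                continue
            xa = g.dosages[:, ja].astype(float)
            xb = g.dosages[:, jb].astype(float)
            if xa.std() == 0 or xb.std() == 0:
                continue
            r2 = float(np.corrcoef(xa, xb)[0, 1] ** 2)
            if r2 > min_r2:
                cand.append((r2, la.lead, lb.lead))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out: list[tuple[str, str, float]] = []
    for r2, a, b in sorted(cand, key=lambda t: (-t[0], t[1], t[2])):
        if a in used_a or b in used_b:
            continue
        out.append((a, b, r2))
        used_a.add(a)
        used_b.add(b)
    return out


# ---------------------------------------------------------------------------
# LD proxy search
# ---------------------------------------------------------------------------


def find_proxy(
    target_id: str,
    g: DosageMatrix,
    window_bp: int = PROXY_WINDOW_BP,
    min_r2: float = PROXY_MIN_R2,
) -> tuple[str | None, float | None]:
    """Best LD proxy for a variant: largest dosage r² within +/- window_bp on
    the same chromosome, provided r² > min_r2 (strict).  Ties break by
    smaller distance, then lower position.  Returns (proxy_id, r2) or
    (None, None).
    """
    var = g.variants
    hit = var.index[var["id"] == target_id]
    if len(hit) == 0:
        raise KeyError(f"target variant {target_id!r} not in the dosage matrix")
    ti = int(hit[0])
    chrom, pos = var.at[ti, "chrom"], int(var.at[ti, "pos"])
    cand = var.index[
        (var["chrom"] == chrom)
        & ((var["pos"] - pos).abs() <= window_bp)
        & (var.index != ti)
    ]
    if len(cand) == 0:
        return None, None
    x = g.dosages[:, ti].astype(float)
    if x.std() == 0:
        return None, None
    Y = g.dosages[:, cand].astype(float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Yc.T @ xc) / denom, 0.0)
    r2 = r**2
    dist = np.abs(var.loc[cand, "pos"].to_numpy() - pos)
    order = np.lexsort((var.loc[cand, "pos"].to_numpy(), dist, -r2))
    best = order[0]
    if r2[best] > min_r2:
        return str(var.loc[cand[best], "id"]), float(r2[best])
    return None, None
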