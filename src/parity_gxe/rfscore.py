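"""Random-forest out-of-bag genetic scores and the score x parity test.

Procedure: the phenotype is residualised (overall mean plus the residual from
an OLS regression on the GWAS covariates), forests are trained on hard-coded
candidate-variant genotypes (0/1/2), and each sample's genetic score is its
mean out-of-bag prediction over R independent forest repetitions.  Each
repetition also yields one draw of

    r2_oob = 1 - MSE_oob / Var(residualised phenotype),

whose 2.5th/97.5th percentiles over the R draws form the 95% credible
interval of the genetic predictability.  Finally the centred mean score is
tested for interaction with the parity indicator:

    y = b0 + b1 * score + b2 * parity + b3 * score * parity,

where b3 (with no covariates in the model) equals the difference of the
per-stratum slopes of y on the score exactly.

Var() uses the n-1 denominator throughout, so a constant prediction at the
phenotype mean gives r2 = 1/n rather than exactly 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .assoc import CollinearityError
from .simcohort import DosageMatrix

DEFAULT_N_TREES = (500,)
DEFAULT_MIN_NODE = (5, 20)
MIN_STRATUM_SIZE = 50


@dataclass
class ResidualisedPhenotype:
    values: np.ndarray  # mean(y) + residual; same mean as raw y
    covariate_spec: list[str] = field(default_factory=list)


@dataclass
class RfScoreResult:
    score: np.ndarray  # per-sample mean OOB prediction (phenotype units)
    r2_draws: np.ndarray  # R values of r2_oob
    r2_ci: tuple[float, float]
    hyperparams: dict
    R: int
    feature_ids: list[str]

    @property
    def r2_median(self) -> float:
        return float(np.median(self.r2_draws))


def residualise(
    y: np.ndarray, C: np.ndarray | None = None, covariate_names: Sequence[str] = ()
) -> ResidualisedPhenotype:
    """Overall mean plus the residual from OLS of y on [1, C]."""
    y = np.asarray(y, dtype=float)
    n = y.size
    C = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return ResidualisedPhenotype(
        values=y.mean() + resid, covariate_spec=list(covariate_names)
    )


def oob_r2(y_true: np.ndarray, y_oob_pred: np.ndarray) -> float:
    """1 - mean squared OOB error over the n-1 sample variance of y."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_oob_pred, dtype=float)
    if y.size != yhat.size:
        raise ValueError("prediction vector length mismatch")
    var = y.var(ddof=1)
    if not var > 0:
        raise ValueError("zero phenotype variance; r2 undefined")
    mse = float(np.mean((y - yhat) ** 2))
    return 1.0 - mse / float(var)


def default_hyper_grid(n_features: int) -> list[dict]:
    """n_trees x mtry x min_node_size grid; mtry candidates ceil(sqrt(m)) and
    ceil(m/3) (deduplicated)."""
    mtry = sorted({int(np.ceil(np.sqrt(n_features))), int(np.ceil(n_features / 3))})
    grid = []
    for nt, mt, mn in itertools.product(DEFAULT_N_TREES, mtry, DEFAULT_MIN_NODE):
        grid.append({"n_trees": nt, "mtry": mt, "min_node_size": mn})
    return grid


def _fit_forest(
    X: np.ndarray, y: np.ndarray, hp: dict, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One bagged forest with explicit OOB bookkeeping.

    Bootstrap indices are drawn here (not inside scikit-learn) so that the
    per-sample out-of-bag tree counts are exact; each tree is a
    DecisionTreeRegressor with per-node feature subsampling (max_features =
    mtry).  Returns (oob_prediction, has_oob mask); predictions for samples
    with no OOB tree are undefined (masked out).
    """
    from sklearn.tree import DecisionTreeRegressor

    rng = np.random.default_rng(int(seed))
    n = y.size
    pred_sum = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    mtry = min(hp["mtry"], X.shape[1])
    for _ in range(hp["n_trees"]):
        idx = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=hp["min_node_size"],
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        if oob.any():
            pred_sum[oob] += tree.predict(X[oob])
            cnt[oob] += 1
    has = cnt > 0
    pred = np.zeros(n)
    pred[has] = pred_sum[has] / cnt[has]
    return pred, has


def fit_rf_score(
    y_res: ResidualisedPhenotype,
    g_top: DosageMatrix,
    hyper_grid: list[dict] | None = None,
    R: int = 50,
    seed: int = 0,
    extra_features: np.ndarray | None = None,
) -> RfScoreResult:
    """Tune on OOB MSE, then fit R forests with derived seeds.

    score_i = mean of repetition-level OOB predictions over the repetitions
    in which sample i was out of bag at least once; a sample never OOB in any
    repetition raises.  ``extra_features`` (samples x columns) appends
    non-genetic predictors — the genetics-plus-environment variant of the
    model, typically fit on the non-residualised outcome.
    """
    if g_top.n_variants < 1:
        raise ValueError("need at least one candidate variant")
    if R < 2:
        raise ValueError("need R >= 2 repetitions")
    y = np.asarray(y_res.values, dtype=float)
    X = g_top.dosages.astype(np.float64)
    if extra_features is not None:
        X = np.hstack([X, np.asarray(extra_features, dtype=float)])
    grid = hyper_grid if hyper_grid is not None else default_hyper_grid(X.shape[1])

    ss = np.random.SeedSequence(entropy=int(seed))
    tune_seeds = ss.spawn(1)[0].generate_state(len(grid)) % (2**31 - 1)
    best, best_mse = None, np.inf
    # ties -> fewer trees, then smaller mtry (grid scanned in that order)
    for hp, s in sorted(
        zip(grid, tune_seeds), key=lambda t: (t[0]["n_trees"], t[0]["mtry"])
    ):
        pred, has = _fit_forest(X, y, hp, s)
        mse = float(np.mean((y[has] - pred[has]) ** 2))
        if mse < best_mse - 1e-15:
            best, best_mse = hp, mse
    assert best is not None

    rep_seeds = ss.spawn(2)[1].generate_state(R) % (2**31 - 1)
    score_sum = np.zeros(y.size)
    score_cnt = np.zeros(y.size, dtype=int)
    r2_draws = np.empty(R)
    for r in range(R):
        pred, has = _fit_forest(X, y, best, rep_seeds[r])
        r2_draws[r] = oob_r2(y[has], pred[has])
        score_sum[has] += pred[has]
        score_cnt[has] += 1
    if (score_cnt == 0).any():
        raise RuntimeError(
            "some samples were never out of bag in any repetition; "
            "increase R or reduce trees per forest"
        )
    score = score_sum / score_cnt
    ci = (
        float(np.percentile(r2_draws, 2.5)),
        float(np.percentile(r2_draws, 97.5)),
    )
    return RfScoreResult(
        score=score,
        r2_draws=r2_draws,
        r2_ci=ci,
        hyperparams=dict(best),
        R=R,
        feature_ids=g_top.variants["id"].tolist(),
    )


@dataclass
class ScoreInteractionFit:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se3: float
    p3: float
    n: int


def score_parity_interaction(
    y: np.ndarray, score: np.ndarray, env: np.ndarray
) -> ScoreInteractionFit:
    """OLS of y on [1, centred score, env, centred score x env]."""
    y = np.asarray(y, dtype=float)
    env = np.asarray(env, dtype=float)
    if np.all(env == env[0]):
        raise CollinearityError("parity indicator is constant")
    sc = np.asarray(score, dtype=float)
    sc = sc - sc.mean()
    X = np.column_stack([np.ones_like(y), sc, env, sc * env])
    if np.linalg.matrix_rank(X) < 4:
        raise CollinearityError("score/parity design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.size - 4
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se3 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    p3 = 1.0 if se3 == 0 and beta[3] == 0 else float(
        2.0 * stats.t.sf(abs(beta[3] / se3), df) if se3 > 0 else 0.0
    )
    return ScoreInteractionFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta3=float(beta[3]),
        se3=se3,
        p3=max(p3, np.finfo(float).tiny),
        n=y.size,
    )


@dataclass
class StratifiedR2:
    results: dict[str, RfScoreResult]
    ci_overlap: bool
    fold_change_median_r2: float | None  # first / later


def stratified_r2(
    y_res_by_stratum: dict[str, ResidualisedPhenotype],
    g_by_stratum: dict[str, DosageMatrix],
    hyper_grid: list[dict] | None = None,
    R: int = 50,
    seed: int = 0,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> StratifiedR2:
    """fit_rf_score run independently within each parity stratum."""
    results: dict[str, RfScoreResult] = {}
    for s, y_res in sorted(y_res_by_stratum.items()):
        if y_res.values.size < min_stratum_size:
            raise ValueError(
                f"stratum {s!r} has {y_res.values.size} samples "
                f"(< {min_stratum_size})"
            )
        # shared seed across strata: identical inputs give identical fits
        results[s] = fit_rf_score(
            y_res, g_by_stratum[s], hyper_grid=hyper_grid, R=R, seed=seed
        )
    lo_f, hi_f = results["first"].r2_ci
    lo_l, hi_l = results["later"].r2_ci
    overlap = (lo_f <= hi_l) and (lo_l <= hi_f)
    med_later = results["later"].r2_median
    fold = results["first"].r2_median / med_later if med_later > 0 else None
    return StratifiedR2(results=results, ci_overlap=overlap, fold_change_median_r2=fold)
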