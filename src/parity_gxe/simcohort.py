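"""Synthetic cohort generator with parity-dependent genetic architecture.

Generates HWE genotypes with blockwise LD, per-stratum (first vs later
pregnancy) SNP effects with a tunable cross-stratum genetic correlation, and
registry-style pregnancy records — including deliberately malformed records
for the QC filters to catch.  Every downstream stage of the pipeline
(stratified GWAS, SNP x parity interaction, LD score regression, random-forest
genetic scores) is testable against the known simulated truth.

The forward model for the analysed phenotype of mother i in stratum s is

    y_i = mu_s + sum_j beta_{s,j} (g_ij - 2 p_j) + gamma' c_i + eps_i,

with eps_i ~ N(0, sigma2_s) and sigma2_s chosen so Var(y | stratum s) equals
the configured phenotypic variance VP_s in expectation.  Effect vectors are
rescaled so the expected additive genetic variance sum_j 2 p_j (1-p_j)
beta_{s,j}^2 equals h2_s * VP_s exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STRATA = ("first", "later")

# Registry defaults emulating the qualitative pattern that first pregnancies
# are shorter and more variable (gestational duration, days) -- simulator
# presets, configurable, not cohort estimates.
DEFAULT_MEANS = {"first": 279.0, "later": 282.0}
DEFAULT_VPS = {"first": 169.0, "later": 121.0}

CHIP_LABELS = ("chipA", "chipB", "chipC")
N_PCS = 10


class ConfigError(ValueError):
    """A SimConfig field is out of its allowed range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``h2_by_stratum``/``vp_by_stratum``/``mean_by_stratum`` are keyed by
    ``"first"`` and ``"later"``; ``rho_g`` is the cross-stratum correlation of
    causal effect sizes; ``qc_error_rates`` holds per-record probabilities of
    the malformed-record types the QC stage must remove.
    """

    n_samples: int = 2000
    n_variants: int = 500
    n_blocks: int = 25
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 100
    h2_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: {"first": 0.25, "later": 0.25}
    )
    vp_by_stratum: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VPS))
    mean_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS)
    )
    rho_g: float = 1.0
    p_first_pregnancy: float = 0.45
    qc_error_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if not 1 <= self.n_blocks <= self.n_variants:
            raise ConfigError("n_blocks must be in [1, n_variants]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.n_causal <= self.n_variants:
            raise ConfigError("n_causal must be in [0, n_variants]")
        for s in STRATA:
            h2 = self.h2_by_stratum[s]
            if not 0.0 <= h2 <= 1.0:
                raise ConfigError(f"h2_by_stratum[{s}] must be in [0, 1]")
            if self.vp_by_stratum[s] <= 0:
                raise ConfigError(f"vp_by_stratum[{s}] must be > 0")
        if not -1.0 <= self.rho_g <= 1.0:
            raise ConfigError("rho_g must be in [-1, 1]")
        if not 0.0 < self.p_first_pregnancy < 1.0:
            raise ConfigError("p_first_pregnancy must be in (0, 1)")
        for k, v in self.qc_error_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"qc_error_rates[{k}] must be in [0, 1]")


@dataclass
class DosageMatrix:
    """Samples x variants additive dosages (0/1/2) with variant metadata."""

    dosages: np.ndarray  # int8, shape (n_samples, n_variants)
    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Empirical effect-allele (alt) frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def subset_variants(self, ids: Sequence[str]) -> "DosageMatrix":
        idx = self.variants.set_index("id").index.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return DosageMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return DosageMatrix(
            dosages=self.dosages[idx], variants=self.variants, sample_ids=list(sample_ids)
        )


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

VARIANT_SPACING_BP = 5_000  # base pairs between adjacent simulated variants


def simulate_genotypes(cfg: SimConfig) -> DosageMatrix:
    """Draw 2n haplotypes as a first-order Markov chain per LD block.

    Adjacent sites within a block have allele correlation ``cfg.ld_rho``;
    blocks are mutually independent.  Dosages are the sum of a sample's two
    independent haplotypes, so Hardy-Weinberg equilibrium holds by
    construction.  All variants are placed on chromosome "1" at
    ``VARIANT_SPACING_BP`` intervals.
    """
    cfg.validate()
    rng = _rng_for(cfg.seed, 0)
    n, m = cfg.n_samples, cfg.n_variants
    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    block_ids = np.array_split(np.arange(m), cfg.n_blocks)

    haps = np.empty((2 * n, m), dtype=np.int8)
    rho = cfg.ld_rho
    for block in block_ids:
        j0 = block[0]
        u = rng.random((2 * n, len(block)))
        haps[:, j0] = u[:, 0] < freqs[j0]
        for k, j in enumerate(block[1:], start=1):
            p_prev, p_cur = freqs[block[k - 1]], freqs[j]
            # conditional Bernoulli giving Corr(b_prev, b_cur) = rho
            slope = rho * np.sqrt(p_cur * (1 - p_cur) / (p_prev * (1 - p_prev)))
            prev = haps[:, block[k - 1]].astype(np.float64)
            p_cond = np.clip(p_cur + slope * (prev - p_prev), 0.0, 1.0)
            haps[:, j] = u[:, k] < p_cond

    dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
    pos = VARIANT_SPACING_BP * (1 + np.arange(m))
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"rs{j + 1}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    return DosageMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------


def simulate_effects(cfg: SimConfig, g: DosageMatrix) -> dict[str, np.ndarray]:
    """Per-stratum causal effect vectors with cross-stratum correlation rho_g.

    ``n_causal`` variants are chosen at random; their (beta_first, beta_later)
    pairs are bivariate normal with correlation ``rho_g``, then each stratum's
    vector is rescaled so sum_j 2 p_j (1-p_j) beta_{s,j}^2 = h2_s * VP_s
    exactly (p_j = empirical alt-allele frequency).  Non-causal effects are 0.
    """
    cfg.validate()
    if cfg.n_causal > g.n_variants:
        raise ConfigError("n_causal exceeds the number of variants")
    rng = _rng_for(cfg.seed, 1)
    m = g.n_variants
    causal = np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
    # explicit bivariate-normal construction; exact at |rho_g| = 1
    z1 = rng.standard_normal(cfg.n_causal)
    z2 = cfg.rho_g * z1 + np.sqrt(max(1.0 - cfg.rho_g**2, 0.0)) * rng.standard_normal(
        cfg.n_causal
    )
    raw = np.column_stack([z1, z2])

    p = g.allele_frequencies()
    het = 2.0 * p * (1.0 - p)
    effects: dict[str, np.ndarray] = {}
    for col, s in enumerate(STRATA):
        beta = np.zeros(m)
        target = cfg.h2_by_stratum[s] * cfg.vp_by_stratum[s]
        if cfg.n_causal > 0 and target > 0:
            b = raw[:, col]
            current = float(np.sum(het[causal] * b**2))
            if current <= 0:
                raise ConfigError("degenerate causal draw: zero raw genetic variance")
            beta[causal] = b * np.sqrt(target / current)
        effects[s] = beta
    return effects


# ---------------------------------------------------------------------------
# phenotypes + registry
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """Registry records, covariates, and the simulated truth for one cohort."""

    registry: pd.DataFrame  # pregnancy records incl. injected malformed ones
    covariates: pd.DataFrame  # sample_id, maternal_age, sex, chip, PC1..PC10
    phenotype_name: str
    y: np.ndarray  # analysed phenotype on its native analysis scale
    stratum: np.ndarray  # "first"/"later" per sample (model scale)
    sample_ids: list[str]
    effects: dict[str, np.ndarray]
    config: SimConfig


def _covariate_frame(rng: np.random.Generator, sample_ids: list[str]) -> pd.DataFrame:
    n = len(sample_ids)
    df = pd.DataFrame({"sample_id": sample_ids})
    df["maternal_age"] = np.round(rng.normal(29.5, 4.5, size=n), 1)
    df["sex"] = rng.choice(["male", "female"], size=n)
    df["chip"] = rng.choice(CHIP_LABELS, size=n, p=[0.5, 0.3, 0.2])
    pcs = rng.standard_normal((n, N_PCS))
    for k in range(N_PCS):
        df[f"PC{k + 1}"] = pcs[:, k]
    return df


def covariate_design(covariates: pd.DataFrame, include: Sequence[str]) -> np.ndarray:
    """Numeric design matrix (no intercept) for the named covariates.

    Categorical columns (sex, chip) are dummy-coded dropping the first level.
    """
    cols = []
    for name in include:
        v = covariates[name]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(v, prefix=name, drop_first=True)
            cols.append(d.to_numpy(dtype=float))
        else:
            cols.append(v.to_numpy(dtype=float)[:, None])
    if not cols:
        return np.empty((len(covariates), 0))
    return np.hstack(cols)


GWAS_COVARIATES_GD = ["maternal_age", "sex", "chip"] + [f"PC{k+1}" for k in range(N_PCS)]
GWAS_COVARIATES_BW = ["sex", "chip", "gestational_duration"] + [
    f"PC{k+1}" for k in range(N_PCS)
]


def simulate_phenotypes(
    cfg: SimConfig,
    g: DosageMatrix,
    effects: Mapping[str, np.ndarray],
    phenotype: str = "gestational_duration",
    gamma: Mapping[str, float] | None = None,
) -> SimulatedCohort:
    """Assign strata, draw phenotypes under the forward model, build registry.

    Residual variance sigma2_s = VP_s - h2_s*VP_s - Var(gamma'c); an implied
    negative value raises.  Malformed registry records (duplicate parity,
    out-of-order parity, ART, multiple births, out-of-range phenotype values)
    are injected at ``cfg.qc_error_rates``; with all rates zero every record
    passes every downstream QC filter.
    """
    cfg.validate()
    if phenotype not in ("gestational_duration", "birth_weight"):
        raise ConfigError(f"unknown phenotype: {phenotype}")
    rng = _rng_for(cfg.seed, 2)
    n = g.n_samples
    sample_ids = list(g.sample_ids)

    stratum = np.where(
        rng.random(n) < cfg.p_first_pregnancy, "first", "later"
    ).astype(object)
    cov = _covariate_frame(rng, sample_ids)

    p = g.allele_frequencies()
    centered = g.dosages.astype(np.float64) - 2.0 * p

    y = np.empty(n)
    gamma = dict(gamma or {})
    cov_effect = np.zeros(n)
    for name, coef in gamma.items():
        cov_effect += coef * cov[name].to_numpy(dtype=float)
    var_cov = float(np.var(cov_effect)) if gamma else 0.0
    for s in STRATA:
        mask = stratum == s
        h2, vp = cfg.h2_by_stratum[s], cfg.vp_by_stratum[s]
        sigma2 = vp - h2 * vp - var_cov
        if sigma2 < 0:
            raise ConfigError(
                f"implied residual variance < 0 in stratum {s} "
                f"(h2={h2}, vp={vp}, covariate variance={var_cov:.3g})"
            )
        genetic = centered[mask] @ np.asarray(effects[s])
        y[mask] = (
            cfg.mean_by_stratum[s]
            + genetic
            + cov_effect[mask]
            + rng.normal(0.0, np.sqrt(sigma2), size=int(mask.sum()))
        )

    registry = _build_registry(cfg, rng, sample_ids, stratum, cov, y, phenotype)
    return SimulatedCohort(
        registry=registry,
        covariates=cov,
        phenotype_name=phenotype,
        y=y,
        stratum=np.asarray(stratum, dtype=object),
        sample_ids=sample_ids,
        effects=dict(effects),
        config=cfg,
    )


def _build_registry(
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    stratum: np.ndarray,
    cov: pd.DataFrame,
    y: np.ndarray,
    phenotype: str,
) -> pd.DataFrame:
    n = len(sample_ids)
    parity = np.where(stratum == "first", 0, rng.integers(1, 4, size=n))
    if phenotype == "gestational_duration":
        # clean registry values stay inside the analysable 154-308 d window
        # (inclusive); out-of-range durations come only from injected errors
        gd = y.clip(154.0, 308.0)
        bw = np.round(rng.normal(3600.0, 450.0, size=n)).clip(1500, 5500)
    else:
        # analysed phenotype is birth weight on the z-score scale; registry
        # stores grams, QC re-standardises on the included set
        bw = 3600.0 + 480.0 * y
        gd = np.round(rng.uniform(262, 297, size=n))

    rec = pd.DataFrame(
        {
            "mother_id": sample_ids,
            "child_id": [f"{s}-C{o}" for s, o in zip(sample_ids, parity + 1)],
            "delivery_order": parity + 1,
            "parity": parity,
            "gestational_duration": gd,
            "birth_weight": bw,
            "sex": cov["sex"].to_numpy(),
            "maternal_age": cov["maternal_age"].to_numpy(),
            "chip": cov["chip"].to_numpy(),
            "art": False,
            "plurality": 1,
            "malformation": False,
            "perinatal_death": False,
            "death_first_year": False,
            "spontaneous_onset": True,
        }
    )

    rates = dict(cfg.qc_error_rates)
    extra_rows: list[pd.DataFrame] = []

    def _hit(key: str) -> np.ndarray:
        r = rates.get(key, 0.0)
        return rng.random(n) < r if r > 0 else np.zeros(n, dtype=bool)

    rec.loc[_hit("art"), "art"] = True
    rec.loc[_hit("plurality"), "plurality"] = 2
    rec.loc[_hit("malformation"), "malformation"] = True
    rec.loc[_hit("perinatal_death"), "perinatal_death"] = True
    rec.loc[_hit("death_first_year"), "death_first_year"] = True
    rec.loc[_hit("non_spontaneous"), "spontaneous_onset"] = False
    rec.loc[_hit("unknown_sex"), "sex"] = "unknown"
    ext = _hit("extreme_phenotype")
    if ext.any():
        rec.loc[ext, "gestational_duration"] = 120.0

    for key, shift in (("duplicate_parity", 0), ("out_of_order_parity", -1)):
        hit = _hit(key)
        if not hit.any():
            continue
        dup = rec.loc[hit].copy()
        dup["delivery_order"] = dup["delivery_order"] + 1
        dup["parity"] = np.maximum(dup["parity"] + shift, 0)
        if shift == 0:
            pass  # same parity twice
        else:
            # ensure genuinely out of order: later delivery, not-larger parity
            dup["parity"] = np.maximum(dup["parity"], 0)
        dup["child_id"] = dup["mother_id"] + "-Cx"
        extra_rows.append(dup)

    if extra_rows:
        rec = pd.concat([rec, *extra_rows], ignore_index=True)
    return rec


def simulate_cohort(
    cfg: SimConfig, phenotype: str = "gestational_duration"
) -> tuple[DosageMatrix, SimulatedCohort]:
    """Convenience wrapper: genotypes -> effects -> phenotypes."""
    g = simulate_genotypes(cfg)
    eff = simulate_effects(cfg, g)
    cohort = simulate_phenotypes(cfg, g, eff, phenotype=phenotype)
    return g, cohort
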