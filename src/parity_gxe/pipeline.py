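"""End-to-end orchestration: simulate/ingest -> QC -> stratified GWAS ->
SNP x parity interaction -> LD score regression (h2 and cross-stratum rg) ->
random-forest genetic score -> VA = h2 * VP variance decomposition.

Stage order is fixed; every stage is a pure function of (inputs, config,
seed), all per-stage seeds are derived deterministically from the master
seed, and every intermediate artifact is written to the output directory so
a rerun with the same config is byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .assoc import (
    GENOME_WIDE_ALPHA,
    clump_leads,
    effect_correlation,
    run_gwas,
)
from .cohort_qc import build_cohort
from .interaction import bonferroni, run_interaction_scan
from .ldscore import LdscFit, compute_ld_scores, fit_h2, fit_rg
from .rfscore import (
    fit_rf_score,
    residualise,
    score_parity_interaction,
    stratified_r2,
)
from .simcohort import (
    GWAS_COVARIATES_BW,
    GWAS_COVARIATES_GD,
    SimConfig,
    covariate_design,
    simulate_cohort,
)

log = logging.getLogger("parity_gxe")

STRATA = ("first", "later")


@dataclass
class RunConfig:
    """Single-run configuration; module blocks mirror the stage order."""

    out_dir: str = "parity_gxe_out"
    phenotype: str = "gestational_duration"
    seed: int = 0
    # either simulate ...
    simulate: dict | None = field(default_factory=dict)
    # ... or load from files
    genotypes: str | None = None
    registry: str | None = None
    covariates: str | None = None
    # module parameters
    gwas_alpha: float = GENOME_WIDE_ALPHA
    clump_radius_bp: int = 1_500_000
    ld_window_bp: int = 1_000_000
    ldsc_blocks: int = 20
    rf_reps: int = 20
    rf_top_k: int = 20
    family_alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path))


@dataclass
class VarianceDecomposition:
    """VA = h2 * VP per stratum, with a delta-method SE for VA."""

    per_stratum: dict  # stratum -> {vp, h2, va, se_va}
    ratio_va: float | None
    inferred_va_difference: bool

    def to_dict(self) -> dict:
        return {
            "per_stratum": self.per_stratum,
            "ratio_va": self.ratio_va,
            "inferred_va_difference": self.inferred_va_difference,
        }


def decompose_variance(
    phenotype_by_stratum: dict[str, np.ndarray],
    ldsc_fits: dict[str, LdscFit],
) -> VarianceDecomposition:
    """Narrow-sense decomposition per stratum.

    vp is the n-1 sample variance of the analysed phenotype; va = h2 * vp;
    se_va combines se_h2 and the sampling variance of vp by the delta method
    (normal-theory Var(vp) = 2 vp^2/(n-1)).  The "inferred VA difference"
    flag reproduces the qualitative argument that overlapping h2 CIs plus
    non-overlapping VP CIs imply a VA difference; it is a flag, not a test.
    """
    per: dict[str, dict] = {}
    for s in STRATA:
        if s not in phenotype_by_stratum or s not in ldsc_fits:
            raise KeyError(f"missing stratum {s!r}")
        y = np.asarray(phenotype_by_stratum[s], dtype=float)
        n = y.size
        vp = float(y.var(ddof=1))
        fit = ldsc_fits[s]
        va = fit.h2 * vp
        var_vp = 2.0 * vp**2 / (n - 1)
        se_va = float(np.sqrt(fit.se_h2**2 * vp**2 + fit.h2**2 * var_vp))
        per[s] = {
            "n": n,
            "vp": vp,
            "h2": fit.h2,
            "se_h2": fit.se_h2,
            "va": va,
            "se_va": se_va,
        }
    va_later = per["later"]["va"]
    ratio = per["first"]["va"] / va_later if va_later > 0 else None

    z = 1.959963984540054
    h2_lo = {s: per[s]["h2"] - z * per[s]["se_h2"] for s in STRATA}
    h2_hi = {s: per[s]["h2"] + z * per[s]["se_h2"] for s in STRATA}
    h2_overlap = h2_lo["first"] <= h2_hi["later"] and h2_lo["later"] <= h2_hi["first"]
    vp_se = {s: np.sqrt(2.0 * per[s]["vp"] ** 2 / (per[s]["n"] - 1)) for s in STRATA}
    vp_lo = {s: per[s]["vp"] - z * vp_se[s] for s in STRATA}
    vp_hi = {s: per[s]["vp"] + z * vp_se[s] for s in STRATA}
    vp_overlap = vp_lo["first"] <= vp_hi["later"] and vp_lo["later"] <= vp_hi["first"]
    return VarianceDecomposition(
        per_stratum=per,
        ratio_va=ratio,
        inferred_va_difference=bool(h2_overlap and not vp_overlap),
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _covariate_names(phenotype: str) -> list[str]:
    return GWAS_COVARIATES_GD if phenotype == "gestational_duration" else GWAS_COVARIATES_BW


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write artifacts + a consolidated report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    report: dict = {"config": cfg.to_dict(), "stages": {}}

    def fail(stage: str, err: Exception):
        log.error("stage %s failed: %s", stage, err)
        report["stages"][stage] = {"status": "failed", "error": str(err)}
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.genotypes:
            g = (
                io.read_vcf(cfg.genotypes)
                if str(cfg.genotypes).endswith(".vcf")
                else io.read_dosage_tsv(cfg.genotypes)
            )
            registry = io.read_table(cfg.registry)
            covariates = io.read_table(cfg.covariates)
        else:
            sim_cfg = SimConfig(**{"seed": _stage_seed(cfg.seed, "sim"), **(cfg.simulate or {})})
            g, sim = simulate_cohort(sim_cfg, phenotype=cfg.phenotype)
            registry, covariates = sim.registry, sim.covariates
            io.write_dosage_tsv(g, out / "genotypes.tsv")
            io.write_table(registry, out / "registry.tsv")
            io.write_table(covariates, out / "covariates.tsv")
        log.info("inputs: %d samples x %d variants", g.n_samples, g.n_variants)
        report["stages"][stage] = {
            "status": "ok",
            "n_samples": g.n_samples,
            "n_variants": g.n_variants,
        }
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    # --- QC ---------------------------------------------------------------
    stage = "qc"
    try:
        cohort, qc_report = build_cohort(
            registry, covariates, cfg.phenotype, seed=_stage_seed(cfg.seed, "qc")
        )
        (out / "qc_report.json").write_text(qc_report.to_json())
        io.write_table(cohort.rows, out / "cohort.tsv")
        log.info("qc: %d -> %d records", qc_report.n_in, qc_report.n_out)
        report["stages"][stage] = {
            "status": "ok",
            "n_in": qc_report.n_in,
            "n_out": qc_report.n_out,
            "removed": qc_report.counts,
        }
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    rows = cohort.rows
    g_cohort = g.subset_samples(rows["sample_id"].tolist())
    y = rows["phenotype_value"].to_numpy(dtype=float)
    cov_names = _covariate_names(cfg.phenotype)
    C = covariate_design(rows, cov_names)
    env = (rows["stratum"].to_numpy() == "later").astype(float)

    # --- stratified GWAS --------------------------------------------------
    stage = "gwas"
    try:
        scans: dict[str, pd.DataFrame] = {}
        for s in ("all", "first", "later"):
            mask = None if s == "all" else (rows["stratum"].to_numpy() == s)
            scans[s] = run_gwas(y, g_cohort, C=C, stratum=s, mask=mask)
            io.write_sumstats(scans[s], out / f"gwas_{s}.tsv")
        loci = {
            s: clump_leads(scans[s], threshold=cfg.gwas_alpha, radius=cfg.clump_radius_bp)
            for s in scans
        }
        sig_ids = sorted(
            {m for s in ("first", "later") for loc in loci[s] for m in loc.members}
        )
        r_eff, concord, why = effect_correlation(scans["first"], scans["later"], sig_ids)
        report["stages"][stage] = {
            "status": "ok",
            "n_loci": {s: len(loci[s]) for s in loci},
            "leads": {s: [loc.lead for loc in loci[s]] for s in loci},
            "effect_correlation_r": r_eff,
            "sign_concordance": concord,
            "effect_correlation_note": why,
        }
        log.info("gwas: loci per stratum %s", report["stages"][stage]["n_loci"])
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    # --- SNP x parity interaction ----------------------------------------
    stage = "interaction"
    try:
        candidates = sig_ids if sig_ids else None
        itab, alpha_bonf = run_interaction_scan(
            y, g_cohort, env, C=C, variant_ids=candidates, family_alpha=cfg.family_alpha
        )
        io.write_table(itab, out / "interaction.tsv")
        tested = itab.loc[itab["p_inter"].notna()]
        hits: list[str] = []
        if len(tested):
            _, hits = bonferroni(
                tested.set_index("id")["p_inter"], family_alpha=cfg.family_alpha
            )
        (out / "interaction_meta.json").write_text(
            json.dumps(
                {"n_tests": int(len(tested)), "alpha_bonf": alpha_bonf, "significant": hits}
            )
        )
        report["stages"][stage] = {
            "status": "ok",
            "n_tests": int(len(tested)),
            "alpha_bonf": alpha_bonf,
            "significant": hits,
        }
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    # --- LDSC -------------------------------------------------------------
    stage = "ldsc"
    try:
        scores = compute_ld_scores(g_cohort, window_bp=cfg.ld_window_bp)
        st = scores.table.rename(columns={"ell": "L2"})
        io.write_table(st[["id", "chrom", "pos", "L2"]], out / "ld_scores.tsv")
        M = g_cohort.n_variants
        fits = {
            s: fit_h2(
                scans[s],
                scores,
                N=float(scans[s]["n"].iloc[0]),
                M=M,
                n_blocks=cfg.ldsc_blocks,
            )
            for s in ("first", "later")
        }
        rg_fit = fit_rg(
            scans["first"],
            scans["later"],
            scores,
            N_a=float(scans["first"]["n"].iloc[0]),
            N_b=float(scans["later"]["n"].iloc[0]),
            M=M,
            n_blocks=cfg.ldsc_blocks,
        )
        ldsc_json = {
            "h2": {
                s: {
                    "h2": fits[s].h2,
                    "se_h2": fits[s].se_h2,
                    "intercept": fits[s].intercept,
                    "se_intercept": fits[s].se_intercept,
                    "n_blocks": fits[s].n_blocks,
                    "M": fits[s].M,
                    "N": fits[s].N,
                }
                for s in fits
            },
            "rg": {
                "gencov": rg_fit.gencov,
                "rg": rg_fit.rg,
                "se_rg": rg_fit.se_rg,
                "intercept": rg_fit.intercept,
                "reason": rg_fit.reason,
            },
        }
        (out / "ldsc.json").write_text(json.dumps(ldsc_json, indent=2))
        report["stages"][stage] = {"status": "ok", **ldsc_json}
        log.info(
            "ldsc: h2_first=%.3f h2_later=%.3f rg=%s",
            fits["first"].h2,
            fits["later"].h2,
            "NA" if rg_fit.rg is None else f"{rg_fit.rg:.3f}",
        )
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    # --- RF score ---------------------------------------------------------
    stage = "rfscore"
    try:
        if sig_ids:
            top_ids = sig_ids
        else:
            # fall back to the smallest-p variants of the whole-sample scan
            ok = scans["all"].dropna(subset=["p"]).sort_values("p")
            top_ids = ok["id"].head(cfg.rf_top_k).tolist()
        g_top = g_cohort.subset_variants(top_ids)
        y_res = residualise(y, C, covariate_names=cov_names)
        rf_seed = _stage_seed(cfg.seed, "rf")
        rf = fit_rf_score(y_res, g_top, R=cfg.rf_reps, seed=rf_seed)
        sfit = score_parity_interaction(y, rf.score, env)
        strat = stratified_r2(
            {
                s: residualise(
                    y[rows["stratum"] == s],
                    C[(rows["stratum"] == s).to_numpy()],
                    covariate_names=cov_names,
                )
                for s in STRATA
            },
            {s: g_top.subset_samples(rows.loc[rows["stratum"] == s, "sample_id"]) for s in STRATA},
            R=cfg.rf_reps,
            seed=rf_seed,
        )
        io.write_table(
            pd.DataFrame({"sample_id": rows["sample_id"], "score": rf.score}),
            out / "rf_score.tsv",
        )
        rf_json = {
            "hyperparams": rf.hyperparams,
            "R": rf.R,
            "n_features": len(rf.feature_ids),
            "r2_median": rf.r2_median,
            "r2_ci": list(rf.r2_ci),
            "interaction": {
                "beta1_score": sfit.beta1,
                "beta2_parity": sfit.beta2,
                "beta3_inter": sfit.beta3,
                "se3": sfit.se3,
                "p3": sfit.p3,
            },
            "stratified": {
                s: {"r2_median": r.r2_median, "r2_ci": list(r.r2_ci)}
                for s, r in strat.results.items()
            },
            "stratified_ci_overlap": strat.ci_overlap,
            "fold_change_median_r2": strat.fold_change_median_r2,
        }
        (out / "rf_score.json").write_text(json.dumps(rf_json, indent=2))
        report["stages"][stage] = {"status": "ok", **rf_json}
        log.info("rfscore: r2=%.3f p3=%.2g", rf.r2_median, sfit.p3)
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    # --- variance decomposition ------------------------------------------
    stage = "variance"
    try:
        decomp = decompose_variance(
            {s: y[rows["stratum"] == s] for s in STRATA}, fits
        )
        (out / "variance.json").write_text(json.dumps(decomp.to_dict(), indent=2))
        report["stages"][stage] = {"status": "ok", **decomp.to_dict()}
    except Exception as e:  # noqa: BLE001
        fail(stage, e)

    # --- manifest + report -----------------------------------------------
    report["manifest"] = {
        "seed": cfg.seed,
        "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in ("sim", "qc", "rf")},
        "artifact_checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# parity-gxe run report", ""]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            if k == "status":
                continue
            lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)
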