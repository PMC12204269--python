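"""LD scores vs a brute-force oracle; LDSC heritability and rg fits."""

import numpy as np
import pandas as pd
import pytest

from parity_gxe.ldscore import LdScores, compute_ld_scores, fit_h2, fit_rg
from parity_gxe.simcohort import DosageMatrix, SimConfig, simulate_cohort


def brute_force_ld_scores(g, window_bp, adjusted):
    """Independent pairwise-loop oracle for the windowed r2 sums."""
    n, m = g.dosages.shape
    D = g.dosages.astype(float)
    ell = np.ones(m)
    for j in range(m):
        for k in range(m):
            if k == j:
                continue
            if g.variants.at[j, "chrom"] != g.variants.at[k, "chrom"]:
                continue
            if abs(int(g.variants.at[j, "pos"]) - int(g.variants.at[k, "pos"])) > window_bp:
                continue
            if D[:, j].std() == 0 or D[:, k].std() == 0:
                continue
            r = np.corrcoef(D[:, j], D[:, k])[0, 1]
            r2 = r * r
            if adjusted:
                r2 = r2 - (1 - r2) / (n - 2)
            ell[j] += r2
    return ell


def _toy_geno(seed=0, n=200, m=12):
    cfg = SimConfig(n_samples=n, n_variants=m, n_blocks=3, ld_rho=0.7, n_causal=2, seed=seed)
    from parity_gxe.simcohort import simulate_genotypes

    return simulate_genotypes(cfg)


class TestComputeLdScores:
    @pytest.mark.parametrize("adjusted", [False, True])
    def test_matches_pairwise_oracle(self, adjusted):
        g = _toy_geno()
        scores = compute_ld_scores(g, window_bp=25_000, adjusted=adjusted)
        oracle = brute_force_ld_scores(g, 25_000, adjusted)
        np.testing.assert_allclose(scores.table["ell"].to_numpy(), oracle, atol=1e-12)

    def test_independence_limit(self):
        cfg = SimConfig(
            n_samples=10_000, n_variants=30, n_blocks=30, n_causal=5, ld_rho=0.0, seed=2
        )
        from parity_gxe.simcohort import simulate_genotypes

        g = simulate_genotypes(cfg)
        scores = compute_ld_scores(g, adjusted=False)
        ell = scores.table["ell"].to_numpy()
        m_window = 29
        assert np.all(ell >= 1.0)
        assert np.all(ell <= 1.0 + 0.1 * m_window)

    def test_duplicate_column_doubles_score(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 500)
        dos = np.column_stack([x, x]).astype(np.int8)
        g = DosageMatrix(
            dosages=dos,
            variants=pd.DataFrame(
                {"chrom": "1", "pos": [100, 200], "id": ["a", "b"], "ref": "A", "alt": "G"}
            ),
            sample_ids=[f"S{i}" for i in range(500)],
        )
        scores = compute_ld_scores(g, adjusted=False)
        assert np.all(scores.table["ell"].to_numpy() >= 2.0 - 1e-12)

    def test_zero_variance_variant_scores_one(self):
        rng = np.random.default_rng(4)
        dos = np.column_stack([rng.integers(0, 3, 100), np.zeros(100)]).astype(np.int8)
        g = DosageMatrix(
            dosages=dos,
            variants=pd.DataFrame(
                {"chrom": "1", "pos": [100, 200], "id": ["a", "b"], "ref": "A", "alt": "G"}
            ),
            sample_ids=[f"S{i}" for i in range(100)],
        )
        scores = compute_ld_scores(g, adjusted=False)
        assert scores.table["ell"].iloc[1] == pytest.approx(1.0)


def _fake_sumstats(ids, z, n):
    """Summary stats with beta/se chosen so beta/se = z."""
    m = len(ids)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "id": ids,
            "effect_allele": "G",
            "other_allele": "A",
            "eaf": 0.3,
            "beta": z * 0.01,
            "se": 0.01,
            "p": 0.5,
            "n": n,
            "stratum": "all",
        }
    )


def _fake_scores(ids, ell):
    m = len(ids)
    return LdScores(
        table=pd.DataFrame(
            {"id": ids, "chrom": "1", "pos": np.arange(1, m + 1) * 1000, "ell": ell}
        ),
        window_bp=1_000_000,
        adjusted=False,
    )


class TestFitH2:
    def test_flat_chi2_gives_zero_h2(self):
        ids = [f"v{i}" for i in range(100)]
        ss = _fake_sumstats(ids, z=np.ones(100), n=1000)  # chi2 = 1 everywhere
        scores = _fake_scores(ids, np.linspace(1, 10, 100))
        fit = fit_h2(ss, scores, N=1000, M=100)
        assert fit.h2 == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_regression(self):
        # ell = 1 with chi2 = 1, ell = 11 with chi2 = 2 -> slope 0.1;
        # h2 = slope * M / N = 0.1 when N = M (unweighted pass)
        ids = [f"v{i}" for i in range(40)]
        ell = np.array([1.0] * 20 + [11.0] * 20)
        z = np.sqrt(np.array([1.0] * 20 + [2.0] * 20))
        ss = _fake_sumstats(ids, z=z, n=40)
        fit = fit_h2(ss, _fake_scores(ids, ell), N=40, M=40, weighted=False, n_blocks=4)
        assert fit.h2 == pytest.approx(0.1, abs=1e-10)
        assert fit.intercept == pytest.approx(0.9, abs=1e-10)

    def test_invariant_to_row_order_and_chi2_rescaling(self):
        ids = [f"v{i}" for i in range(60)]
        rng = np.random.default_rng(5)
        z = rng.standard_normal(60) * 1.4
        ell = rng.uniform(1, 8, 60)
        ss = _fake_sumstats(ids, z=z, n=500)
        scores = _fake_scores(ids, ell)
        fit = fit_h2(ss, scores, N=500, M=60)
        shuffled = ss.sample(frac=1, random_state=1).reset_index(drop=True)
        fit2 = fit_h2(shuffled, scores, N=500, M=60)
        assert fit2.h2 == pytest.approx(fit.h2, rel=1e-10)
        scaled = ss.assign(beta=ss["beta"] * 3.7, se=ss["se"] * 3.7)
        fit3 = fit_h2(scaled, scores, N=500, M=60)
        assert fit3.h2 == pytest.approx(fit.h2, rel=1e-10)

    def test_too_few_variants_for_blocks(self):
        ids = [f"v{i}" for i in range(5)]
        ss = _fake_sumstats(ids, z=np.ones(5), n=100)
        with pytest.raises(ValueError, match="blocks"):
            fit_h2(ss, _fake_scores(ids, np.ones(5)), N=100, M=5, n_blocks=4)

    def test_recovery_on_simulated_architecture(self):
        cfg = SimConfig(
            n_samples=4000,
            n_variants=800,
            n_blocks=20,
            ld_rho=0.9,
            n_causal=160,
            h2_by_stratum={"first": 0.3, "later": 0.3},
            seed=6,
        )
        from parity_gxe.assoc import run_gwas

        g, sim = simulate_cohort(cfg)
        res = run_gwas(sim.y, g)
        scores = compute_ld_scores(g)
        fit = fit_h2(res, scores, N=4000, M=800, constrain_intercept=True)
        assert abs(fit.h2 - 0.3) < 3 * fit.se_h2 + 0.05
        assert fit.se_h2 > 0

    def test_jackknife_stable_in_block_count(self):
        cfg = SimConfig(
            n_samples=2000, n_variants=600, n_blocks=15, ld_rho=0.9,
            n_causal=120, h2_by_stratum={"first": 0.3, "later": 0.3}, seed=7,
        )
        from parity_gxe.assoc import run_gwas

        g, sim = simulate_cohort(cfg)
        res = run_gwas(sim.y, g)
        scores = compute_ld_scores(g)
        f20 = fit_h2(res, scores, N=2000, M=600, n_blocks=20)
        f40 = fit_h2(res, scores, N=2000, M=600, n_blocks=40)
        assert abs(f40.se_h2 - f20.se_h2) < 0.5 * f20.se_h2


class TestFitRg:
    def _stratified_fit(self, seed, rho, constrain=True, n=2500, M=800):
        cfg = SimConfig(
            n_samples=2 * n,
            n_variants=M,
            n_blocks=M // 40,
            ld_rho=0.9,
            n_causal=M // 5,
            h2_by_stratum={"first": 0.3, "later": 0.3},
            rho_g=rho,
            p_first_pregnancy=0.5,
            seed=seed,
        )
        from parity_gxe.assoc import run_gwas

        g, sim = simulate_cohort(cfg)
        mf = sim.stratum == "first"
        ra = run_gwas(sim.y, g, stratum="first", mask=mf)
        rb = run_gwas(sim.y, g, stratum="later", mask=~mf)
        scores = compute_ld_scores(g)
        return fit_rg(
            ra, rb, scores, N_a=mf.sum(), N_b=(~mf).sum(), M=M,
            constrain_intercept=constrain,
        )

    def test_self_rg_is_one(self, small_sim):
        from parity_gxe.assoc import run_gwas

        g, sim = small_sim
        res = run_gwas(sim.y, g)
        scores = compute_ld_scores(g)
        fit = fit_rg(res, res.copy(), scores, N_a=600, N_b=600, M=g.n_variants)
        assert fit.rg == pytest.approx(1.0, abs=1e-8)
        assert fit.se_rg == pytest.approx(0.0, abs=1e-8)

    def test_allele_flip_invariance(self, small_sim):
        from parity_gxe.assoc import run_gwas

        g, sim = small_sim
        res = run_gwas(sim.y, g)
        scores = compute_ld_scores(g)
        flipped = res.copy()
        rows = np.arange(0, len(flipped), 3)
        flipped.loc[rows, "beta"] *= -1
        flipped.loc[rows, "eaf"] = 1 - flipped.loc[rows, "eaf"]
        flipped.loc[rows, ["effect_allele", "other_allele"]] = (
            flipped.loc[rows, ["other_allele", "effect_allele"]].to_numpy()
        )
        base = fit_rg(res, res.copy(), scores, N_a=600, N_b=600, M=g.n_variants)
        flip = fit_rg(res, flipped, scores, N_a=600, N_b=600, M=g.n_variants)
        assert flip.rg == pytest.approx(base.rg, abs=1e-10)

    def test_null_permutation_rg_near_zero(self):
        fit = self._stratified_fit(seed=8, rho=0.0)
        assert fit.rg is not None
        assert abs(fit.rg) < max(3 * fit.se_rg, 0.3)

    def test_rho_recovery_point_estimate(self):
        fit = self._stratified_fit(seed=9, rho=0.7)
        assert fit.rg == pytest.approx(0.7, abs=0.25)

    def test_non_positive_h2_returns_reason(self):
        ids = [f"v{i}" for i in range(100)]
        rng = np.random.default_rng(10)
        # chi2 decreasing in ell -> negative h2 slope
        ell = np.linspace(1, 10, 100)
        z = np.sqrt(np.maximum(2.0 - 0.15 * ell, 0.05)) * np.sign(rng.standard_normal(100))
        ss = _fake_sumstats(ids, z=z, n=500)
        scores = _fake_scores(ids, ell)
        fit = fit_rg(ss, ss.copy(), scores, N_a=500, N_b=500, M=100)
        assert fit.rg is None and "heritability" in fit.reason
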