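"""Association scans vs an independent OLS oracle; clumping; proxies."""

import numpy as np
import pandas as pd
import pytest

from parity_gxe.assoc import (
    CollinearityError,
    clump_leads,
    effect_correlation,
    find_proxy,
    fit_snp,
    run_gwas,
)
from parity_gxe.simcohort import DosageMatrix, SimConfig, simulate_cohort

from conftest import ols_oracle


def _random_instance(rng, n=50, k=3):
    g = rng.integers(0, 3, size=n).astype(float)
    C = rng.standard_normal((n, k))
    y = 0.3 * g + C @ rng.standard_normal(k) + rng.standard_normal(n)
    return y, g, C


class TestFitSnp:
    def test_exact_fit(self):
        g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        beta, se, p, n = fit_snp(2 * g, g)
        assert beta == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_gives_zero(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 40).astype(float)
        y = rng.standard_normal(40)
        y = y - g * (g @ y) / (g @ g)
        y = y - y.mean() + 0  # keep intercept orthogonality too
        # residualise y on [1, g] to force beta exactly 0
        X = np.column_stack([np.ones(40), g])
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        beta, *_ = fit_snp(y, g)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_100_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y, g, C = _random_instance(rng)
            beta, se, p, n = fit_snp(y, g, C)
            ob, ose, op, _ = ols_oracle(y, np.column_stack([np.ones(len(y)), g, C]))
            assert beta == pytest.approx(ob[1], abs=1e-10)
            assert se == pytest.approx(ose[1], abs=1e-10)
            assert p == pytest.approx(op[1], abs=1e-8)

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 30).astype(float)
        C = np.column_stack([g, rng.standard_normal(30)])  # C duplicates g
        with pytest.raises(CollinearityError):
            fit_snp(rng.standard_normal(30), g, C)


class TestRunGwas:
    def test_matches_fit_snp_per_variant(self, small_sim):
        g, sim = small_sim
        res = run_gwas(sim.y, g, C=None, stratum="all")
        for j in [0, 17, 63, 119]:
            beta, se, p, n = fit_snp(sim.y, g.dosages[:, j].astype(float))
            row = res.iloc[j]
            assert row["beta"] == pytest.approx(beta, abs=1e-10)
            assert row["se"] == pytest.approx(se, abs=1e-10)
            assert row["p"] == pytest.approx(p, rel=1e-8)

    def test_stratum_partition(self, small_sim):
        g, sim = small_sim
        res_all = run_gwas(sim.y, g, stratum="all")
        res_f = run_gwas(sim.y, g, stratum="first", mask=sim.stratum == "first")
        res_l = run_gwas(sim.y, g, stratum="later", mask=sim.stratum == "later")
        assert (res_f["n"] + res_l["n"] == res_all["n"]).all()

    def test_monomorphic_reported_not_dropped(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(100, 3)).astype(np.int8)
        dos[:, 1] = 0  # monomorphic
        g = DosageMatrix(
            dosages=dos,
            variants=pd.DataFrame(
                {"chrom": "1", "pos": [100, 200, 300], "id": ["a", "b", "c"],
                 "ref": "A", "alt": "G"}
            ),
            sample_ids=[f"S{i}" for i in range(100)],
        )
        res = run_gwas(rng.standard_normal(100), g)
        assert len(res) == 3
        assert res.loc[res["id"] == "b", "reason"].item() == "low_mac"
        assert np.isnan(res.loc[res["id"] == "b", "beta"].item())

    def test_type_one_error_and_inflation_under_null(self):
        cfg = SimConfig(
            n_samples=2000,
            n_variants=2000,
            n_blocks=100,
            n_causal=0,
            h2_by_stratum={"first": 0.0, "later": 0.0},
            seed=77,
        )
        g, sim = simulate_cohort(cfg)
        res = run_gwas(sim.y, g)
        p = res["p"].dropna()
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06  # binomial 95% band at 2000 trials
        chi2 = ((res["beta"] / res["se"]) ** 2).dropna()
        assert 0.95 <= chi2.mean() <= 1.05

    def test_single_strong_causal_attains_min_p(self):
        cfg = SimConfig(
            n_samples=5000,
            n_variants=200,
            n_blocks=200,  # independent variants
            ld_rho=0.0,
            n_causal=1,
            h2_by_stratum={"first": 0.2, "later": 0.2},
            rho_g=1.0,
            seed=31,
        )
        g, sim = simulate_cohort(cfg)
        res = run_gwas(sim.y, g)
        causal_id = g.variants["id"][np.flatnonzero(sim.effects["first"])[0]]
        assert res.loc[res["p"].idxmin(), "id"] == causal_id


class TestClumpLeads:
    def _frame(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "p"])
        df["effect_allele"] = "G"
        df["other_allele"] = "A"
        return df

    def test_hand_run_of_greedy_rule(self):
        res = self._frame(
            [
                ("1", 1_000_000, "v1", 1e-10),
                ("1", 2_000_000, "v2", 1e-9),
                ("1", 4_000_000, "v3", 1e-9),
            ]
        )
        loci = clump_leads(res)
        assert [l.lead for l in loci] == ["v1", "v3"]
        assert set(loci[0].members) == {"v1", "v2"}

    def test_no_significant_variants(self):
        res = self._frame([("1", 1000, "v1", 1e-3)])
        assert clump_leads(res) == []

    def test_all_within_one_radius(self):
        res = self._frame(
            [("2", 1_000_000 + 1000 * i, f"v{i}", 1e-9 / (i + 1)) for i in range(5)]
        )
        loci = clump_leads(res)
        assert len(loci) == 1
        assert loci[0].lead_p == min(res["p"])

    def test_every_significant_variant_in_exactly_one_locus(self):
        rng = np.random.default_rng(4)
        rows = [
            ("1", int(p), f"v{i}", 10.0 ** -rng.uniform(7, 15))
            for i, p in enumerate(np.sort(rng.integers(1, 2e7, size=40)))
        ]
        res = self._frame(rows)
        loci = clump_leads(res)
        members = [m for l in loci for m in l.members]
        sig = res.loc[res["p"] < 5e-8, "id"]
        assert sorted(members) == sorted(sig)

    def test_lead_set_invariant_under_row_order(self):
        rng = np.random.default_rng(5)
        rows = [
            ("1", int(rng.integers(1, 2e7)), f"v{i}", 10.0 ** -rng.uniform(7, 12))
            for i in range(30)
        ]
        res = self._frame(rows)
        shuffled = res.sample(frac=1, random_state=9).reset_index(drop=True)
        assert [l.lead for l in clump_leads(res)] == [l.lead for l in clump_leads(shuffled)]

    def test_different_chromosomes_never_merge(self):
        res = self._frame([("1", 1000, "a", 1e-10), ("2", 1000, "b", 1e-9)])
        assert len(clump_leads(res)) == 2


class TestEffectCorrelation:
    def _res(self, ids, betas, ea="G", oa="A"):
        return pd.DataFrame(
            {"id": ids, "beta": betas, "effect_allele": ea, "other_allele": oa}
        )

    def test_identical_and_negated(self):
        ids = list("abcd")
        b = [0.1, -0.2, 0.3, 0.4]
        r, c, _ = effect_correlation(self._res(ids, b), self._res(ids, b), ids)
        assert r == pytest.approx(1.0) and c == 1.0
        r, c, _ = effect_correlation(
            self._res(ids, b), self._res(ids, [-x for x in b]), ids
        )
        assert r == pytest.approx(-1.0) and c == 0.0

    def test_too_few_variants(self):
        r, c, reason = effect_correlation(
            self._res(["a"], [0.1]), self._res(["a"], [0.1]), ["a"]
        )
        assert r is None and "fewer than 3" in reason

    def test_allele_flip_invariance(self):
        ids = list("abcde")
        rng = np.random.default_rng(6)
        b = rng.standard_normal(5)
        first = self._res(ids, b)
        later = self._res(ids, b + 0.1)
        flipped = later.copy()
        flipped.loc[[1, 3], "beta"] *= -1
        flipped.loc[[1, 3], ["effect_allele", "other_allele"]] = ["A", "G"]
        r0, c0, _ = effect_correlation(first, later, ids)
        r1, c1, _ = effect_correlation(first, flipped, ids)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert c1 == c0


class TestMatchLeads:
    def test_identical_and_ld_proxied_leads_pair_up(self):
        from parity_gxe.assoc import Locus, match_leads

        rng = np.random.default_rng(12)
        x = rng.integers(0, 3, 600)
        near_dup = np.where(rng.random(600) < 0.03, rng.integers(0, 3, 600), x)
        other = rng.integers(0, 3, 600)
        dos = np.column_stack([x, near_dup, other]).astype(np.int8)
        g = DosageMatrix(
            dosages=dos,
            variants=pd.DataFrame(
                {"chrom": "1", "pos": [1000, 2000, 3000],
                 "id": ["a", "a_tag", "b"], "ref": "A", "alt": "G"}
            ),
            sample_ids=[f"S{i}" for i in range(600)],
        )
        la = [Locus(lead="a", lead_p=1e-10, chrom="1", pos=1000),
              Locus(lead="b", lead_p=1e-9, chrom="1", pos=3000)]
        lb = [Locus(lead="a_tag", lead_p=1e-9, chrom="1", pos=2000)]
        pairs = match_leads(la, lb, g)
        assert len(pairs) == 1
        a, b, r2 = pairs[0]
        assert (a, b) == ("a", "a_tag") and r2 > 0.85

    def test_independent_leads_do_not_match(self):
        from parity_gxe.assoc import Locus, match_leads

        rng = np.random.default_rng(13)
        dos = rng.integers(0, 3, size=(400, 2)).astype(np.int8)
        g = DosageMatrix(
            dosages=dos,
            variants=pd.DataFrame(
                {"chrom": "1", "pos": [1000, 2000], "id": ["a", "b"],
                 "ref": "A", "alt": "G"}
            ),
            sample_ids=[f"S{i}" for i in range(400)],
        )
        la = [Locus(lead="a", lead_p=1e-10, chrom="1", pos=1000)]
        lb = [Locus(lead="b", lead_p=1e-9, chrom="1", pos=2000)]
        assert match_leads(la, lb, g) == []


class TestFindProxy:
    def _geno(self, cols, positions, ids):
        dos = np.column_stack(cols).astype(np.int8)
        return DosageMatrix(
            dosages=dos,
            variants=pd.DataFrame(
                {"chrom": "1", "pos": positions, "id": ids, "ref": "A", "alt": "G"}
            ),
            sample_ids=[f"S{i}" for i in range(dos.shape[0])],
        )

    def test_largest_r2_selected(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 500)

        def noisy(r):
            flip = rng.random(500) < (1 - r) / 2
            out = np.where(flip, rng.integers(0, 3, 500), x)
            return out

        g = self._geno(
            [x, noisy(0.3), noisy(0.6), noisy(0.9)],
            [100, 200, 300, 400],
            ["t", "lo", "mid", "hi"],
        )
        pid, r2 = find_proxy("t", g, window_bp=1000, min_r2=0.3)
        assert pid == "hi" and r2 > 0.3

    def test_perfect_duplicate(self):
        x = np.random.default_rng(8).integers(0, 3, 200)
        g = self._geno([x, x.copy()], [100, 500], ["t", "dup"])
        pid, r2 = find_proxy("t", g, window_bp=1000)
        assert pid == "dup" and r2 == pytest.approx(1.0)

    def test_threshold_strict(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 3, 300)
        y = rng.integers(0, 3, 300)  # independent, r2 ~ 0
        g = self._geno([x, y], [100, 200], ["t", "c"])
        pid, r2 = find_proxy("t", g, window_bp=1000, min_r2=0.3)
        assert pid is None and r2 is None

    def test_window_excludes_distant(self):
        x = np.random.default_rng(10).integers(0, 3, 200)
        g = self._geno([x, x.copy()], [100, 700_000], ["t", "dup"])
        pid, _ = find_proxy("t", g)  # default +/- 550 kb
        assert pid is None

    def test_unknown_target_raises(self, small_genotypes):
        with pytest.raises(KeyError):
            find_proxy("nope", small_genotypes)
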