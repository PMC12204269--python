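# parity-gxe

Does parity — the number of children a mother has previously delivered —
modify genetic effects on pregnancy outcomes?  `parity-gxe` implements the
full analysis chain for that question on registry-style cohorts, for
gestational duration (days) and birth weight (z-scores):

1. **Cohort QC** — parity-history validation, one random pregnancy per
   mother, phenotype-specific inclusion rules (singleton, non-ART,
   spontaneous onset, 154–308 d for gestational duration; 259–300 d and a
   ±5 SD trim for birth weight), with a per-filter exclusion audit.
2. **Parity-stratified GWAS** — covariate-adjusted per-SNP OLS
   (y ~ 1 + g + C) in the whole sample and within first/later-pregnancy
   strata, greedy 1.5 Mb lead-locus clumping at p < 5×10⁻⁸, cross-stratum
   effect-size correlation, and ±550 kb LD-proxy search (r² > 0.3).
3. **SNP × parity interaction** — y ~ 1 + g + env + g·env + C with Bonferroni
   control over the candidate set.
4. **LD-score regression** — locally computed windowed LD scores
   ℓ_j = Σ_k r²_jk, heritability from E[χ²] = N·h²·ℓ/M + intercept,
   cross-stratum genetic correlation r_g = gencov/√(h²_first·h²_later), with
   block-jackknife standard errors.  r_g < 1 between parity strata is the
   headline signal of parity-dependent genetic effects.
5. **Random-forest OOB genetic score** — forests on hard-coded candidate
   genotypes predicting the covariate-residualised phenotype; per-sample mean
   out-of-bag score over R repetitions; r²_oob = 1 − MSE/σ² with a percentile
   credible interval; and the score × parity interaction
   y = β₀ + β₁·score + β₂·parity + β₃·score·parity.
6. **Variance decomposition** — VA = h²·VP per stratum with delta-method SEs.

Individual-level cohort data of this kind are access-controlled, so the
package ships a first-class synthetic cohort generator (`simcohort`):
HWE genotypes with blockwise LD, per-stratum effect sizes with a tunable
cross-stratum correlation ρ_g, parity-dependent phenotype means/variances,
and deliberately malformed registry records for the QC filters to catch.
Every stage is tested against this generator's known truth.

## Worked example

```python
import parity_gxe as pg
from parity_gxe.simcohort import SimConfig

cfg = SimConfig(
    n_samples=6000, n_variants=1000, n_blocks=25, ld_rho=0.9, n_causal=200,
    h2_by_stratum={"first": 0.3, "later": 0.3},
    vp_by_stratum={"first": 169.0, "later": 121.0},   # days^2
    rho_g=0.7, p_first_pregnancy=0.5, seed=7919,
)
g, sim = pg.simulate_cohort(cfg)

first = sim.stratum == "first"
gwas_first = pg.run_gwas(sim.y, g, stratum="first", mask=first)
gwas_later = pg.run_gwas(sim.y, g, stratum="later", mask=~first)

scores = pg.compute_ld_scores(g)                       # 1 Mb window
rg = pg.fit_rg(gwas_first, gwas_later, scores,
               N_a=int(first.sum()), N_b=int((~first).sum()),
               M=g.n_variants, constrain_intercept=True)
print(f"h2 first = {rg.fit_a.h2:.3f} (SE {rg.fit_a.se_h2:.3f})")
print(f"h2 later = {rg.fit_b.h2:.3f} (SE {rg.fit_b.se_h2:.3f})")
print(f"rg       = {rg.rg:.3f} (SE {rg.se_rg:.3f})")
```

prints

```
h2 first = 0.378 (SE 0.098)
h2 later = 0.266 (SE 0.048)
rg       = 0.788 (SE 0.061)
```

The simulated cross-stratum effect correlation was 0.7: both stratum
heritability intervals cover the generative 0.3, and the genetic correlation
estimate sits well below 1 — the signature of parity-dependent effect sizes
the pipeline is built to detect.

The same analysis runs end to end from the shell, including QC, the
interaction scan, the forest score and the report:

```bash
parity-gxe run-all --seed 7 --out demo_run/
cat demo_run/report.md
```

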