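# Methods

`parity-gxe` asks whether parity — the number of a mother's previous
deliveries — modifies maternal (or foetal) genetic effects on two pregnancy
phenotypes: gestational duration (days) and birth weight (analysed as
z-scores).  The package implements the full inference chain on registry-style
data and ships a synthetic cohort generator so that every stage can be tested
against known truth without access to individual-level cohort data.

## The synthetic cohort

**Genotypes.** For each of `n_samples` mothers, two haplotypes are drawn per
LD block as a first-order Markov chain: within a block, adjacent sites have
allele correlation `ld_rho`; blocks are independent.  Per-variant alt-allele
frequencies are uniform on `maf_range`.  Dosages (0/1/2) are the sum of the
two independent haplotypes, so Hardy–Weinberg equilibrium holds by
construction; realized LD (r²) is whatever the haplotypes produce, and is
always measured from the data rather than assumed.  Variants sit on one
chromosome at 5 kb spacing, giving blocks a physical extent that the 1 Mb
LD-score window and the 1.5 Mb clumping radius can interact with.  The default
`ld_rho` for statistical studies in the tests is 0.9 with blocks of ~40
variants (~200 kb), chosen to produce an LD-score range (roughly 1–7) wide
enough to identify the LD-score regression slope at desk-scale M; weaker LD
leaves the slope/intercept decomposition poorly identified at a few thousand
variants.

**Effects.** `n_causal` variants are chosen uniformly; their per-stratum
effect pairs (β_first, β_later) are bivariate normal with correlation
`rho_g`, then each stratum's vector is rescaled so that the expected additive
genetic variance Σ_j 2p_j(1−p_j)β²_{s,j} equals h²_s·VP_s exactly (asserted to
1e-10 in the tests).  `rho_g` is the generative counterpart of the
cross-stratum genetic correlation the LDSC stage estimates; `rho_g = 1` with
equal per-stratum scalings gives identical effects in both strata.

**Phenotypes and registry.** Each mother is assigned to the first-pregnancy
stratum with probability `p_first_pregnancy`, and

    y_i = μ_s + Σ_j β_{s,j}(g_ij − 2p_j) + γ'c_i + ε_i,   ε_i ~ N(0, σ²_s),

with σ²_s = VP_s − h²_s·VP_s − Var(γ'c) so that Var(y | s) = VP_s in
expectation.  Centring the dosages makes μ_s control the stratum mean
exactly.  Covariates (maternal age, foetal sex, genotyping chip, ten
standard-normal PC stand-ins) are generated and adjusted for throughout, but
their effect vector γ defaults to zero: the simulator does not model
population structure or covariate confounding, so covariates act as benign
regressors and the phenotypic variance stays exactly VP_s.  Default presets
emulate the qualitative registry pattern — first pregnancies shorter and more
variable (means 279/282 days, VP 169/121 days²) — and are configurable, not
cohort estimates.  Clean registry gestational durations are kept inside the
analysable 154–308-day window; out-of-range values, ART pregnancies,
multiples, duplicate or out-of-order parity histories and the other
QC-violating record types appear only at the configured `qc_error_rates`.

What the generator does **not** emulate: relatedness, population structure,
imputation dosage uncertainty, the X chromosome, realistic allele-frequency
spectra, or linkage maps.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
model, not robustness to those real-data complications.

## Cohort QC

Filters run in a fixed, documented order, and each removed record is
attributed to the first filter that catches it, so audit counts are well
defined and sum to n_in − n_out.  Parity histories are validated first
(duplicate parity, or parity not strictly increasing in delivery order
flags the mother), then one pregnancy per mother is kept uniformly at random
(seeded), which guarantees no mother appears in both strata.  Gestational
duration analyses keep singleton, non-ART, known-sex, malformation-free
births with no early perinatal death, spontaneous onset, 154 ≤ GD ≤ 308 days
(inclusive), surviving the first year.  Birth-weight analyses apply the
shared exclusions, then 259 ≤ GD ≤ 300 days, then a single-pass ±5 SD trim
with mean/SD computed on the records surviving the earlier filters (the trim
is deliberately not iterated).  Birth weight enters all downstream models as
a z-score using the mean/SD of the final included set (n−1 SD), so stored
values have mean 0, SD 1 exactly.  The one-year-death rule applies only to
gestational duration, and spontaneous onset is not required for birth
weight, mirroring the phenotype definitions.

## Association scans

Per-variant association is ordinary least squares of the phenotype on
[1, g, C], with the gestational-duration covariate set (maternal age, sex,
chip, 10 PCs) or the birth-weight set (sex, chip, gestational duration,
10 PCs).  Genome-wide scans project the covariates out once (Frisch–Waugh)
— algebraically identical to the per-variant fit, verified against an
independent normal-equations oracle to 1e-10.  p-values use the exact t
distribution with n − k − 1 df.  Variants with minor-allele count below 5
are reported with a reason code rather than dropped, keeping row counts
identical across strata.  A whole-genome ridge step for
relatedness/polygenicity control is deliberately absent: simulated samples
are unrelated, and the one-pregnancy-per-mother rule plus a kinship cutoff
are treated as input assumptions.  Lead loci are greedy distance clumps:
smallest p first, absorbing significant variants within 1.5 Mb on the same
chromosome; ties break by (chrom, pos).  Proxy search scans ±550 kb and
returns the candidate with the largest dosage r², required to exceed 0.3
strictly; ties break by distance then position.  A companion utility pairs
lead variants across two stratum scans, calling two leads the same signal
when they are the same variant or their dosage r² exceeds 0.85 (greedy on
descending r², each lead used once).

## SNP × parity interaction

The interaction model is y ~ 1 + g + env + g·env + C with env the binary
first/later indicator (0 = first).  The binary coding was chosen over raw
parity count because every stratified analysis uses the same dichotomy; an
integer-coded env can be passed to the same functions.  With no covariates,
the g·env coefficient equals the difference of stratum-specific slopes
exactly (asserted to 1e-10).  Significance uses Bonferroni control with the
number of *tested* variants as denominator and a strict inequality.  The
scan is vectorised by residualising y, g and g·env on [1, env, C] and
solving a 2×2 system per variant; the env main effect is recovered from the
same projection.

A calibration caveat: when residual variance differs between parity strata
(as the default generator presets do, 169 vs 121 days²), the homoskedastic
OLS t test for the interaction is mildly anticonservative (empirically
~0.055 at nominal 0.05 for a variance ratio of 1.4).  Robust (sandwich)
variances are out of scope for this version; calibration tests therefore use
equal-variance nulls, and real-data users should treat borderline
interaction p-values near threshold with this in mind.

## LD-score regression

LD scores are computed from the analysed genotypes: ℓ_j = Σ_k r̃²_jk over
variants within a 1 Mb window on the same chromosome, self term included
(exactly 1), with the finite-sample correction r̃² = r² − (1−r²)/(n−2) by
default.  A kb window replaces the reference-panel cM window because the
simulator has no genetic map; the window is configurable.  Heritability is
the slope of the χ² regression E[χ²_j] = N·h²·ℓ_j/M + intercept, weighted by
1/[max(ℓ,1)·(1 + N·ĥ²₍₁₎·ℓ/M)²] with ĥ²₍₁₎ from an unweighted first pass — a
simplification of the full LDSC weighting that omits the separate
regression-weight LD scores.  Genetic covariance regresses z_a·z_b on ℓ with
weights built from unweighted first-pass estimates of both heritabilities
and the covariance, with the intercept term kept inside the covariance
component so that feeding the same summary statistics twice returns rg = 1
identically.  rg = gencov/√(h²_a·h²_b) and is reported as undefined, with a
reason, when either heritability estimate is non-positive.

Uncertainty is a delete-one-block jackknife over contiguous equal-count
position blocks (default 20, auto-scaled to at most M/10).  For rg the full
ratio is recomputed per deleted block; a deleted block that drives either
heritability slope non-positive contributes the point estimate (zero
deviation) rather than an exploding ratio, a robustification that can
slightly understate the SE in pathological fits.  The regression intercepts
are free by default (they absorb confounding and sample overlap); a
constrained mode (χ² intercept 1, cross-trait intercept 0) exists for
simulations known to be clean — disjoint strata, no confounding — where it
substantially sharpens the slope, and the parameter-recovery tests use it.
No MAF filter is applied by default since simulated frequencies are
controlled; an optional filter mirrors real-data practice.

## Random-forest out-of-bag genetic score

The phenotype is residualised as mean(y) plus the residual from OLS on the
GWAS covariates, preserving the raw mean.  Forests are trained on hard-coded
candidate-variant dosages; bagging is implemented explicitly (bootstrap
indices drawn outside the tree learner) so per-sample out-of-bag counts are
exact.  Hyperparameters (n_trees ∈ {500}, mtry ∈ {⌈√m⌉, ⌈m/3⌉},
min_node_size ∈ {5, 20} by default; fully configurable) are tuned by OOB
MSE, ties preferring fewer trees then smaller mtry.  With the tuned setting,
R independent forests are fit with derived seeds; each repetition yields one
draw of r²_oob = 1 − MSE_oob/Var(y_res) and an OOB prediction vector, and a
sample's genetic score is its mean OOB prediction over the repetitions where
it was out of bag at least once (never being OOB in any repetition is an
error).  The 95% credible interval of r²_oob is the 2.5th/97.5th percentile
of the R draws.  Var uses the n−1 denominator — chosen to match the
closed-form worked example ({1,2,3,4} vs {1,2,3,8} → r² = −1.4) — so a
constant mean prediction scores 1/n rather than exactly 0.  R is read as
independent forest refits rather than one forest of that many trees; the
reference analysis used 10 000, tests use 4–50, and the acceptance script
uses 20, since the credible interval stabilises quickly.  Extra non-genetic
columns can be appended as features for the genetics-plus-environment
variant of the model.

The centred mean score is then tested for parity interaction:
y ~ β₀ + β₁·score + β₂·env + β₃·score·env, with β₃'s two-sided t test.  With
the env coding used here (1 = later pregnancies), genetic effects that are
stronger in the first pregnancy give β₃ < 0.  Stratified predictability fits
the whole procedure independently per stratum (shared seed, so identical
inputs give identical intervals) and reports interval overlap and the
first/later fold change of the median r².

## Variance decomposition

From h² = VA/VP: per stratum, VP is the n−1 sample variance of the analysed
phenotype, VA = h²·VP, and the VA standard error combines se(h²) and the
normal-theory Var(VP) = 2VP²/(n−1) by the delta method.  The
"inferred VA difference" flag reproduces the qualitative argument —
overlapping h² intervals together with non-overlapping VP intervals imply a
VA difference — and is reported as a flag with both intervals, never as a
formal test.

## Orchestration and reproducibility

`run_all` executes QC → stratified GWAS → interaction → LDSC → RF score →
variance decomposition under one config; every stage seed derives
deterministically from the master seed (SHA-256 of seed:stage), every
intermediate artifact is written as TSV/JSON, and reruns with the same
config are byte-stable (checksums recorded in a manifest).  Stage failures
abort with the stage name; partial outputs are retained.

## Problem sizes and test design

Desk-scale studies cannot approach biobank precision, so the test suite
checks *properties*: oracle equivalence of every regression (1e-10), exact
hand fixtures for every rule, calibrated type-I error, and parameter
recovery with calibrated jackknife intervals.  Recovery studies use
M = 1500 variants / n = 4000 samples over 100 replicates for heritability,
M = 1000 / n = 3000 per stratum over 50 seeds per rho_g ∈ {1.0, 0.7, 0.0}
for genetic correlation, and 50 seeds of a 1.5× first-vs-later effect-ratio
design for the directional end-to-end check — sizes chosen so the whole
suite runs serially in minutes while pilot runs showed unbiased means
(e.g. rg means 0.996/0.691/0.020 against 1.0/0.7/0.0) and ≥90% interval
coverage.

## Known limitations

* In-sample LD scores and GWAS from the same sample: fine at these scales
  with the adjusted-r² correction, but reference-panel scores and
  regression-weight corrections would be needed for biobank-scale accuracy.
* Free-intercept LDSC is poorly identified at small M; the ratio estimator
  rg is then unstable.  Constrained intercepts are appropriate only when
  confounding and sample overlap are genuinely absent.
* The OLS interaction test's mild anticonservatism under stratum
  heteroskedasticity (above).
* The forest score, like any bagged OOB construction, gives slightly
  pessimistic r² relative to a fully refit out-of-sample estimate.
* No mixed models, no relatedness handling, no X chromosome, no
  annotation-partitioned heritability.
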