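# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `wildqg`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Genotype QC and relatedness

Input genotypes are dosages (counts of the alternate allele as read from the
input; 0/1/2 with missing allowed), parsed from biallelic VCF records
(multiallelic sites skipped with a logged count) or a TSV table ("NA", ".",
"./." all read as missing). QC applies, in order: locus call rate ≥ 0.90,
MAF > 0.01, individual call rate ≥ 0.85, and observed-heterozygosity bounds
(0.02, 0.98) recomputed on the survivors. The order matters — removing loci
changes the base on which individual call rates and oHET are computed, and
whole-pipeline survivor counts are *not* jointly monotone in the thresholds
(removing more low-MAF loci can raise individual call rates) — so the QC
report carries per-step removal counts. Whether individual call rate should
be computed before or after locus filtering is not decidable from the study
description; this package filters loci first and surfaces the choice in the
report.

Missing dosages are imputed as the locus mean (2p̂), the allele-frequency
expectation used by realized-relatedness software; imputation preserves
column means exactly. The GRM is VanRaden method 1 with a single global
denominator `2Σp(1−p)` and allele frequencies from the analyzed sample
itself (no external reference exists for a wild population); monomorphic
loci are excluded from numerator and denominator with a logged count.
Before entering the animal model the GRM is subset to the phenotyped
plants and ridge-stabilized: if the smallest eigenvalue is below 1e-8, a
diagonal ridge (at least 1e-6) lifts it above that tolerance, and the
applied ridge is recorded.

## Animal model

The observation model for trait records on replicate flowers is

    y = Xb + Z1 a + Z2 s + Z3 i + e,
    a ~ N(0, G V_a),  s ~ N(0, I V_s),  i ~ N(0, I V_i),  e ~ N(0, I V_e),

with X = intercept + centred elevation (linear; with elevation constant
within site and only six sites there is no information to support a spline).
Constant fixed covariates and single-level site factors are dropped
automatically (they are confounded with the intercept and otherwise make
the mixed-model equations singular). The naive variant drops elevation and
site entirely.

**Sampler.** Blocked Gibbs on the mixed-model equations: all location
effects are drawn jointly from N(C⁻¹Wᵀy, V_e C⁻¹) with
C = WᵀW + blockdiag(0, (V_e/V_a)G⁻¹, (V_e/V_s)I, (V_e/V_i)I), then each
variance from its scaled inverse-chi-squared conditional
(ν₀ + q df, sum of squares against the component's structure matrix).
Default priors are weakly informative: ν₀ = 0.002 with scale s₀² = var(y)/4
per component — effectively flat on the scale of the data. Posterior draws
of h², e and r_G are computed per draw and then summarized (posterior mean
and 2.5–97.5% quantiles), never from summarized components.

**Parameter expansion** (`px=True`): each of the additive, site and
permanent-environment effects can be written u = α·ũ with a standard-normal
working parameter α, giving the identified variance α²·Ṽ a heavy-tailed
scaled-F prior (a χ² with one degree of freedom in the numerator). The plain
sampler has a near-absorbing region at zero variance (once the effect
vector collapses, the variance conditional keeps it there); keeping α
explicit lets the chain leave it. Used by default for the near-zero trait
(standard petal area) in the pipeline, available everywhere.

**Identifiability and mixing.** V_a and V_i are separated only by the
off-diagonal structure of G; with a few dozen families this contrast mixes
slowly (effective sample sizes for h² are far below the draw count) and the
posterior mean legitimately sits off the REML point estimate — the
posterior for a family-level variance with ~20 effective groups is
right-skewed, so its mean exceeds its mode. The test suite therefore
validates the sampler against an exact posterior computed by brute-force
quadrature (location effects integrated analytically, variances on a 3-D
log grid) on a small instance, and checks that REML point estimates fall
inside the posterior intervals rather than demanding mean/mode equality.

**Bivariate model.** Effects gain a 2×2 covariance block per component
(Σ_a ⊗ G etc.), sampled from inverse-Wishart conditionals with ν₀ = 4 and
prior scale set so the prior mean is diag(var(y_t))/4; r_G = Σ_a[0,1] /
√(Σ_a[0,0]Σ_a[1,1]) per draw.

**DIC** uses the conditional-on-random-effects deviance: DIC = 2·mean(D) −
D(θ̄) with D the Gaussian deviance at the fitted values including all random
effects, and θ̄ the posterior-mean fitted values and residual variance. This
is the convention of the MCMC mixed-model software family this analysis
style comes from; an alternative marginal DIC would penalize the site and
additive terms differently.

**Chain lengths.** Defaults are n_iter = 5000, burnin = 1000, thin = 2. For
study-grade inference the target is several thousand effective samples,
which for these weakly identified variance ratios means chains an order of
magnitude longer; the test-suite and acceptance runs use 1200–2500
iterations, which is enough for posterior means and 95% quantiles at the
tolerances tested. Two chains at the default length agree on the h²
posterior mean to within 0.02 (tested).

## Selection surface and averaged-derivative coefficients

Plant-level data are plant-mean traits with binomial fruit counts (fruits
of flower scars). Traits are variance-standardized over plants inside the
model, so all coefficients are in SD units. The surface is a penalized
B-spline additive model on the logit scale: cubic B-splines (df = 6 basis
functions per trait, boundary knots padded beyond the data range so
finite-difference probes never extrapolate), second-order difference
penalty, the sum-to-zero constraint absorbed by reparameterization (the
centred B-spline basis otherwise carries an exact null direction because
the raw basis partitions unity). Site enters as a ridge-penalized factor
term (all levels, penalty weight 1 on the logit scale — a random-effect-like
shrinkage); elevation enters linearly but is dropped with a log note when
exactly collinear with site (always true when elevation is constant within
site, as in the study design). Smoothing weights are chosen by coordinate
descent on AIC = deviance + 2·edf with edf = tr[(BᵀWB + S)⁻¹BᵀWB], over a
log grid 10⁻²–10⁶; the fit itself is penalized IRLS. Fits that push the
linear predictor beyond ±50 are declared separated and error out.

Selection coefficients follow the function-valued (averaged-derivative)
convention: with Ŵ(z) the fitted absolute-fitness surface (each plant's own
covariates) and W̄ the mean of Ŵ over observed plants, relative fitness is
w(z) = Ŵ(z)/W̄ (its mean over plants is 1 by construction, tested at 1e-8).
Then s/β_j = mean over plants of ∂w/∂z_j and c/γ_jk = mean of ∂²w/∂z_j∂z_k,
by central finite differences with step 1e-3 SD (second derivatives via the
3-point and 4-point stencils; step sensitivity at 10× and 0.1× recorded in
the result's diagnostics). γ is the averaged second derivative *without*
halving, which equals 2× the Lande–Arnold quadratic regression coefficient;
in the identity-link, unpenalized, quadratic-basis limit the whole estimator
reduces exactly to Lande–Arnold OLS (tested to 1e-6). Univariate fits give
differentials; the bivariate additive fit gives gradients, whose interaction
term is non-zero through the logit nonlinearity even with additive smooths.

**Bootstrap.** Plants (the independent unit) are resampled with
replacement; each resample is refitted with the smoothing weights fixed at
the original fit's values (re-selecting the penalty per resample is
disproportionately expensive and mostly adds noise); traits are
re-standardized within each resample. SE = SD over replicates; two-sided
p = 2·min(frac ≤ 0, frac ≥ 0) with a +1 continuity correction; failed
refits are dropped and counted, with an error above 10%. Under a flat
surface the realized per-coefficient rejection rate at α = 0.05 is within
[0.02, 0.10] (tested over 200 scaled-down datasets with n_boot = 200).

## Descriptive statistics

The variance partition is moment-based (expected mean squares, Searle's
coefficients for the unbalanced two-fold nested design site / plant-in-site
/ flower), with negative moment estimates truncated at zero; percentages
sum to 100 by construction. Moment estimators were chosen over likelihood
because they are closed-form, deterministic and independently checkable —
and they double as an independent cross-check on the generator.
Repeatability is the among-plant (site + individual) percentage, i.e.
100 − within%. CV uses the sample (n−1) SD of plant means. The census
summary reports the per-flower visitation rate (mean over censuses of
visits/flowers), integer-rounded taxon shares, and the waiting time
duration/rate/60 rounded to one decimal hour.

## GREML power

se(ĥ²) = √(2/(n²·var_rel)); the test is a 1-df non-central chi-squared with
ncp = ĥ⁴/se² evaluated at the α critical value (one-sided normal variant by
flag). var_rel defaults to 2e-5, the conventional value for samples of
conventionally unrelated individuals; a wild sample with sibships has a far
larger empirical value (compute it from the GRM with `var_rel_from_grm`),
and correspondingly more power — both paths are exposed because the choice
dominates the answer. For the genetic correlation between two traits on the
same individuals, the sampling variance of r̂_g = ĉ_g/√(v̂₁v̂₂) is a
delta-method approximation neglecting the covariance cross-terms:

    var(r̂_g) = V(1 + r_p²)/(h₁²h₂²) + r_g²·V/2·(1/h₁⁴ + 1/h₂⁴),
    V = 1/(n² var_rel),

with r_p the phenotypic correlation (defaulting to r_g·h₁·h₂), tested
against a standard normal, so power equals α exactly at r_g = 0. The
approximation satisfies the qualitative behaviour expected of the published
calculator (monotone in both heritabilities; power ≈ α for a design with
one near-zero heritability); the calculator's exact bivariate formula is
not published in a citable closed form.

## Synthetic-data generator

The generator emulates the study design: 6 sites at elevations
[60, 150, 320, 480, 660, 850] m, 40 plants per site, 5 flowers per plant,
2000 unlinked SNPs (configurable up to ~10⁴ — 2000 keeps GRM noise well
below the family signal at a fraction of the cost).

**Genotypes** come from gene-dropping: founder haplotypes are Bernoulli(p_k)
draws with p_k ~ U(0.05, 0.5) shared across sites (hence minimal
between-site differentiation, matching a continuous, well-connected
population); each site has a 25-founder pool; plants are grouped into
full-sib families (sizes 1 + Poisson(mean sibship − 1), default mean 4)
whose two parents are drawn from the pool — founder reuse creates half-sib
links, and with probability 0.05 one parent comes from another site's pool,
creating cross-site relatives. The resulting GRM has most pairs near zero,
a long right tail to ~0.5+ and variance in relatedness concentrated within
sites — the precondition for field heritability estimation, and the reason
a naive (no-site) model can absorb site variance into V_a.

**Phenotypes.** Breeding values are genotype-based: per-locus effects
(correlated r_G = 0.06 across traits) summed over centred dosages and
rescaled so the realized sample variance equals V_a exactly — the VanRaden
GRM then captures the simulated additive variance by construction, making
parameter recovery a clean test. Site, permanent-environment and
flower-level effects are Gaussian with an environmental cross-trait
correlation solved in closed form so the expected plant-mean Pearson
correlation is 0.43. Default trait parameters (flower-level variances):

| trait | mean | V_a | V_s | V_i | V_e | h² | partition site/plant/flower |
|---|---|---|---|---|---|---|---|
| flower weight (mg) | 26 | 4.74 | 17.94 | 6.44 | 4.74 | 0.140 | ≈53/33/14 % |
| standard petal area (mm²) | 50 | 0.131 | 52.4 | 55.0 | 23.6 | 0.001 | ≈40/42/18 % |

These were fixed a priori so the emulated population shows plant-mean CV
≈ 21%, repeatability ≈ 80–86% and the stated variance-partition
percentages; they are not tuning knobs. Small negative elevation slopes (−0.002 mg/m, −0.005
mm²/m) add a trend inside the site-level variance. With only six sites the
realized site-effect draws dominate a single study's phenotypic correlation
and variance partition, so single-study values scatter widely around the
targets; calibration is therefore asserted on means over replicate studies
(realized h² to ±0.02 over 50 replicates; r to ±0.10 over 40).

**Fitness.** Flower scars are 1 + Poisson(39); fruits are binomial with
p(z) = 0.3·exp(−(z−θ)²/2ω²) on the plant-mean standard petal area, θ at the
realized trait mean. The width is solved so the analytic
variance-standardized quadratic gradient equals −0.086: with θ at the mean,
γ = −1/(1 + (ω/σ_z)²) in closed form (Gauss–Hermite quadrature for general
θ; checked against brute-force numerical integration). The truth record
stores both the normal-assumption analytic γ and its empirical average over
the realized plant means. max_prob = 0.3 gives a mean fruit set ≈ 0.28 —
a realistic value for a bee-dependent shrub — and cancels from relative
fitness entirely.

**Censuses** are 569 three-minute counts of ~40 flowers with visits
Poisson(0.0155 per flower) split multinomially among honeybee (91%),
bumblebee (6.9%) and other (2.1%) — so the computed rate, waiting time and
shares land near those figures by computation, not by hard-coding.

All draws flow through `SimulationConfig.seed` via named SeedSequence
children; identical configs give byte-identical studies.

**What the generator does not emulate:** linkage and LD (loci are
independent, so GRM eigenstructure is milder than real GBS panels),
genotyping error and allelic dropout, selfing and inbreeding, spatial
autocorrelation within sites, temporal variation in pollinators, and any
male-fitness pathway. Passing tests therefore demonstrate correct recovery
of the generating process, not robustness to these real-data features.

## Problem sizes used in tests and acceptance runs

The acceptance experiments use the study design (240 plants, 5 flowers,
2000 SNPs) with 20 replicate studies and 1200-iteration chains for the
coverage/bias/naive-model checks; selection recovery uses one ~2000-plant
study plus 20 study-sized replicates for the sign test; bootstrap
calibration uses 200 datasets of 100 plants with 200 bootstrap draws. The
pipeline defaults (5000-iteration chains, 2000 bootstrap draws) are the
recommended working settings; both are below what a publication-grade
analysis would use (≥5000 effective samples, which these chains do not
reach for the slow-mixing V_a/V_i contrast).

## Known limitations

- The Gibbs sampler's h² effective sample size per iteration is low when
  relatives are few; budget long chains or use `px=True`.
- DIC is conditional-deviance; comparisons with marginal-likelihood
  criteria are not like for like.
- The bivariate sampler uses a proper inverse-Wishart prior (ν₀ = 4), which
  shrinks r_G slightly toward 0 in small samples.
- Selection-surface p-values are bootstrap percentile tests; with fixed
  smoothing they can be mildly anticonservative for the linear term (still
  within the tested [0.02, 0.10] band at α = 0.05).
- The r_G power formula is an approximation; treat its absolute values as
  indicative (its qualitative behaviour, not its third decimal, is tested).
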