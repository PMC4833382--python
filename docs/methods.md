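# Methods

## Model and testing procedure

The unit of analysis is one SNP within one ancestry stratum. The outcome
is a binary disease indicator; the exposure is residential distance to
the nearest major roadway in meters, divided by its interquartile range
(IQR) so that one exposure unit equals one IQR of distance. Quartiles use
linear interpolation (R type 7); the convention matters only in small
samples and is stated because alternatives exist. The scaled exposure is
recomputed whenever the analysis subset changes (each stratum is scaled
by its own IQR), so within-stratum effect sizes are per within-stratum
IQR.

The full per-SNP model is a case-control logistic regression with an
additive genotype coding and a multiplicative interaction:

    logit P(y=1) = b0 + bG*g + bE*e + bGxE*g*e + c'x

where x contains age, sex and per-stratum principal components
(the clinical variant adds BMI, hypertension, smoking, diabetes and
dyslipidemia as adjustments). Dosages are flipped so g counts the minor
allele within the stratum under analysis; odds ratios are therefore per
minor allele per IQR. Missing dosages drop the subject for that SNP only
(complete case per variant).

Interaction significance uses a score test evaluated at the null model
(the same design without the g*e column), with an empirical
sandwich-type variance of the score:

    U = sum_i z_i (y_i - p_i),        z = g*e, p from the null fit
    a = z - X (X'WX)^-1 X'W z,        W = diag(p(1-p))
    V_rob = sum_i a_i^2 (y_i - p_i)^2
    T = U^2 / V_rob  ->  chi-squared(1) under H0.

The model-based variance a'Wz is retained for diagnostics. The score
test needs only the null fit and is the locally most powerful asymptotic
test, which is why it is preferred over the Wald test in small cohorts.
Fits run through iteratively reweighted least squares (statsmodels GLM,
at most 50 iterations, coefficient tolerance 1e-8, zero start). A fit is
flagged non-converged — and no p-value emitted — when IRLS fails to
converge, a coefficient exceeds 30 in absolute value, or a standard
error is non-finite; these symptoms indicate (quasi-)separation, where
the MLE does not exist at a finite point. Reported effect sizes come
from the full-model Wald fit, because the downstream inverse-variance
meta-analysis requires a beta and SE pair; the score/Wald mix is a
deliberate choice and the two agree asymptotically.

### Small-sample behavior of the robust statistic

The sandwich statistic converges to chi-squared(1) slowly when the
tested column g*e is highly skewed (a log-normal exposure makes it so)
and the outcome is rare. Two measured consequences shape the tests and
the defaults:

- At roughly 2,000 subjects with a 6.3% outcome (the cohort scale the
  generator defaults to), the 5% level is held almost exactly.
  At n = 500 with ~32 cases the test is conservative at the 5% level
  (~0.036) even though the implementation is exact to 1e-9 against a
  numerical oracle — the asymptotics, not the code, are the limit.
- The *median* of the null statistics is inflated (lambda ~ 1.1-1.25 at
  n in the hundreds) even where the 5% tail is calibrated. A small
  stratum therefore shows lambda_m > 1 under the null — the same regime
  the method's genomic-control stage exists to correct.

## Genomic-control F-test (GCF)

lambda_m is the median of the observed score statistics over the
chi-squared(1) median (0.454936...), estimated on a without-replacement
random subsample whose seed is recorded in the estimate. Each statistic
is divided by lambda_m and referred to F(1, df2), default df2 = 100; df2
= infinity recovers the chi-squared reference. The F reference has a
thicker far tail, deliberately making genome-wide-scale p-values more
conservative than plain genomic control, which protects small p-values
against an imprecisely estimated lambda. By default the adjustment is
applied only to strata with lambda_m > 1 (a toggle exposes
always-adjust). Genomic control restores *median* calibration by
construction; when the raw statistics carry bulk inflation with a
calibrated tail (the small-sample regime above), the adjusted tail is
conservative. That trade-off is inherent to the method, not an
implementation artifact.

## Meta-analysis

Per-cohort records are aligned to a common effect allele: if cohort B
reports the opposite allele, its beta is negated and its allele
frequency complemented. A/T and C/G pairs are strand-ambiguous; when
both cohorts' MAFs lie in [0.4, 0.6] the frequencies cannot arbitrate
the strand and the variant is excluded (the window is conventional; the
0.4-0.6 band is a design choice). Combination is fixed-effect
inverse-variance: w = 1/se^2, beta = sum(w b)/sum(w), se =
sum(w)^(-1/2), two-sided normal p. Weights come only from Wald SEs;
GCF-adjusted p-values are never back-transformed into weights. The MAF
filter is relaxed to "MAF >= 0.05 in at least one cohort". Consistency
is defined as equal signs of the aligned betas. Random-effects models
and heterogeneity statistics are out of scope.

## Stability screening

For each screened hit the full model is refit after removing
observations with |standardized Pearson residual| > 4 (residuals
standardized by IRLS leverage). The verdict is unstable when the
interaction OR or its p-value moves by an order of magnitude or more, or
when the refit fails to converge. The threshold 4 is configurable; it is
far-tail under a correctly specified model, and at the default ~6.3%
prevalence an ordinary case sits at residual ~3.9, so the rule flags
only observations materially worse-fit than "any case in a low-risk
stratum". Residual-based rules cannot flag a high-leverage point the
model can absorb; they catch points that conflict with slopes pinned by
the rest of the data. Separately, interactions with SE > 10 are marked
for removal regardless of the refit, since an SE of that size alongside
a small p-value implies an implausible odds ratio. Independently of the
screen, LD is computed as composite r^2 (squared Pearson correlation of
dosage vectors over pairwise-complete subjects) — the standard surrogate
when phase is unavailable — and CpG annotation evaluates the given
strand only.

## Synthetic cohort generator

The generator produces the structure the analysis assumes, not a
demographic simulation:

- **Allele frequencies.** Ancestral frequencies uniform on a configured
  interval (default [0.05, 0.5]); stratum frequencies from the
  Balding-Nichols distribution Beta(p(1-F)/F, (1-p)(1-F)/F) with
  F_st default 0.1, which separates strata on PC1 of standardized
  dosages. F_st = 0 with rho > 0 and multiple strata is rejected:
  stratum divergence can only come from F_st, and a silent zero would
  produce indistinguishable strata.
- **LD.** Within blocks of `block_size` SNPs (default 10), a latent
  AR(1) Gaussian with correlation rho (default 0.7) is thresholded into
  Hardy-Weinberg dosage classes at the stratum frequency. This gives
  monotone control of r^2 with no recombination-map realism; blocks are
  independent, so cross-block r^2 is ~0.
- **Exposure.** Log-normal distance with log-mean 6.09 and log-sd 1.0,
  chosen once so the theoretical IQR is ~641 m, matching the IQR scale
  of the real exposure; the true distributional shape of such exposures
  is not publicly documented, so both parameters are config-exposed.
- **Outcome.** Bernoulli from the logistic model above, with age
  (years, effect 0.03/yr from the 60-year mean) and female sex (effect
  -0.3) as covariate effects and configurable per-SNP (beta_G,
  beta_GxE). The intercept is calibrated by Brent root-finding so the
  expected prevalence over the simulated covariates hits the target
  (default 6.34%) within 0.002; calibration failure raises rather than
  silently drifting. Clinical covariates are generated with realistic
  marginals but independent of outcome — they are nuisance adjustments,
  not confounders.
- **Missingness** is completely at random (default rate 0.002), since
  the QC stage only uses call rates.
- **Determinism.** One integer seed; genotype and phenotype streams are
  derived via independent SeedSequence spawn keys, so identical configs
  give bit-identical outputs.

What passing tests on this generator do *not* show: robustness to
spatially structured exposure, confounded clinical covariates,
imputation error, relatedness, or realistic recombination — all
explicitly out of scope.

## QC and principal components

Filters run in a fixed order: SNP call rate >= 98%, then subject call
rate >= 98%, then MAF, with per-stage removal counts reported. The MAF
boundary is inclusive (MAF >= 0.05 retained): variant tables customarily
print retained MAFs of exactly 0.05, which implies boundary inclusion at
printed precision; the threshold is configurable. PCs follow the standard
standardized-dosage construction: center by 2p, scale by sqrt(2p(1-p)),
missing to zero after centering, scores from the top singular vectors
scaled by singular values, sign fixed by the largest-magnitude loading.
Iterative outlier removal is not implemented — the PCs serve only as
covariates. The per-stratum PC count is configurable (default 2 for each stratum);
no single count suits every cohort, so the value is never inferred
silently.

## Cohort summaries

Table-1-style reports give mean (SD) with one-way ANOVA for continuous
covariates and count (%) with a continuity-corrected chi-squared test
for binary ones. The correction term is min(0.5, |O-E|) per cell (the R
convention), which reproduces the reference cohort table's printed
p-values — the uncorrected statistic does not — and collapses to exactly
zero when observed equals expected. Missing covariate values are dropped
per summary cell.

## Problem sizes in the tests and acceptance script

Simulation-based checks use the smallest sizes at which the property
under test is expected to hold: oracle equivalence at n = 60, null
calibration over 2,000 SNPs at n = 500, parameter recovery at
n = 20,000 (where the 95% CI is tight enough to be informative about a
planted OR of 2), pipeline determinism on a 2-stratum, ~100-SNP run,
and a study-scale (1623 + 554 subjects) null scan for the inflation
report. These are the package's own choices of informative minimal
designs.

## Known limitations

- Wald effect estimates paired with score p-values (stated above);
  near-separated fits are dropped rather than penalized (no Firth
  correction).
- Biallelic variants only; no imputation, no relatedness handling, no
  haplotype-phase r^2.
- The GCF df2 = 100 default is the conventional operating point; the GC
  literature would tie df2 to the lambda-estimation subsample size, and
  the parameter is exposed for users who prefer that.
- The stability screen's residual rule is one operationalization of
  "examine residual plots, remove outliers, refit"; influence-based
  diagnostics (Cook's distance, dfbeta) would catch absorbed
  high-leverage points that residuals cannot.
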