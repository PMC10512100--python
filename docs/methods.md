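# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `adipomr`. It describes what the code
computes; every empirical number cited here is produced by the test suite or
by `scripts/acceptance.py`, not asserted from elsewhere.

## Study design implemented

The package reproduces a comparative adiposity–mortality design on a single
prospective cohort:

1. **Cohort assembly.** Complete-case filtering on required phenotype
   fields, removal of extreme BMI (strictly < 15 or > 50 kg/m²; boundary
   values retained), and removal of prevalent cardiovascular, cancer, and
   respiratory disease (outcome-specific or global — the `"any"` default
   removes all three, since prevalent disease threatens reverse causation
   for every mortality outcome). The `ExclusionLog` telescopes exactly, and
   filtering is idempotent.
2. **Discovery/validation partition.** All deaths are matched 1:1 to living
   controls on the propensity score from a logistic model of case status on
   age, sex, and the first 10 genetic principal components. Matching is
   greedy nearest-neighbour on the logit scale, without replacement, in
   random case order under the run seed; distance ties break to the lowest
   control iid for determinism. No caliper by default (a caliper in SDs of
   the logit score is available; cases with no control inside it stay in
   the discovery set). Greedy-NN is the least-assumption default for a
   design whose matching algorithm is not otherwise pinned down.
3. **Observational analysis** on the full filtered cohort; **MR analyses**
   on the matched validation cohort, where the 50/50 case-control balance
   maximizes logistic power and the estimand is an odds ratio.

## Observational model

Cox proportional hazards via lifelines. Covariate schemes: `unadjusted`
(none), `adjusted` (age, sex, PC1–10), `fully_adjusted` (adds smoking,
diabetes, alcohol, total/LDL/HDL cholesterol, triglycerides, systolic and
diastolic blood pressure). The exposure enters as

- a standardized linear term (HR per SD; invariant to affine rescaling),
- a restricted cubic spline — Harrell truncated-power basis, 4 knots at the
  5/35/65/95th percentiles, k−1 basis columns, implemented directly so the
  knot convention is explicit — or
- a centered quadratic.

**Nonlinearity ANOVA.** The default F statistic is the likelihood-ratio
chi-square per added degree of freedom, F = (dev_lin − dev_spline)/Δdf,
flagged above a configurable threshold (default 10). A partial likelihood
has dispersion fixed at 1, so this is the natural ANOVA scale; a
residual-deviance-scaled convention (dividing further by
dev_spline/(n_events − k)) is retained as an option but is far more
conservative, because a Cox partial deviance per event is ≈ 2·log(risk-set
size), not ≈ 1. The LR chi-square p is always reported alongside.

**Nadir.** Argmin of the fitted relative log-hazard curve on a 512-point
grid over the 1st–99th exposure percentiles. If the curve is monotone or the
argmin lands in the outermost 1% of the grid, the result is flagged
`boundary` and the CI suppressed; otherwise a percentile bootstrap over
participants (default 200 replicates; the pipeline disables it by default
and exposes `nadir_bootstrap`) gives the 95% CI. A caveat found during
validation and worth knowing: with a shallow quadratic truth the 4-knot
spline's linear tails can displace the argmin by 1–2 BMI units even when
binned empirical rates place it correctly; when a parabolic hazard is the
working hypothesis, the quadratic form recovers the vertex to a few tenths
of a unit at n = 50 000 (this is what the nadir-recovery study uses,
reporting the spline argmin alongside).

**Cause-specific mortality** uses cause-specific hazards: deaths from
competing causes are censored. Subdistribution (Fine–Gray) hazards are out
of scope. ICD-10 codes map to {cancer, cvd, respiratory, other} by
configurable chapter ranges (defaults C00–C97, I00–I99, J00–J99); malformed
codes fall through to `other` with a warning.

## Linear MR

Single-instrument allelic scoring: the PRS is Σⱼ wⱼ dⱼ over variants with
association p below the threshold (default .01), dosages flipped to `2 − d`
when the counted allele differs from the effect allele, missing dosages
mean-imputed per variant, and the score standardized in the sample being
scored (a switch allows standardizing in a reference sample). γ comes from
OLS of the standardized exposure on the score, Γ from logistic regression of
case status, both with the same covariates; θ = Γ/γ is a log-OR per SD.
First-order delta SE by default; the second-order variant adds
Γ²·SE(γ)²/γ⁴. A weak-instrument guard refuses the ratio when |t(γ)| < 2
(configurable) — in stratified analyses such strata are flagged and excluded
from trend fitting, never silently imputed.

Sensitivity estimators consume per-variant (γⱼ, Γⱼ) pairs estimated in the
same sample (a one-sample approximation, flagged as a limitation below):
IVW (exact closed form; single variant falls back to the plain ratio),
MR-Egger (weighted regression with free intercept, γ oriented positive,
≥ 3 variants), and the weighted median (ordered ratios, cumulative
normalized weights with the midpoint convention, linear interpolation to
0.5; parametric bootstrap SE). The weighted median's duplication invariance
(splitting a variant in two at half weight) holds exactly for variants away
from the median under this interpolation convention; an exactly invariant
step-function quantile would sacrifice the interpolation behaviour.

Sex interaction is the Wald p of the score × sex product term in the
logistic outcome model. Stratified analyses (sex, empirical age tertiles,
menopausal age — females ≤ 52 vs ≥ 53 years) re-estimate both γ and Γ
within each stratum.

## Nonlinear MR (residual stratification)

Exposure residualized on the score by OLS (covariates optional); residuals
keep natural units and are exactly orthogonal to the instrument in-sample,
which is the collider-avoidance property (stratifying on the raw exposure
instead leaves a stratum–score correlation of ≈ 0.3 at PRS R² = 0.1; on the
residual it is statistically zero — both measured by the acceptance study).
Rank-based assignment into K = 20 strata of size n/K ± 1 (any K ≥ 4 is
supported; n ≥ 10·K enforced). Stratum Wald ratios share the full-sample
exposure scale so K = 1 reproduces the unstratified estimate exactly.

The trend regression is **unweighted OLS of θ_k on the stratum mean of the
measured exposure** (the literal reading of an "ordinary least squares"
specification; 1/SE² weighting and a stratum-index regressor are flags).
The quadratic term is added to the centered regressor and the two fits
compared by an F test; consistency requires slope p ≥ α **and** curvature
p ≥ α. Under a purely quadratic exposure→risk map the stratum estimates
vary approximately *linearly* with the stratum mean, so the slope test, not
the curvature test, carries the power against a J-shape — the calibration
studies therefore check the curvature test's type-I error under a constant
effect (≈ 5% over 500 replicates) and the combined consistency test's
detection under a J-shaped truth (100% at n = 100 000).

## Heterogeneity

Generic inverse variance: CI→SE conversion uses z = 1.959964 (the extra
digits matter when reproducing I² from printed, rounded CIs), Q with
df = k − 1, I² clipped at 0 and reported as a percentage. Comparisons
across the three measures use the single k-group Q; a pairwise mode covers
two-way contrasts. Both are exposed because a set of published comparisons
can mix the two conventions.

## Synthetic-cohort generator

What it emulates, with defaults chosen once to mimic a middle-aged
population biobank:

- **Genotypes:** m = 100 independent biallelic variants, dosage
  ~ Binomial(2, MAF), MAF ~ U(0.05, 0.5). No linkage disequilibrium,
  relatedness, genotyping error, or population structure.
- **Exposures:** per-exposure genetic score (independent N(0,1) weights)
  plus environmental noise correlated across exposures
  (BMI–FMI 0.85, BMI–WHR 0.45, FMI–WHR 0.40 on the environmental
  component); the score explains 10% of exposure variance by construction
  (realized R² within ±0.02 at n ≥ 20 000). Latents map affinely to
  BMI ≈ 27 (SD 4.7), FMI ≈ 8 (SD 3), WHR ≈ 0.87 (SD 0.09) — fixture
  constants, configurable, chosen as typical adult values so the BMI
  bounds filter operates on meaningful units.
- **Mortality:** exponential individual hazard,
  log λ = λ₀ + 0.09·(age − 56.9) + 0.45·male + Σ exposure maps, with
  administrative censoring at 12.5 years; λ₀ = −5.5 yields a realistic
  single-digit-percent death fraction. Default maps: quadratic for BMI
  (curvature 0.005 per unit², nadir 24.9) and FMI (0.012, nadir 6.15),
  linear for WHR (0.34 per SD). Exponential sampling is exact and
  closed-form; no Weibull shape is needed for recovery testing. Cause codes
  are chapter-representative ICD-10 strings sampled from a four-category
  mix (cancer .48, cvd .20, respiratory .06, other .26).
- **Case-control outcome:** for estimator-calibration studies the generator
  also draws Bernoulli case status with logit = α + θ·X_sd, so a "true OR
  per SD" is exact rather than a rare-disease approximation of a hazard
  ratio.
- **Imperfections:** missingness completely at random in a few phenotype
  columns (4.9%), extreme BMI injection (0.1%), prevalent-disease flags.
- **Determinism:** one integer seed fans out to per-stage child generators
  via fixed offsets; identical config + seed ⇒ byte-identical files.

What passing tests on this generator do **not** show about real data: no
LD or pleiotropic genetic architecture (instrument validity is built in
except where pleiotropy is injected explicitly), no confounding of the
exposure–outcome relation beyond age/sex hazard terms, MCAR rather than
informative missingness, and exposures measured without error.

## Numerical choices

- Logistic and OLS/WLS fits via statsmodels (Newton, maxiter 200); Cox fits
  via lifelines (Efron ties). Propensity models fall back to a ridge
  penalty under separation; constant covariate columns are dropped first.
- Standardization uses the sample SD (ddof 1); score standardization
  enforces mean < 1e−10 and |SD − 1| < 1e−10.
- Residual stratification raises on numerically zero residual variance
  (< 1e−10), which is what a noise-free exposure = c·score produces.
- Trend fitting centers the regressor before squaring to decorrelate the
  linear and quadratic terms, and treats a numerically flat fit (fitted
  variation < 1e−10 of the estimate scale) as slope p = 1 so that exactly
  constant stratum estimates read as consistent rather than as a
  round-off-level "trend".
- The nonlinearity LR is clipped at 0 (nesting guarantees non-negativity up
  to round-off).
- Grid argmin uses 512 points; the boundary guard is the outer 1% of grid
  points or a monotone fitted curve.
- Problem sizes in the validation studies: Wald recovery 100 seeds at
  n = 50 000; nadir recovery at n = 50 000; trend null calibration 500
  replicates at n = 4 000 (K = 20); J-shape power 25 replicates at
  n = 100 000; Egger calibration 200 replicates of 50-variant summary
  sets. These sizes give Monte-Carlo error comfortably below the effects
  being measured while keeping a full run in the minutes range on one CPU.

## Known limitations

- One-sample MR throughout: per-variant summaries, the score, and the
  outcome model share participants; winner's curse and weak-instrument
  bias are mitigated only by the t-guard, not corrected.
- The matched case-control validation design yields ORs; no rare-disease
  conversion to HRs is attempted, and logistic noncollapsibility introduces
  a small conservative attenuation of the Wald ratio (visible in the
  recovery study as a median bias of ≈ −0.01 on the log-OR scale, well
  inside the CI width at the study sizes).
- Cause-specific analyses are cause-specific hazards, not competing-risk
  cumulative-incidence models.
- The spline nadir inherits basis artefacts for shallow curvatures (see
  above); CIs for the nadir are bootstrap percentile intervals and assume
  the resampled fits converge.
- PRS weights are inputs: penalized-regression weight estimation, LD
  clumping, and GWAS itself are out of scope.
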