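# Methods

## The design

The pipeline estimates the causal effect of a binary exposure on a
case-control outcome with genetic instruments, two ways:

1. **Individual-level (wGRS) arm.** Published per-allele exposure
   log-ORs weight effect-allele dosages into a per-sample score; a
   logistic regression of case status on the score, adjusted for age
   group, sex, ever-smoking and ten ancestry principal components, is
   fitted separately per genotyping dataset; the per-dataset log-ORs
   are pooled by fixed-effect inverse-variance meta-analysis. Note the
   exposure itself is never observed — only its genetic prediction —
   which is exactly what makes the estimate immune to confounding of
   the exposure-outcome relationship.
2. **Summary-statistic arm.** For each instrument, the published
   exposure effect is paired with the cohort's own covariate-adjusted
   outcome log-OR, and IVW, MR-Egger, simple-median and weighted-median
   estimators are computed as a sensitivity analysis with different
   robustness to pleiotropy.

## Models and algorithms

**Logistic fitting.** Newton-Raphson on the binomial log-likelihood
(IRLS), convergence when the relative log-likelihood change falls below
1e-8, at most 25 iterations. Standard errors come from the inverse
information at the optimum; 95% intervals use z = 1.959964. Any
coefficient passing |beta| > 15 mid-iteration is treated as
(quasi-)separation: the fit is flagged non-converged and no estimate is
emitted. Exact collinearity is fatal with the offending columns named.
The per-SNP scan shares the covariate block across variants and warm
starts each fit from the covariate-only model, which keeps an 82-variant
scan to a few milliseconds; per-column missing dosages are mean-imputed.

**Meta-analysis.** Fixed-effect weights \(w_k = 1/se_k^2\); Cochran's
Q = \(\sum w_k(\beta_k - \hat\beta)^2\) is chi-square with k−1 df under
homogeneity. Q always uses fixed-effect weights. A DerSimonian-Laird
random-effects option exists for sensitivity; it reduces to the fixed
fit when Q ≤ df. Subgroup heterogeneity applies the same Q across
stratum-level pooled estimates.

**IVW.** First-order weights (outcome variance only), no residual
over-dispersion scaling — the classical fixed-effect estimator, which is
algebraically the fixed-effect meta-analysis of per-variant ratio
estimates (asserted in tests). Ignoring the exposure-side uncertainty is
the convention of the standard two-sample toolchain and is a documented
limitation (it mildly understates the SE when instruments are weak).

**MR-Egger.** Pairs are re-oriented so every exposure effect is
non-negative (estimates are invariant to input orientation); weighted
least squares with intercept, weights \(1/se_Y^2\); coefficient
variances scaled by the residual dispersion floored at 1. The intercept
estimates average directional pleiotropy; its Wald test is the
pleiotropy diagnostic. The floor makes the intercept test mildly
conservative when the true dispersion is below 1.

**Medians.** Per-variant ratios \(\hat\beta_Y/\hat\beta_X\); the
weighted median interpolates linearly in cumulative weight at 0.5
(exact sample median at equal weights), weights
\(\hat\beta_X^2/se_Y^2\) (inverse first-order ratio variance). SEs by
parametric bootstrap (default 1,000 draws, mandatory seed): both effect
columns are resampled from normal(estimate, se) and the median
recomputed. Ratios with \(\hat\beta_X = 0\) are dropped with a warning.

**Harmonization.** Allele matching tries identity, swap (d → 2−d),
strand flip, and flip+swap, in that order. Palindromic (A/T, C/G)
variants are resolved by comparing effect-allele frequencies; if either
frequency is within 0.08 of 0.5 the variant is ambiguous and fatal
(or dropped under `--drop-palindromic`). The 0.42–0.58 ambiguity band is
standard harmonization practice.

**Instrument selection.** Order of operations: non-autosomal exclusion,
reference-MAF floor (default 0.01), indel→proxy substitution (best
available SNP with r² > 0.40 in the panel; the proxy inherits the
indel's published beta unchanged, since re-estimation is not possible
from a published table), then greedy independence pruning at r² < 0.10
— variants are visited in order of exposure p-value (ties by rsid, so
output is deterministic) and kept only if independent of everything
already kept. LD is the squared Pearson correlation of dosages, the
standard unphased composite estimator; no phasing is assumed.
Candidates absent from the panel are excluded as unresolvable with a
warning, never fatally; an empty final set is fatal.

**QC.** Variant rules in fixed attribution order: call rate ≥ 0.95,
control MAF ≥ 0.005, HWE in all samples (p ≥ 1e-5), in controls
(≥ 1e-7), in cases (≥ 1e-12); each HWE rule can be disabled, since it
is ambiguous whether such thresholds are chip-specific alternatives or
jointly applied — the default applies all three. HWE is the 1-df
chi-square goodness of fit on hard calls (rounded dosages); the exact
test is not needed at simulated sample sizes and the chi-square is
hand-checkable. Sample rules: call rate ≥ 0.95; from each pair with
PI_HAT > 0.25 the lower-call-rate member is dropped (PI_HAT is consumed
as a precomputed table — IBD estimation is upstream tooling);
heterozygosity outliers beyond 6 SD of the cohort mean.

## The synthetic cohort generator

The generator emulates the *statistical* structure the analysis
assumes, not real LD or imputation noise:

* variants are independent Binomial(2, EAF) draws (HWE by
  construction), EAF ~ U(0.05, 0.50), exposure effects
  β ~ U(0.03, 0.15) per liability unit — chosen to give realistic
  per-variant effect sizes and adequate instrument strength at the
  sample sizes used in the tests; the variance explained by a real
  instrument set is not identifiable from a published hit table alone;
* exposure liability \(L = \sum_i \beta_i g_i + c\,U + \varepsilon\),
  with unmeasured confounder U ~ N(0,1), noise SD 0.5; binary exposure
  status thresholds L at its upper decile (a realistic adult prevalence
  for a common metabolic disease);
* outcome log-odds
  \(\gamma_0 + \theta L + \sum_i \alpha_i g_i + c\,U + 0.3\,\mathrm{age}
  + 0.2\,\mathrm{sex} + 0.9\,\mathrm{smoker}\); θ is the causal
  parameter (`causal_logor`, null by default) and the αᵢ are direct
  (pleiotropic) variant effects drawn
  N(`pleiotropy_mean`, `pleiotropy_sd`); γ₀ targets ~10% superpopulation
  prevalence;
* covariate marginals are Bernoulli(0.5) indicators and standard-normal
  PCs, matching the near-even splits typical of matched case-control
  GWAS panels; smoking carries the dominant covariate effect;
* case-control ascertainment samples a superpopulation in batches until
  the requested per-dataset case and control counts are met exactly
  (at most 20 rounds, then an explicit failure). Under a logistic
  outcome model, outcome-dependent sampling shifts only the intercept,
  so simulated log-ORs remain interpretable;
* one global seed; per-dataset and per-purpose streams are derived by
  fixed offsets, making cohorts bit-reproducible.

**Summary-statistic export.** Per variant, the outcome effect is a
logistic regression of case status on dosage adjusted for the standard
covariates plus dataset indicators. The exposure effect is, by
default, a *linear* regression of the continuous liability on dosage
with the same adjustment — the scale on which the generator's causal
effect is defined, so ratio-based estimators recover `causal_logor`
directly. A logistic fit on the thresholded binary status is available
(`exposure_scale="binary"`) but is attenuated relative to the liability
scale by non-collapsibility of the odds ratio and by the omitted
liability noise, and will not recover the liability-scale parameter;
real analyses avoid this issue by taking exposure effects from the
published GWAS rather than re-estimating them.

What passing tests do **not** show about real data: robustness to LD
between instruments, imputation error, population stratification beyond
linear PC adjustment, allele-frequency mismatch between the weight
source and the target population, or winner's-curse inflation of
published weights.

## Numerical and calibration notes

* Per-SNP outcome ORs in the synthetic cohorts carry a small
  non-collapsibility attenuation (the other 81 variants and the
  liability noise act as omitted covariates); at the default effect
  sizes this is below 2% and well inside estimator SEs at the tested
  sample sizes.
* One-sample bias: exposure and outcome effects are estimated in the
  same cohort, so weak instruments bias IVW toward the confounded
  association. The confounding demonstration test therefore uses
  deliberately strong instruments; with the default β range and no
  confounding the effect is negligible.
* Monomorphic variants: HWE p = 1 by convention (trivially in
  equilibrium); dropped from summary statistics and scans with a
  warning.
* Replicate sizes used by the simulation-based tests: 200 null cohorts
  of 2,000 cases + 2,000 controls for calibration; 50 cohorts of
  10,000 + 10,000 for recovery of a causal log-OR of 0.3 and of a
  directional pleiotropy of 0.1. The pleiotropy-recovery runs use a
  null causal effect so the intercept isolates the pleiotropy
  parameter.
* The family-wise "no significant variant at 0.05/82" check is
  intrinsically knife-edged: a perfectly calibrated scan leaves
  ~95.1% of null replicates clean, so the observed fraction over 200
  replicates fluctuates by ±1.5 percentage points around a 95% bar.

## Known limitations

First-order weights throughout (no exposure-uncertainty propagation);
no MR-PRESSO/mode-based/multivariable estimators; no Firth correction
for separated strata (they are skipped with a warning); LD pruning and
proxy search operate on whatever reference panel is supplied — the
bundled panel is synthetic and sized for testing, not population
inference.
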