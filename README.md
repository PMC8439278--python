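# mrscore

Mendelian randomization (MR) of a binary exposure on a case-control
outcome using individual-level genotype dosages, with a
summary-statistic sensitivity arm. The package re-implements, as a
reusable and tested pipeline, the classic wGRS design used to ask
whether type 2 diabetes causally affects lung cancer risk: a set of
exposure-associated SNPs serves as instrumental variables, their
published effects weight a per-sample genetic risk score, and the score
is tested against the outcome with covariate-adjusted logistic
regression, per genotyping dataset, pooled by fixed-effect
meta-analysis.

Because alleles are randomized at conception, an association between
the genetically predicted exposure and the outcome is protected from
the confounding and reverse causation that plague observational
studies — provided the instruments act on the outcome only through the
exposure, which the sensitivity estimators probe.

## What it computes

**Weighted genetic risk score.** For sample *s* with effect-allele
dosages \(d_{si} \in [0,2]\) and published per-allele exposure log-ORs
\(\beta_i\):

\[ \mathrm{wGRS}_s = \sum_i \beta_i\, d_{si} \]

Dosages are harmonized to each instrument's effect allele (swap,
strand-flip, frequency-resolved palindromes), missing dosages are
imputed as twice the control effect-allele frequency, and the headline
odds ratio is reported per control-SD of the score. The association
model is a logistic regression of case status on the score adjusted for
age group, sex, smoking status and ten principal components, fitted per
dataset and pooled by inverse-variance meta-analysis with Cochran's Q
for between-dataset and between-subgroup heterogeneity.

**Instrument selection.** Candidate loci are filtered against a
reference panel: non-autosomal variants and variants with MAF < 0.01
are excluded, indels are replaced by the best proxy SNP with
\(r^2 > 0.40\) (inheriting the published effect), and the remainder is
greedily pruned to pairwise \(r^2 < 0.10\), keeping the variant with
the stronger exposure association.

**Summary-statistic estimators.** From per-variant pairs
\((\hat\beta_{Xi}, \hat\beta_{Yi})\): IVW
(\(\hat\theta = \sum w_i \hat\beta_{Xi}\hat\beta_{Yi} / \sum w_i
\hat\beta_{Xi}^2\), \(w_i = 1/\mathrm{se}^2_{Yi}\)), MR-Egger
regression with its pleiotropy-intercept test, and simple/weighted
median estimators with parametric-bootstrap standard errors.

**Synthetic cohorts.** A generator draws multi-dataset case-control
cohorts with independent HWE variants, a liability-based exposure,
configurable causal effect, confounding and directional pleiotropy, so
every stage is testable without access-restricted genotypes.

## Worked example

Simulate three datasets of 1,000 cases + 1,000 controls with a true
causal log-OR of 0.3 per liability unit, then run the full pipeline:

```sh
mrscore simulate --n-variants 82 --n-datasets 3 --n-cases 1000 \
    --n-controls 1000 --causal-logor 0.3 --seed 7 --out-dir cohort
cat > config.yaml <<EOF
instruments: cohort/instruments.tsv
dosages: cohort/dosages.tsv
phenotypes: cohort/phenotypes.tsv
out_dir: reports
strata: [overall, age, sex, smoking]
n_boot: 1000
seed: 7
EOF
mrscore run config.yaml
```

`reports/meta.tsv` (wGRS arm, pooled across the three datasets):

```
  stratum     beta       se     or_  ci_low  ci_high            p        Q  df    p_het  k
  overall 0.203271 0.027301 1.22540 1.16156  1.29276 9.647170e-14 1.915090   2 0.383834  3
smoking=1 0.205680 0.035718 1.22836 1.14531  1.31743 8.486880e-09 1.480200   2 0.477066  3
```

The score is strongly associated with the outcome (OR 1.23 per control
SD of the score, p ≈ 1e-13) and homogeneous across datasets
(p_het = 0.38) and subgroups. `reports/mr_estimates.tsv` (sensitivity
arm):

```
         method     beta       se     or_  ci_low  ci_high            p  n_snps  intercept  intercept_se  p_intercept
            ivw 0.381298 0.049657 1.46418 1.32839  1.61385 1.608640e-14      82        NaN           NaN          NaN
          egger 0.298790 0.137383 1.34823 1.02996  1.76483 2.963970e-02      82   0.008464       0.01301     0.515325
```

All estimators detect the simulated effect in the right direction; the
IVW interval (OR 1.33-1.61) covers the generating value
exp(0.3) = 1.35, and the Egger intercept is compatible with zero
(p = 0.52), as it should be for instruments simulated without
pleiotropy.

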