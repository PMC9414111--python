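# Methods

## The model

The outcome throughout is offspring birthweight adjusted for sex and
gestational age, centred at 40 weeks, in grams. The analysis fits a
sequence of nested OLS models whose predictors accumulate from genetic
scores alone to the full set of clinical covariates, parental heights
and scores, and asks at each step whether the added predictors explain
variance beyond what the smaller model captures. The quantities
reported are R² (variance explained), Adj-R² (penalized for predictor
count — the statistic used to judge improvement), the nested F-test
between each model and its reduced counterpart, a percentile-bootstrap
CI for each model's R², and per-predictor VIFs as a collinearity check.

Coefficients are reported in grams per 1 SD of the predictor for
continuous variables and per category for the binary indicators
(smoking: 1 = smoked in pregnancy; parity: 1 = first pregnancy). The
per-SD scale is implemented by dividing each continuous column by its
sample SD before fitting; for OLS this is identical to rescaling the
coefficients afterwards. The SD used is computed once on the analysis
cohort and reused in any refit (including bootstrap resamples), so
coefficients remain comparable across resamples.

## Genetic scores

Each score is GS = Σ w_i g_i over the retained SNP panel, with g the
effect-allele dosage (0–2) and w the per-allele weight in grams. Three
weight columns are carried per SNP: maternal effect adjusted for fetal
genotype, fetal effect adjusted for maternal genotype, and the
unadjusted fetal effect (used for the paternal score so it captures
maximum information about the father's own birthweight). Scores are
standardized (mean 0, SD 1, n−1 denominator) on the analysis sample.

Variant filtering retains SNPs with MAF = min(f, 1−f) *strictly*
greater than the MAF threshold and imputation r² strictly greater than
the quality threshold (defaults 0.001 and 0.4). The strict comparison
is made robust to floating-point representation (a frequency of 0.999
yields MAF exactly at a 0.001 threshold and is excluded). Missing
dosages are imputed as 2f, the standard polygenic-score convention.
Strand-ambiguous (A/T, C/G) SNPs are retained with a logged warning by
default; a strict flag drops them. Dosages are re-oriented to the
effect allele (d → 2 − d where the VCF counts the other allele), and
scores are invariant to the file's allele orientation by construction.

## Cohort preparation

Default birthweight adjustment is *internal*: OLS of raw birthweight on
a male indicator and (GA − 40), returning the residual plus the fitted
value at GA = 40 with sex at its sample mean. This keeps values on the
gram scale and makes them exactly uncorrelated with sex and GA in the
sample. A *reference* mode implements adjustment against an external
sex- and week-specific table of birthweight means and SDs (z-score at
the observed week mapped onto the 40-week distribution); the table is
an external resource supplied by the user, looked up at the floor
integer week. Internal mode uses linear GA; a quadratic option exists
but is off by default — over the term range (five weeks) the linear
term dominates.

Term inclusion is 37.0 ≤ GA < 42.0 weeks (closed-left, open-right).
Completeness requires every analysis field plus genotypes for all three
trio members; each exclusion is logged with a single reason (first
failing check). Included and excluded groups are compared with Welch's
t-test for continuous variables (the variance-equality assumption is
not defensible for a selected subgroup; a pooled option exists) and
chi-square without continuity correction for categorical ones (a
correction flag exists).

## The trio simulator

The generator emulates a community-based birth cohort of 549
parent-offspring trios. Defaults are the cohort's descriptive
statistics: birthweight 3570 (444) g, gestational age 40.1 (1.2) weeks,
maternal height 165.0 (6.4) cm, weight 76.3 (12.6) kg, age 30 (5)
years, smoking prevalence 14.6%, primiparity 44.8%, male fraction
52.2%. Paternal height (178.0 (7.0) cm) and fasting glucose (4.5 (0.4)
mmol/L) are not part of the published descriptives; values typical of a
UK adult cohort were chosen once. Because every continuous effect is
per-SD, these two choices do not influence the variance calibration.

Covariates are drawn mutually independent. This is a deliberate
default: summing independent per-predictor variance contributions from
the published clinical coefficients reproduces the published
five-covariate model R² to ~0.001 (0.218 vs 0.217), which the test
suite checks in closed form — so independence is the configuration
under which the printed numbers are mutually consistent. An observed
covariance structure for the real covariates is not published; the
independence default is therefore a modelling choice, not a claim about
the study population.

Genotypes: parental dosages are Binomial(2, f) per SNP (Hardy–Weinberg),
mother and father independent; each parent transmits one allele
(heterozygotes at random), so parent–child dosage correlation ≈ 0.5 and
generation-stable allele frequencies emerge rather than being imposed.
No linkage disequilibrium, assortative mating, imputation noise or
population structure is simulated — passing tests say nothing about
robustness to those features of real data.

Birthweight (adjusted scale) is bw_mean + Σ β_j z_j + ε, with ε normal
and its variance set to total_sd² minus the *sample* variance of the
realized systematic component. Sample-based (rather than theoretical)
calibration keeps the marginal-SD contract exact in expectation even in
genotype mode, where the maternal and fetal scores are correlated
through transmission and a theoretical independent sum would
under-budget the systematic variance. The generated birthweight is on
the sex/GA-adjusted scale; the raw birthweight written to phenotype
files adds a sex difference (120 g) and a GA slope (125 g/week around
40 weeks) so the adjustment step downstream has real work to undo.

Two modes exist. *Direct-score* mode draws the standardized scores as
(bivariate) normals — maternal/fetal correlation 0 by default, the only
value under which the published marginal (0.030, 0.020) and joint
(0.060) score R² are mutually consistent — and gives exact control of
score-attributable variance; all calibration checks use it.
*Genotype* mode computes scores from simulated trio genotypes through
the score-construction code and exists to exercise that pipeline end to
end.

Parents' own self-reported birthweights are generated correlated with
the parent's score (60–70 g per SD) and rounded to 10 g to mimic
self-report coarseness; they feed the extension models only.

## Numerical and design choices

- OLS is fitted via statsmodels; classical (non-robust) SEs; coefficient
  CIs from the t distribution with residual df.
- Nested F-tests are computed from RSS; the algebraically equivalent R²
  form agrees to 1e-10 in tests. Only the five reported comparisons
  (3v2, 4v2, 5v4, 6v4, 7v4) are computed by default; any nested pair is
  available through the API.
- Bootstrap: nonparametric case resampling of whole trios, B = 1000,
  95% percentile interval, deterministic given the seed. Resamples are
  refitted with a streamlined least-squares path (R² is invariant to
  the per-SD rescaling, so it is skipped there); rank-deficient
  resamples are redrawn with a capped retry count. Percentile intervals
  for R² are known to undercover somewhat near small R²; the coverage
  test asserts only a loose ≥85% bound at nominal 95%.
- VIF regresses each predictor on the others with an intercept; perfect
  collinearity is reported as unbounded with the offending partner
  logged, not raised.
- No multiple-testing adjustment is applied anywhere, matching the
  analysis design.
- Rank deficiency in a primary fit is an error naming the collinear
  columns; models whose predictors are absent from the data are skipped
  with a logged reason while the rest of the suite runs.
- Adj-R² is always recomputed from the formula; the identity is asserted
  on every emitted fit.

## Problem sizes

Calibration checks average 200–300 replicates of 549-trio cohorts in
direct-score mode (a replicate is a simulate-plus-fit cycle taking a
few milliseconds, so the full recovery table runs in seconds).
Pipeline-level tests use genotype-mode cohorts of 60–200 trios with
12–40 SNPs, and the analysis walkthrough uses the full 549 × 209
configuration. Statistical assertions use 3-Monte-Carlo-SE tolerances
at the stated sizes.

## Known limitations

- The simulator's effect presets are taken from fitted coefficient
  columns; simulating from a fitted model reproduces that model's R² in
  expectation but is not a causal model of birthweight.
- Reference-mode adjustment implements a mean/SD z-score, not a full
  LMS (skew-adjusted) transformation.
- Bootstrap CIs are percentile-type only; BCa is not implemented.
- The included-vs-excluded comparison treats trios as independent; no
  within-family clustering is modelled anywhere.
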