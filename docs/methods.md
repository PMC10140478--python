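# Methods

`twinbile` implements the analysis chain used to dissect host-genetic and
gut-microbial contributions to serum and stool bile-acid levels in twin
cohorts. This note documents the models, the numerical choices, and what
the bundled synthetic-data generator does and does not emulate.

## Metabolite preprocessing

Untargeted metabolomics panels arrive as positive abundance values with
instrument-batch structure and detection-limit missingness. The QC chain
is order-fixed:

1. **Missingness filter.** Metabolites missing in strictly more than 20%
   of samples (default) are removed. The rule is strict: exactly 20%
   missing is retained.
2. **Batch median scaling.** Each (metabolite, batch) block is divided by
   the within-batch median of its observed values, so every batch — and
   hence the metabolite — has median exactly 1. This removes
   multiplicative inter-day instrument effects and is idempotent. A batch
   with no observed value, or a zero median, for a metabolite is an
   error rather than a silent NaN.
3. **Minimum imputation.** Missing entries are filled with the
   metabolite's minimum observed value across *all* batches of the scaled
   matrix. This is only sensible under left-censoring (values below the
   detection limit), which is exactly what the synthetic generator
   plants; the real missingness mechanism of vendor-delivered panels is
   not observable, and this choice is a modeling assumption.
4. **Inverse normal transform.** Each metabolite is mapped to Gaussian
   quantiles through its average ranks, `z_i = Phi^-1((r_i - c)/(n - 2c + 1))`.
   The rank offset `c` defaults to Blom's 3/8 and is configurable
   (`tukey` = 1/3, `waerden` = 0); with average ranks the transform is
   well defined on the duplicate values that minimum imputation creates.

On a complete single-batch matrix the whole chain reduces to the inverse
normal transform column-wise.

## Twin variance decomposition (ACE)

For a trait measured on MZ and DZ twin pairs plus singletons, phenotypic
variance is decomposed into additive-genetic (A), common-environment (C)
and unique-environment (E) components. With variance shares
`a2 + c2 + e2 = 1`, the implied within-pair correlations are
`r_MZ = a2 + c2` and `r_DZ = a2/2 + c2` (DZ genetic correlation fixed at
0.5, the standard additive assumption). Each pair contributes an
exchangeable bivariate-normal likelihood term with common mean and total
variance across zygosity groups; singletons contribute univariate terms
(they inform the mean and total variance only). The saturated model frees
mean, variance and covariance per zygosity group (closed-form ML from
group moments) and acts as the fit ceiling.

Numerics: the non-saturated models are maximized over
`(mu, log sigma^2, shares)` with the free shares parameterized by a
stick-breaking map (`a2 = t1`, `c2 = (1 - t1) t2` for ACE) so each lies
in [0, 1] under simple box constraints; L-BFGS-B from a Falconer
moment-based start plus 4 random restarts (deterministic given the seed
argument). Shares are capped at `1 - 1e-7` to keep pair correlations off
the singular `r = 1` boundary; `log sigma^2` is bounded to ±50. Boundary
estimates (e.g. `c2 = 0`) are legitimate maximizers and are reported as
such.

Model selection is by AIC (`2k - 2 logL`) over saturated/ACE/AE/CE/E;
ties break toward fewer parameters, then the fixed order ACE, AE, CE, E.
Confidence intervals on the shares are profile-likelihood intervals
(chi-square 1-df cutoff, brentq root finding on the profile deviance),
truncated to [0, 1]; a share estimated on the boundary yields a one-sided
interval with a flag. A delta-method interval was considered and
rejected: it misbehaves exactly where twin analyses live, near the
`c2 = 0` boundary.

Traits are assumed preprocessed (inverse-normalized), so a single grand
mean is adequate for the non-saturated models; no covariate adjustment is
applied inside the twin model.

## Twin-aware random-forest prediction

Each metabolite is predicted from species relative abundances (used
untransformed, as compositions) with random forests: a regressor
(`ntree` trees, `mtry = floor(p/3)`, floored at 1) scored by the Spearman
correlation between observed and out-of-fold predicted values, and a
classifier (`mtry = floor(sqrt(p))`) on the response dichotomized into
its bottom (class 0) vs top (class 1) quartiles, scored by out-of-fold
AUC via the Mann–Whitney rank formulation with midrank tie credit.
Middle-quartile samples are removed before fold construction and the
folds rebuilt on the kept subset, keeping fold sizes balanced. Species
with zero or near-zero variance (most-common/second-most-common frequency
ratio > 19 and distinct-value fraction < 10%) are dropped first.

Cross-validation is 5-fold with individual-level randomization followed
by a family purge: for each test fold, any training sample sharing a
family with a test sample is removed from that fold's training set. This
matters because co-twins share both trait variance and microbiome
composition; without the purge, a forest can "predict" a test twin by
memorizing its co-twin, inflating apparent performance. The package keeps
a naive (unpurged) fold builder alongside for exactly this comparison,
and the test suite demonstrates the leakage: with a fully family-shared
trait and family-correlated but causally unrelated microbiomes, naive CV
shows spurious skill that twin-aware CV removes.

Per-fold statistics are summarized by their mean and a t-based 95% CI
over the defined folds; a fold with a constant training target or a
single-class test set is undefined (NaN) and excluded with a warning.

## Association statistics

- **Partial Spearman.** Rank-transform x and y (average ranks),
  residualize each on an intercept + covariates by least squares, and
  take the Pearson correlation of the residuals; the p-value uses the t
  transform with `n - 2 - k` degrees of freedom. With no covariates this
  is exactly Spearman's rho. The species screen vectorizes this across
  all species, applies a strict >20% prevalence filter first, and
  adjusts p-values per screen by Benjamini–Hochberg. A constant covariate
  (e.g. sex in a single-sex cohort) is dropped automatically.
- **Two-cohort concordance.** A feature replicates when it passes BH
  q < 0.05 in the discovery screen, nominal p < 0.05 in the validation
  screen, and has the same estimate sign in both; features absent from
  the validation screen are reported, not silently dropped.
- **Post-prandial summaries.** Baseline is the time-0 value; the peak is
  the maximum over `0 < t <= window`, deliberately excluding the fasting
  sample (a post-prandial peak), so delta = peak − baseline can be
  negative for falling trajectories. Associations between metabolites and
  peak/delta outcomes use OLS with t-based CIs; model R² and F ride along
  for the no-covariate use case. Tertile contrasts are coded 0/1/2 by
  sample tertiles.
- **Meta-analysis.** DerSimonian–Laird random-effects inverse-variance
  pooling with Wald CI/p; with estimated `tau^2 = 0` it reduces exactly
  to fixed-effect pooling. No Knapp–Hartung correction.
- **Paired intervention tests.** Mean of (after − before) with a t-based
  CI; zero difference variance is an error, not a p-value.
- **Clustering.** Complete-linkage agglomeration on Euclidean distances
  between species association profiles, for heatmap leaf ordering.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions under which every recovery claim is made.

- **Twin cohort.** Latent factors per trait: G (shared within MZ,
  correlated 0.5 within DZ), C (shared within any pair), U (independent),
  combined with path coefficients `sqrt(a2), sqrt(c2), sqrt(e2)`.
  Covariates: age ~ Uniform(35, 80) shared within a pair, BMI ~
  Normal(26, 5) per individual, sex ~ Bernoulli(0.5) identical within MZ
  pairs. Optional linear covariate effects can be planted per trait. The
  reference design used in the recovery checks is 654 MZ pairs + 380 DZ
  pairs + 471 singletons (2,539 individuals).
- **Microbiome.** Zero-inflated log-normal: presence gated by a latent
  standard Gaussian thresholded at the target prevalence, abundance
  log-normal with species-specific location ~ Normal(0, 1.5) and log-SD 1
  (heavy right tails), rows closed to unit sum. An optional family factor
  (variance share `family_rho`) enters both the presence latent and the
  log-abundance, correlating co-family profiles while preserving marginal
  prevalence; this is what makes the CV leakage demonstrable. A sample
  with no present species receives its highest-prevalence species before
  closure — so realized prevalence tracks the target only when profiles
  are rich enough that empty samples are rare, which all defaults ensure.
- **Species→metabolite coupling.** `trait = sum_j beta_j log1p(x_j) +
  N(0, noise_sd)`; the realized signal variance and implied
  `R^2 = V_s / (V_s + noise_sd^2)` are reported, and a calibration helper
  picks `noise_sd` for a target R². The recovery checks plant 5 causal
  species among 100 at R² = 0.5.
- **Batches and censoring.** Samples are randomly balanced across
  batches, values multiplied by per-batch scales, and the lowest
  `censor_quantile` fraction of each metabolite set to missing —
  left-censoring by construction, matching the minimum-imputation
  assumption.
- **Meal responses.** A flat baseline plus a smooth bump (zero at the
  window ends, unit maximum over the realized timepoints) whose height is
  `rise_intercept + beta * trait + covariate effects + noise`; the
  trajectory peak therefore equals baseline + height and regression of
  peak on the trait recovers `beta`. The planted default in the recovery
  checks is `beta = 0.32`. Negative realized heights are clamped to zero
  (flat trajectory); with the default intercept of 2.0 this is a
  ~1e-6-probability event, negligible for recovery.

What the generator does **not** emulate: real phylogenetic correlation
structure among species, longitudinal microbiome dynamics, non-linear or
interaction effects of species on metabolites, informative missingness
beyond left-censoring, measurement-batch effects on the microbiome side,
and assortative mating or age effects on twin similarity. Passing
recovery tests therefore demonstrates that the estimators are correct
under their stated models, not that those models capture every property
of real cohort data.

## Problem sizes and runtime choices

The verification suite and `scripts/acceptance.py` use sizes chosen to
make Monte-Carlo error small relative to the assertion bands while
staying comfortable on a single CPU: 50 replicates of the 2,539-person
twin design for model-selection rates; 10⁴+10⁴ pairs for the Falconer
consistency grid; n = 800 samples × 100 species with 200-tree forests
for coupling recovery; n = 400 × 200 species × 200 trees × 50 replicates
for the leakage sign test; 100 (suite) / 50 (script) global-null screens
of 500 species at n = 150 for FDR control. Forests use 200 trees in
these checks; performance estimates stabilize well below the 1000-tree
production default, which remains the default for real analyses.

## Known limitations

- Correlations in the species screen ignore twin relatedness (no mixed
  model); this mirrors the intended analysis but means screen p-values
  are exact only for unrelated subjects.
- Profile-likelihood CIs assume the chi-square calibration, which is
  approximate near boundary estimates; boundary cases are flagged
  one-sided rather than corrected.
- The saturated model assumes exchangeable co-twins (common mean within a
  zygosity group); birth-order effects are not modeled.
- `couple_metabolite` plants additive log1p effects only; forests can of
  course be scored against any externally supplied trait.
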