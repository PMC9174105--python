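# Methods

This note documents the statistical procedures implemented in `gutglyc`,
the assumptions behind them, the synthetic-data generator that stands in
for restricted cohort data, and the numerical and design choices that were
genuinely open.

## Study design being modelled

A prospective cohort: participants from ~15 provinces nested in two
geographic regions (North/South) provide a baseline stool sample
(summarised as a genus-level relative-abundance table), a baseline
glycaemic panel (fasting glucose in mmol/l, fasting insulin in pmol/l,
HbA1c in mmol/mol) and rich covariates; a follow-up survey ~3 years later
repeats the glycaemic panel and records diabetes treatment. Exclusions at
baseline (recent antibiotics, intestinal disease, prevalent diabetes) are
applied sequentially with disjoint accounting. Analyses of follow-up
traits and incidence use the followed-up subsample only.

## Preprocessing

* **Prevalence filter.** A genus is retained when detected (abundance
  strictly > 0) in at least 10% of participants, boundary inclusive.
* **Imputation.** Single imputation within region: continuous covariates
  get the regional mean of observed values, categorical covariates the
  regional mode, ties broken by lexicographic category order. Imputation
  is region-wise (not province-wise) because the regional stratum is the
  analysis unit. Missingness is explicit in the data model; nothing is
  imputed at read time.
* **HOMA-IR** = glucose [mmol/l] × insulin [μU/ml] / 22.5. The cohort
  measures insulin in pmol/l, so it is divided by 6.945 pmol/l per μU/ml
  before entering the formula; the conversion is configurable
  (`RunConfig.insulin_conversion`). With the cohort's mean panel
  (5.2 mmol/l, 50.7 pmol/l) this yields 1.69 ≈ 1.7, matching the published
  summary only under this conversion — which is why 6.945 is the default.
* **HbA1c units** interconvert by the NGSP↔IFCC master equation
  (IFCC = (NGSP% − 2.15) × 10.929).
* **Incident type 2 diabetes** at follow-up: fasting glucose
  ≥ 7.0 mmol/l, or HbA1c ≥ 47.5 mmol/mol (6.5%), or current diabetes
  medication; thresholds inclusive.
* **Staple preference**: wheat/rice intake ratio; ≥ 1 labels a wheat
  preference; zero rice with positive wheat is a wheat preference; zero
  intake of both leaves the label undefined and flagged.

## Association model

Effects are expressed per SD of genus abundance on the SD scale of the
follow-up trait. The exposure is the standardized *relative abundance*
(no log or CLR by default): the per-SD effect scale makes the estimate
invariant to affine rescaling of the raw abundance, and a CLR option
(`RunConfig.clr_transform`, multiplicative zero replacement at half the
minimum positive value) is available for sensitivity. Standardization is
computed within the regional analysis sample, the population actually
modelled. The baseline trait enters raw (untransformed), as an adjustment
rather than an effect of interest.

The regional model is a linear mixed model with a random intercept and a
random genus slope by province, fit by REML. Random slopes on ~6–9
provinces frequently produce singular covariance estimates; the fallback
hierarchy is explicit: full model → random intercept only → refusal, and
the fallback taken is recorded in every result row. Fewer than 30 usable
observations is refused outright.

Two regional estimates are pooled by DerSimonian–Laird. With only two
strata τ² is a noisy quantity; it is reported in every record so
heterogeneity can be audited, and the homogeneous case reduces exactly to
fixed-effect inverse-variance pooling. P-values are two-sided normal.
Benjamini–Hochberg q-values are computed across all genus × trait tests
of one scan variant (the FDR family is the scan). Three variants exist:
primary (BMI-adjusted), +diet (food groups added to the covariates), and
−BMI (for effects potentially mediated by BMI).

**Signed panel.** A genus enters the panel when its pooled p < 0.05 for at
least one trait — deliberately the raw p, not the q-value: in cohorts of
this size individual genus effects are weak and FDR-surviving hits are not
expected, yet the additive index built from nominally significant genera
is the object of interest; q-values are always reported alongside. The
direction comes from the minimum-p admitting association (favourable =
negative β). A genus whose admitting associations tie at the minimum p
with conflicting signs is excluded with a warning — a conservative rule
for a case the additive index cannot represent coherently.

## HMI and risk model

The HMI is an unweighted count: +1 for each favourable genus carried and
each harmful genus absent. "Carried" defaults to abundance > 0, with a
configurable detection threshold for sensitivity. The index is
standardized over the follow-up analysis sample, since that is the
modelled population.

Incidence is modelled by Poisson regression with a log link on the binary
outcome. For a binary outcome the Poisson likelihood is misspecified but
the point estimate remains a consistent log risk ratio; sandwich (HC1)
standard errors (the default) make the Wald CI well calibrated. Model-based
SEs are available behind `robust=False`. Subgroup analyses stratify by
region, age (< / ≥ 50 years), sex, BMI (< / ≥ 24 kg/m², the Chinese
overweight threshold), and urban/rural residence; the stratifying variable
is dropped from that model's covariates, and strata with fewer than 10
events are skipped with a logged reason. Cut-points are configurable.

## Ecology

Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) over genera
(all-zero rows are an error). PCoA is the classical eigendecomposition of
the double-centred −D²/2 matrix; Bray–Curtis is non-Euclidean, so negative
eigenvalues occur and are *excluded* — from the returned axes and from the
explained-variance denominator (no Lingoes/Cailliez correction). Axis
signs are fixed by making each axis's largest-magnitude coordinate
positive, so ordinations are reproducible. The regional test is a
PERMANOVA pseudo-F (the conventional companion to Bray–Curtis ordination)
with whole-label permutations and the add-one p-value
p = (1 + #{F* ≥ F}) / (1 + n_perm), which cannot reach zero; 1000
permutations by default.

## Machine learning

Region classification uses gradient-boosted trees (LightGBM, library
default hyperparameters frozen in `DEFAULT_LGBM_PARAMS` and logged in the
report) evaluated leave-one-province-out: each fold's test set is one
entire province, so geographic leakage is structurally impossible. The
cycle is repeated (default 10×) with seeds `seed + r` and per-participant
probabilities averaged — "repeated" is read as reseeded repetition of the
full cycle. Holding out a whole province skews the training class ratio
towards the other region, and boosted trees leak that prior into held-out
scores (under a null this alone pushes AUC well below 0.5); each fold
therefore trains on equal region counts by seeded downsampling of the
majority class.

Genus attributions use TreeSHAP as implemented inside LightGBM
(`pred_contrib=True`); each fold model attributes its own held-out
samples, attributions are pooled over folds and repeats, and a genus is
region-discriminating when its mean |SHAP| exceeds 1e-12 (a
floating-point floor on the strict "> 0" rule).

Diet prediction from the selected genera is tenfold cross-validated
gradient boosting; folds are stratified by region so a geography imbalance
cannot dominate the signal. Performance is the Pearson correlation of
out-of-fold predictions (regression) or ROC AUC with a Hanley–McNeil
normal-approximation 95% CI (classification).

## Diet and lifestyle regressions

For each factor (wheat, rice, wheat/rice ratio, fruit, vegetable, nuts,
pork, poultry, milk, egg, fish, alcohol, smoking, physical activity):
linear regression of each standardized panel genus and the HMI on the
factor, mutually adjusted for the other factors plus confounders (age,
sex, BMI, energy, income, marital status, education, residence,
urbanisation index, animal and vegetable oil). Continuous factors are
standardized (per-SD effects); smoking and alcohol are binary
(per-category effects). Wheat, rice and their ratio are functionally
dependent and never co-included in one model. The ratio is modelled on
the log scale: a ratio is multiplicative, and the raw ratio's heavy right
tail (near-zero rice intakes) otherwise creates single high-leverage
points that fabricate spurious associations. Near-collinear factor pairs
(|r| > 0.99) keep the first member, logged. BH FDR runs across the full
factor × outcome grid; q < 0.05 flags a discovery. The fibre scan uses
the identical machinery with fibre as sole dietary exposure. The
food-group → trait regressions are fit twice, differing only by the HMI
term, so attenuation can be read off directly.

## Synthetic cohort generator

The generator is first-class, tested code defining the package's study
conditions. Defaults: 2772 participants, 80 genera, 15 provinces
(6 North / 9 South at the observed 36/64 split), 66% MCAR retention at
follow-up, a 25-genus panel (15 favourable / 10 harmful), per-SD HMI log
risk ratio ln(0.69), baseline incidence 0.067 (≈123 events among 1829).

* **Abundances** are zero-inflated log-normal compositions: per-genus
  occupancy probability (a few "core" genera are always present, ruling
  out all-zero rows), log-normal abundance given carriage, a per-genus
  regional shift applied on the log scale (default: 12 genera, ±0.8),
  optional diet effects on the log scale, rows closed to sum 1.
  Zero-inflated log-normal was chosen over Dirichlet because prevalence
  (occupancy) and abundance must be controllable independently — the
  prevalence filter and the HMI's carriage logic both key on zeros.
* **Covariates** are drawn to match the cohort's published region-specific
  means/SDs (normal, gamma or log-normal as appropriate for each
  quantity). Daily fibre intake is not tabulated there; 10.8 ± 5 g/day, a
  typical adult intake in this population, is used.
* **Follow-up traits** follow a z-scale structural model:
  z₁ = 0.5·z₀ + Σ β_g·z_g + 0.1·age_z + c_bmi·bmi_z + u_province + ε, with
  the residual variance chosen so Var(z₁) ≈ 1 — hence the planted β *is*
  the per-SD estimand the association scan reports. Fasting insulin is
  generated log-normally (its realistic scale), so planted insulin
  effects live on the log scale and recovery on the raw-insulin z scale
  is approximate; glucose and HbA1c recover exactly. HOMA-IR is derived
  from glucose × insulin at analysis time, so it has no free planted
  parameter. An optional mediation construction routes a genus effect
  through BMI only.
* **Incidence** is Bernoulli with log p = log(p₀) + log RR · HMI_z, where
  HMI_z comes from the planted panel — a log-link process, so the Poisson
  regression estimand equals the planted parameter exactly. Configs whose
  implied probability reaches 1 are rejected. The draw is encoded in the
  follow-up panel so threshold ascertainment recovers it exactly: cases
  carry the medication flag, and non-cases have follow-up glucose/HbA1c
  clipped just below the diagnostic cut-offs (a "verified diabetes-free"
  follow-up). The clip affects < 1% of values; without it, background
  threshold crossings unrelated to the microbiome dilute the planted risk
  ratio by ~10%, and bumping case glucose instead would inflate the trait
  variance and attenuate every per-SD trait effect.
* **Attrition** is MCAR — the design being emulated reports no attrition
  model, so this is an explicit assumption, not a finding.

What passing tests on this generator do **not** show: robustness to
phylogenetic correlation between genera, informative missingness or
attrition, measurement error in diet recall, or real-data effect sizes
(the published per-genus associations are weak and none survive FDR; the
generator's defaults are calibrated for testability of the machinery, and
power/type-I claims are about the methods, not about any real cohort).

## Numerical choices

* Standardization uses the sample SD (ddof = 1); constant columns are a
  named error.
* The exclusion cascade counts each participant once, at the first
  criterion met (sequential, disjoint accounting).
* Stage seeds derive from the global seed by a 31-bit blake2s hash of
  `"{seed}:{stage}"`, so stages are independently reproducible.
* Mixed-model optimisation tries L-BFGS then CG with up to 200 iterations;
  non-convergence or a singular random-effects covariance triggers the
  documented fallback.
* Categorical covariates are dummy-encoded with the first level dropped.
* The permutation test, classifier repeats, CV splits and the generator
  all take explicit integer seeds; identical seed + config is
  bit-identical.

## Problem sizes

The shipped test suite exercises the pipeline at n = 500–2772 for
structural tests, n = 2000 for effect-recovery and power checks
(10–12 seeds), n = 1200 × 40 genera for the type-I calibration of the
full scan, and n = 20,000 × 30 seeds for risk-ratio recovery; these sizes
give the calibration assertions comfortable binomial tolerances while the
whole suite stays fast enough for routine development.

## Known limitations

* DerSimonian–Laird with k = 2 strata estimates τ² from a single degree
  of freedom; the pooled CI can under-cover under real heterogeneity.
* The Poisson risk model ignores follow-up time variation (no offset);
  with a ~3-year near-constant follow-up the risk ratio and rate ratio
  coincide, but variable follow-up would need an exposure offset.
* Multiple imputation (chained equations) is out of scope; the package
  implements single region-wise imputation only.
* The PCoA reports no correction for negative eigenvalues; explained
  variance is relative to the positive spectrum only.
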