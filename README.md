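# gutglyc

Gut microbiota and glycaemic traits in a two-region prospective cohort:
a reusable, fully tested implementation of the analysis that links
genus-level gut microbial abundances to fasting glucose, fasting insulin,
HbA1c and HOMA-IR, builds a **Healthy Microbiome Index (HMI)** from the
trait-related genera, and estimates the HMI's association with incident
type 2 diabetes.

It is written for epidemiologists and microbiome analysts who have a
participants × genera relative-abundance table (16S, genus level) and a
longitudinal metadata table, and who want the whole chain — filtering,
region-stratified mixed models, meta-analytic pooling, index construction,
risk modelling, geography-aware machine learning and diet regressions —
as composable, seedable library functions. Because cohort data of this
kind are usually access-restricted, the package ships a synthetic cohort
generator that emulates the study design with *planted, recoverable*
parameters, so every stage is testable end to end without any download.

## The model

**Genus–trait association.** Within each geographic region, for genus *g*
and follow-up trait *y* (both standardized within the regional analysis
sample),

```
y₁ᵢ(z) = β · gᵢ(z) + γ · y₀ᵢ + covariatesᵢ + u_p(i) + b_p(i) · gᵢ(z) + εᵢ
```

a linear mixed model with random intercept `u_p` and random genus slope
`b_p` by province (REML; falls back to random intercept only when the
random-effects covariance is singular). The Northern and Southern
estimates are pooled by DerSimonian–Laird random-effects meta-analysis:

```
τ² = max(0, (Q − 1) / (Σw − Σw²/Σw)),   w*ᵢ = 1/(seᵢ² + τ²)
β_pooled = Σ w*β / Σ w*,   se_pooled = (Σ w*)^(−1/2)
```

with Benjamini–Hochberg q-values over the whole scan.

**Healthy Microbiome Index.** Genera with pooled p < 0.05 for ≥ 1 trait
form a signed panel (favourable if β < 0, harmful if β > 0) and

```
HMIᵢ = Σⱼ gᵢⱼ,  gᵢⱼ = 1 if i carries favourable genus j
                        or does not carry harmful genus j, else 0,
```

where "carries" means relative abundance > 0 (threshold configurable).
Incident diabetes (fasting glucose ≥ 7.0 mmol/l, HbA1c ≥ 47.5 mmol/mol,
or diabetes medication) is modelled by Poisson regression with a log link
on the standardized baseline HMI, with sandwich (HC1) standard errors;
`RR = exp(β_HMI)` is the risk ratio per SD of HMI.

Other stages: Bray–Curtis dissimilarity + PCoA + seeded PERMANOVA
(pseudo-F, add-one permutation p); leave-one-province-out LightGBM region
classification with mean-|SHAP| genus selection; tenfold cross-validated
diet prediction; mutually adjusted diet/lifestyle → genus regressions.

## Worked example

```python
from gutglyc import generate_cohort, compute_hmi, hmi_risk_model
from gutglyc.assoc import SignedPanel
from gutglyc.preprocess import derive_glycaemic_panel
from gutglyc.tables import GenusAbundanceTable, DEMO_COVARIATES
import math

table, cohort, truth = generate_cohort(
    n_participants=20000, seed=5,
    truth={"hmi_log_rr": math.log(0.69), "baseline_incidence": 0.067})
cohort = derive_glycaemic_panel(cohort)
followed = cohort.loc[cohort["incident_t2d"].notna()]
scores = compute_hmi(
    GenusAbundanceTable(table.data.loc[followed["participant_id"]]),
    SignedPanel(entries=truth.panel))
est = hmi_risk_model(scores["hmi_z"], followed["incident_t2d"],
                     followed[DEMO_COVARIATES].astype(
                         {"sex": str, "marital": str, "education": str,
                          "residence": str, "alcohol": str, "smoking": str}))
print(f"RR per SD of HMI: {est.rr:.3f} ({est.ci_low:.3f}, {est.ci_high:.3f})")
```

prints (seed 5):

```
RR per SD of HMI: 0.710 (0.669, 0.754)
```

i.e. each additional SD of the Healthy Microbiome Index is associated
with ~29% lower incidence in this cohort — the covariate-adjusted Poisson
fit recovering the planted risk ratio of 0.69 within its 95% CI. The
scripts in `examples/` walk every other capability the same way
(simulation, preprocessing, ecology, the association scan, subgroups, the
region classifier, diet regressions), each printing the numbers it
computes and what they mean.

A thin CLI mirrors the pipeline: `gutglyc simulate | preprocess | ecology
| assoc | hmi | region-ml | diet-assoc | all`, each taking `--seed`,
`--config` (YAML/JSON) and `--outdir`; `gutglyc all` writes a manifest
with per-stage seeds and output checksums.

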