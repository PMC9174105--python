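"""Healthy Microbiome Index and incident-diabetes risk, with subgroups.

Scores every followed-up participant against the signed genus panel
(carrying a favourable genus or lacking a harmful one each add 1), then
fits a covariate-adjusted Poisson model of incident type 2 diabetes on the
standardized HMI. The planted truth is RR = 0.69 per SD.
"""

import math

from gutglyc import generate_cohort, compute_hmi, hmi_risk_model, subgroup_scan
from gutglyc.assoc import SignedPanel
from gutglyc.preprocess import derive_glycaemic_panel
from gutglyc.tables import GenusAbundanceTable, DEMO_COVARIATES, CATEGORICAL_COVARIATES

table, cohort, truth = generate_cohort(
    n_participants=20000, seed=5,
    truth={"hmi_log_rr": math.log(0.69), "baseline_incidence": 0.067},
)
cohort = derive_glycaemic_panel(cohort)
followed = cohort.loc[cohort["incident_t2d"].notna()].reset_index(drop=True)

panel = SignedPanel(entries=truth.panel)
scores = compute_hmi(
    GenusAbundanceTable(table.data.loc[followed["participant_id"]]), panel
)
cov = followed[DEMO_COVARIATES].copy()
for c in CATEGORICAL_COVARIATES:
    cov[c] = cov[c].astype(str)

est = hmi_risk_model(scores["hmi_z"], followed["incident_t2d"], cov)
print(f"HMI range {scores['hmi'].min()}-{scores['hmi'].max()} over a "
      f"{len(panel.entries)}-genus panel; {est.n_events}/{est.n} incident cases")
print(f"risk ratio per SD of HMI: {est.rr:.3f} "
      f"(95% CI {est.ci_low:.3f}, {est.ci_high:.3f}); planted 0.690")

for e in subgroup_scan(followed, scores["hmi_z"].to_numpy(),
                       followed["incident_t2d"].to_numpy()):
    print(f"  {e.subgroup:<22} RR {e.rr:.3f} ({e.ci_low:.3f}, {e.ci_high:.3f}) "
          f"[{e.n_events}/{e.n}]")
print("A homogeneous planted effect shows similar RRs in every stratum - "
      "the robustness pattern the subgroup analysis is designed to reveal.")
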