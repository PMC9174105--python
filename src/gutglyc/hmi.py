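"""Healthy Microbiome Index (HMI) and its incident-diabetes risk model.

The HMI is an unweighted additive score over the signed genus panel:

    HMI_i = sum_j g_ij,   g_ij = 1 if participant i carries a favourable
                          genus j, or does not carry a harmful genus j;
                          otherwise g_ij = 0.

"Carries" means relative abundance strictly above a detection threshold
(default 0: any detection). The prospective association of the baseline
HMI (per SD) with incident type 2 diabetes is estimated by Poisson
regression with a log link on the binary outcome; sandwich (HC1) standard
errors make the Wald 95% CI well calibrated for a binary outcome, and
RR = exp(coefficient) is the risk ratio per SD of HMI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import SignedPanel, _design_matrix
from .preprocess import standardize
from .tables import GenusAbundanceTable, DEMO_COVARIATES, CATEGORICAL_COVARIATES

logger = logging.getLogger(__name__)


def carries(abundance, threshold: float = 0.0):
    """1 iff the relative abundance is strictly above the detection threshold."""
    a = np.asarray(abundance, dtype=float)
    if (a < 0).any():
        raise ValueError("abundance must be non-negative")
    result = (a > threshold).astype(int)
    return int(result) if result.ndim == 0 else result


def compute_hmi(
    abundance: GenusAbundanceTable,
    panel: SignedPanel,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Score every participant against the signed panel.

    Panel genera absent from the table count as not carried (zero-filled
    columns). Returns a DataFrame indexed by participant with the integer
    ``hmi`` (0..m) and ``hmi_z`` standardized over the scored sample.
    """
    if not panel.entries:
        raise ValueError("empty signed panel")
    data = abundance.data
    scores = np.zeros(len(data), dtype=int)
    for genus, direction in panel.entries:
        col = data[genus].to_numpy() if genus in data.columns else np.zeros(len(data))
        c = carries(col, threshold)
        scores += c if direction == "favourable" else 1 - c
    hmi = pd.DataFrame({"hmi": scores}, index=data.index)
    try:
        z, _, _ = standardize(hmi["hmi"].rename("hmi"))
    except ValueError:  # constant score (e.g. single participant): no z-scale
        z = np.full(len(hmi), np.nan)
    hmi["hmi_z"] = z
    return hmi


@dataclass
class RiskEstimate:
    """Risk ratio per SD of HMI with its Wald 95% CI."""

    rr: float
    ci_low: float
    ci_high: float
    subgroup: str = "overall"
    n: int = 0
    n_events: int = 0
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def hmi_risk_model(
    hmi_z,
    incident_t2d,
    covariates: pd.DataFrame | None = None,
    robust: bool = True,
    subgroup: str = "overall",
) -> RiskEstimate:
    """Poisson regression of incident diabetes on the standardized HMI.

    The outcome is binary; the log link makes exp(coefficient) a risk
    ratio per SD of HMI. With ``robust`` (default) the Wald CI uses HC1
    sandwich standard errors. Requires >= 10 events; zero events is an
    error. Quasi-separation (divergent coefficient) is flagged rather than
    silently reported.
    """
    x = np.asarray(hmi_z, dtype=float)
    y = np.asarray(incident_t2d, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("incident_t2d must be binary")
    n_events = int(y.sum())
    if n_events == 0:
        raise ValueError("no incident events")
    if n_events < 10:
        raise ValueError(f"only {n_events} events (< 10); estimate would be unstable")

    parts = [np.ones(len(y)), x]
    cov = _design_matrix(covariates)
    if cov is not None:
        parts.append(cov.to_numpy(dtype=float).T)
    exog = np.column_stack([p.T if p.ndim > 1 else p for p in parts])
    model = sm.GLM(y, exog, family=sm.families.Poisson())
    res = model.fit(cov_type="HC1" if robust else "nonrobust")
    coef = float(res.params[1])
    se = float(res.bse[1])
    separation = (not np.isfinite(se)) or abs(coef) > 10
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    return RiskEstimate(
        rr=float(np.exp(coef)), ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        subgroup=subgroup, n=len(y), n_events=n_events,
        separation_flag=bool(separation),
    )


#: Default stratifications: name -> (column builder, covariate to drop).
def _default_strata(age_cut: float, bmi_cut: float) -> dict:
    return {
        "region": (lambda df: df["region"], None),
        "age_group": (
            lambda df: np.where(df["age"] < age_cut, f"age<{age_cut:g}", f"age>={age_cut:g}"),
            "age",
        ),
        "sex": (lambda df: df["sex"], "sex"),
        "bmi_level": (
            lambda df: np.where(df["bmi"] < bmi_cut, f"bmi<{bmi_cut:g}", f"bmi>={bmi_cut:g}"),
            "bmi",
        ),
        "urbanisation": (lambda df: df["residence"], "residence"),
    }


def subgroup_scan(
    cohort: pd.DataFrame,
    hmi_z,
    incident_t2d,
    covariate_columns: list[str] | None = None,
    age_cutpoint: float = 50.0,
    bmi_cutpoint: float = 24.0,
    robust: bool = True,
) -> list[RiskEstimate]:
    """Fit the HMI risk model within each subgroup stratum.

    Strata: geographic region, age group (< / >= ``age_cutpoint`` years),
    sex, BMI level (< / >= ``bmi_cutpoint`` kg/m^2) and urbanisation
    (urban/rural residence). The stratifying variable is removed from that
    model's covariates. Strata failing the risk-model preconditions
    (e.g. < 10 events) are skipped with a logged reason.
    """
    covariate_columns = covariate_columns or list(DEMO_COVARIATES)
    hmi_z = np.asarray(hmi_z, dtype=float)
    incident = np.asarray(incident_t2d, dtype=float)
    estimates: list[RiskEstimate] = []
    for name, (labeller, drop) in _default_strata(age_cutpoint, bmi_cutpoint).items():
        labels = np.asarray(labeller(cohort))
        cols = [c for c in covariate_columns if c != drop]
        for level in pd.unique(labels):
            mask = labels == level
            sub = cohort.loc[mask, cols].copy()
            for c in CATEGORICAL_COVARIATES:
                if c in sub.columns:
                    sub[c] = sub[c].astype(str)
            try:
                est = hmi_risk_model(
                    hmi_z[mask], incident[mask], sub, robust=robust,
                    subgroup=f"{name}={level}",
                )
            except ValueError as exc:
                logger.warning("skipping stratum %s=%s: %s", name, level, exc)
                continue
            estimates.append(est)
    return estimates
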