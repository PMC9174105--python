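"""Diet/lifestyle - microbiota association regressions.

Cross-sectional linear regressions estimate, for each dietary or lifestyle
factor, the difference in each glycaemic-trait-related genus (and in the
HMI) in SD units per SD change of a continuous factor (per category for
binary factors), adjusted for confounders and mutually adjusted for the
other tested factors. A separate scan tests dietary fibre as the sole
dietary exposure. Finally, food-group -> glycaemic-trait regressions are
fit with and without the HMI term, to ask how much of any diet effect is
carried by the microbiome score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import bh_fdr, _design_matrix
from .preprocess import standardize, staple_ratio_frame
from .tables import CATEGORICAL_COVARIATES

logger = logging.getLogger(__name__)

#: Tested dietary / lifestyle factors (continuous unless listed as binary).
DIET_FACTORS = [
    "wheat", "rice", "staple_ratio", "fruit", "vegetable", "nuts", "pork",
    "poultry", "milk", "egg", "fish", "alcohol", "smoking",
    "physical_activity",
]
BINARY_FACTORS = {"alcohol", "smoking"}

#: Wheat, rice and their ratio are functionally dependent: no model may
#: contain two of them.
_STAPLE_TRIO = {"wheat", "rice", "staple_ratio"}

#: Confounders for the diet scans.
DIET_ADJ_COVARIATES = [
    "age", "sex", "bmi", "energy", "income", "marital", "education",
    "residence", "urbanisation_index", "animal_oil", "vegetable_oil",
]


def _factor_matrix(cohort: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Analysis-ready factor columns: continuous standardized, binary as 0/1."""
    out = pd.DataFrame(index=cohort.index)
    ratio = None
    if "staple_ratio" in factors:
        raw = staple_ratio_frame(cohort)["staple_ratio"]
        # a ratio is a multiplicative quantity: model it on the log scale,
        # which also removes the extreme leverage of near-zero denominators
        with np.errstate(divide="ignore"):
            ratio = np.log(raw.to_numpy(dtype=float))
        if not np.isfinite(ratio).all():
            raise ValueError(
                "staple ratio is zero, infinite or undefined for some "
                "participants; resolve zero-intake rows before the diet scan"
            )
    for f in factors:
        if f == "staple_ratio":
            x = ratio
        else:
            x = cohort[f].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"factor {f!r} has missing values; impute first")
        if f in BINARY_FACTORS:
            out[f] = x
        else:
            out[f], _, _ = standardize(pd.Series(x, name=f))
    return out


def _drop_collinear(factors_df: pd.DataFrame, threshold: float = 0.99) -> pd.DataFrame:
    """Drop the later factor of any near-collinear pair (|r| > threshold)."""
    keep = list(factors_df.columns)
    corr = factors_df.corr().abs()
    for i, a in enumerate(factors_df.columns):
        for b in factors_df.columns[i + 1:]:
            if a in keep and b in keep and corr.loc[a, b] > threshold:
                logger.warning("dropping %r: collinear with %r (|r|=%.3f)",
                               b, a, corr.loc[a, b])
                keep.remove(b)
    return factors_df[keep]


def _covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    cov = cohort[DIET_ADJ_COVARIATES].copy()
    for c in CATEGORICAL_COVARIATES:
        if c in cov.columns:
            cov[c] = cov[c].astype(str)
    return _design_matrix(cov)


def mutual_adjustment_sets(factors: list[str]) -> dict[str, list[str]]:
    """Which other factors enter each factor's mutually adjusted model.

    Symmetric by construction except for the wheat/rice/ratio exclusion
    rule, which removes staple-trio pairs from both sides.
    """
    return {
        f: [
            g for g in factors
            if g != f and not (f in _STAPLE_TRIO and g in _STAPLE_TRIO)
        ]
        for f in factors
    }


def _ols_scan(
    outcomes_z: pd.DataFrame,
    factors_df: pd.DataFrame,
    cov_mat: pd.DataFrame,
    mutual: bool,
) -> pd.DataFrame:
    """One OLS per factor x outcome; exposure coefficient collected."""
    records = []
    adjustment = mutual_adjustment_sets(list(factors_df.columns))
    for factor in factors_df.columns:
        others = adjustment[factor] if mutual else []
        X = np.column_stack(
            [np.ones(len(factors_df)), factors_df[factor].to_numpy()]
            + [factors_df[f].to_numpy() for f in others]
            + [cov_mat.to_numpy(dtype=float)]
        )
        for outcome in outcomes_z.columns:
            res = sm.OLS(outcomes_z[outcome].to_numpy(), X).fit()
            records.append({
                "factor": factor, "outcome": outcome,
                "beta": float(res.params[1]), "se": float(res.bse[1]),
                "p": float(res.pvalues[1]),
            })
    out = pd.DataFrame.from_records(records)
    out["q_bh"] = bh_fdr(out["p"].to_numpy())
    out["direction"] = np.where(out["beta"] >= 0, "positive", "negative")
    return out


def diet_genus_scan(
    cohort: pd.DataFrame,
    outcomes_z: pd.DataFrame,
    factors: list[str] | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Associate every diet/lifestyle factor with every panel genus and the HMI.

    ``outcomes_z`` holds one standardized column per glycaemic-trait-related
    genus (and typically an ``HMI`` column), row-aligned with ``cohort``.
    Each factor's model mutually adjusts for the other factors (except that
    wheat, rice and the wheat/rice ratio are never co-included) plus the
    standard confounders; near-collinear factor pairs (|r| > 0.99) keep only
    the first member. BH FDR is applied across the full factor x outcome
    grid; ``significant`` flags q below ``fdr_q``.
    """
    factors_df = _drop_collinear(_factor_matrix(cohort, factors or DIET_FACTORS))
    out = _ols_scan(outcomes_z, factors_df, _covariates(cohort), mutual=True)
    out["significant"] = out["q_bh"] < fdr_q
    return out


def fibre_scan(
    cohort: pd.DataFrame, outcomes_z: pd.DataFrame, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Associate dietary fibre (sole exposure) with the panel genera / HMI.

    Same covariates and output schema as :func:`diet_genus_scan`.
    """
    fibre = pd.DataFrame(index=cohort.index)
    fibre["fibre"], _, _ = standardize(cohort["fibre"].rename("fibre"))
    out = _ols_scan(outcomes_z, fibre, _covariates(cohort), mutual=False)
    out["significant"] = out["q_bh"] < fdr_q
    return out


def trait_regression_with_without_hmi(
    cohort: pd.DataFrame,
    trait_z,
    hmi_z,
    food_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Food-group -> glycaemic-trait coefficients with and without the HMI.

    Two OLS models of the standardized trait on all (standardized) food
    groups plus confounders, differing only by the ``hmi_z`` term. Returns
    one row per food group with the paired coefficients, so attenuation
    after HMI adjustment can be read off directly.
    """
    food_groups = food_groups or [
        f for f in DIET_FACTORS if f not in BINARY_FACTORS
        and f not in {"staple_ratio", "physical_activity"}
    ]
    factors_df = _factor_matrix(cohort, food_groups)
    cov = _covariates(cohort)
    y = np.asarray(trait_z, dtype=float)
    base = np.column_stack(
        [np.ones(len(y))]
        + [factors_df[f].to_numpy() for f in factors_df.columns]
        + [cov.to_numpy(dtype=float)]
    )
    with_hmi = np.column_stack([base, np.asarray(hmi_z, dtype=float)])
    res0 = sm.OLS(y, base).fit()
    res1 = sm.OLS(y, with_hmi).fit()
    rows = []
    for i, f in enumerate(factors_df.columns, start=1):
        rows.append({
            "factor": f,
            "beta_without_hmi": float(res0.params[i]),
            "se_without_hmi": float(res0.bse[i]),
            "p_without_hmi": float(res0.pvalues[i]),
            "beta_with_hmi": float(res1.params[i]),
            "se_with_hmi": float(res1.bse[i]),
            "p_with_hmi": float(res1.pvalues[i]),
        })
    return pd.DataFrame(rows)
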