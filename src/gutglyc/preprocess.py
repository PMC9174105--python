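"""Cohort preprocessing: exclusions, prevalence filter, imputation, derived variables.

The pipeline's preprocessing mirrors standard epidemiological practice for a
prospective microbiome cohort:

* a sequential exclusion cascade (recent antibiotics, history of intestinal
  disease, prevalent diabetes at baseline) with disjoint accounting;
* a genus prevalence filter - a genus is kept when detected (abundance > 0)
  in at least a stated fraction of participants, boundary inclusive;
* single imputation of covariates within geographic region (mean for
  continuous, mode for categorical, ties broken lexicographically);
* derived variables: HOMA-IR, HbA1c unit conversion, incident-diabetes
  ascertainment, wheat/rice staple preference;
* per-SD standardization, returning the scaling constants so effects can be
  reported back on the measured scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GenusAbundanceTable, DEMO_COVARIATES, CATEGORICAL_COVARIATES, FOOD_GROUPS


@dataclass
class ExclusionReport:
    """Disjoint accounting of the baseline exclusion cascade."""

    n_input: int
    n_excluded_antibiotics: int
    n_excluded_intestinal_disease: int
    n_excluded_prevalent_t2d: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_excluded_antibiotics
            + self.n_excluded_intestinal_disease
            + self.n_excluded_prevalent_t2d
        )
        assert self.n_retained == self.n_input - total


#: Exclusion criteria in application order.
EXCLUSION_ORDER = ["antibiotics", "intestinal_disease", "prevalent_t2d"]


def apply_exclusions(
    cohort: pd.DataFrame, flags: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the baseline exclusion cascade.

    ``flags`` has one row per participant (aligned on ``participant_id`` if
    present, else positionally) and boolean columns ``antibiotics``,
    ``intestinal_disease`` and ``prevalent_t2d``. Criteria are applied in
    that order; a participant meeting several criteria is counted once,
    under the first criterion met.
    """
    missing = [c for c in EXCLUSION_ORDER if c not in flags.columns]
    if missing:
        raise ValueError(f"exclusion flags missing criteria: {missing}")
    if "participant_id" in flags.columns:
        flags = (
            flags.set_index("participant_id")
            .reindex(cohort["participant_id"])
            .fillna(False)
        )
    elif len(flags) != len(cohort):
        raise ValueError("flags and cohort have different lengths")

    remaining = np.ones(len(cohort), dtype=bool)
    counts = {}
    for criterion in EXCLUSION_ORDER:
        hit = remaining & flags[criterion].to_numpy(dtype=bool)
        counts[criterion] = int(hit.sum())
        remaining &= ~hit
    report = ExclusionReport(
        n_input=len(cohort),
        n_excluded_antibiotics=counts["antibiotics"],
        n_excluded_intestinal_disease=counts["intestinal_disease"],
        n_excluded_prevalent_t2d=counts["prevalent_t2d"],
        n_retained=int(remaining.sum()),
    )
    return cohort.loc[remaining].reset_index(drop=True), report


def filter_prevalence(
    table: GenusAbundanceTable, threshold: float = 0.10
) -> tuple[GenusAbundanceTable, list[str]]:
    """Keep genera detected in at least ``threshold`` of participants.

    Detection means strictly positive abundance; the boundary is inclusive
    (a genus present in exactly 10% of participants passes a 0.10
    threshold).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if table.n_participants == 0 or table.n_genera == 0:
        raise ValueError("empty abundance table")
    prev = table.prevalence()
    keep = prev >= threshold
    dropped = list(prev.index[~keep])
    return GenusAbundanceTable(table.data.loc[:, keep]), dropped


#: Columns imputed by impute_missing, split by type.
CONTINUOUS_IMPUTABLE = [
    c for c in DEMO_COVARIATES if c not in CATEGORICAL_COVARIATES
] + FOOD_GROUPS + ["fibre"]
CATEGORICAL_IMPUTABLE = list(CATEGORICAL_COVARIATES)


def impute_missing(cohort: pd.DataFrame) -> pd.DataFrame:
    """Single imputation of covariates within region.

    Continuous covariates get the mean of observed values in the same
    region; categorical covariates get the modal category in the same
    region, ties broken by lexicographic order of the category label.
    Observed cells are never touched. A region with no observed value for a
    column is an error.
    """
    if cohort["region"].isna().any():
        raise ValueError("region column must be complete before imputation")
    out = cohort.copy()
    for col in CONTINUOUS_IMPUTABLE:
        if not out[col].isna().any():
            continue
        means = out.groupby("region")[col].mean()
        if means.isna().any():
            bad = means.index[means.isna()][0]
            raise ValueError(f"no observed values of {col!r} in region {bad!r}")
        fill = out["region"].map(means)
        out[col] = out[col].fillna(fill)
    for col in CATEGORICAL_IMPUTABLE:
        if not out[col].isna().any():
            continue
        modes = {}
        for reg, grp in out.groupby("region")[col]:
            counts = grp.value_counts()
            if counts.empty:
                raise ValueError(f"no observed values of {col!r} in region {reg!r}")
            top = counts[counts == counts.max()]
            modes[reg] = sorted(str(k) for k in top.index)[0]
            # preserve original dtype of the modal value
            modes[reg] = next(k for k in top.index if str(k) == modes[reg])
        fill = out["region"].map(modes)
        out[col] = out[col].fillna(fill)
        if cohort[col].dtype.kind in "iu":
            out[col] = out[col].astype(cohort[col].dtype)
    return out


def compute_homa_ir(
    glucose: float | np.ndarray,
    insulin: float | np.ndarray,
    conversion: float = 6.945,
) -> float | np.ndarray:
    """HOMA-IR = fasting glucose (mmol/l) x fasting insulin (uU/ml) / 22.5.

    ``insulin`` is given in pmol/l and converted to uU/ml by dividing by
    ``conversion`` (default 6.945 pmol/l per uU/ml), since the classical
    formula expects uU/ml.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if conversion <= 0:
        raise ValueError("conversion must be positive")
    if (glucose < 0).any() or (insulin < 0).any():
        raise ValueError("glucose and insulin must be non-negative")
    result = glucose * (insulin / conversion) / 22.5
    return float(result) if result.ndim == 0 else result


def ngsp_to_ifcc(hba1c_percent: float) -> float:
    """Convert HbA1c from NGSP (%) to IFCC (mmol/mol), one decimal.

    Master equation: (NGSP - 2.15) x 10.929.
    """
    if hba1c_percent < 0:
        raise ValueError("HbA1c must be non-negative")
    return round((hba1c_percent - 2.15) * 10.929, 1)


def ascertain_t2d(
    glucose_1: float | np.ndarray,
    hba1c_1: float | np.ndarray,
    on_medication: int | np.ndarray,
) -> int | np.ndarray:
    """Incident type 2 diabetes at follow-up.

    Positive iff fasting glucose >= 7.0 mmol/l, or HbA1c >= 47.5 mmol/mol
    (6.5%), or current medical treatment for diabetes. Thresholds inclusive.
    Inputs must be complete (this step runs after imputation).
    """
    g = np.asarray(glucose_1, dtype=float)
    h = np.asarray(hba1c_1, dtype=float)
    m = np.asarray(on_medication, dtype=float)
    if np.isnan(g).any() or np.isnan(h).any() or np.isnan(m).any():
        raise ValueError("ascertain_t2d requires complete inputs")
    result = ((g >= 7.0) | (h >= 47.5) | (m > 0)).astype(int)
    return int(result) if result.ndim == 0 else result


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Z-score a vector using the analysis sample's mean and sample SD.

    Returns ``(z, mean, sd)`` so effects can be back-transformed to the
    measured scale. A constant vector is an error (the column name is
    included when a named Series is passed).
    """
    name = getattr(values, "name", None)
    x = np.asarray(values, dtype=float)
    mean = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        label = f" {name!r}" if name else ""
        raise ValueError(f"cannot standardize constant column{label}")
    return (x - mean) / sd, mean, sd


def staple_ratio(
    wheat: float, rice: float
) -> tuple[float, str | None]:
    """Wheat/rice intake ratio and staple-preference label.

    Ratio >= 1 labels a wheat preference, otherwise rice. Zero rice with
    positive wheat gives an infinite ratio (wheat preference); zero intake
    of both leaves the label undefined (``None``) and the ratio NaN, to be
    flagged by the caller.
    """
    if wheat < 0 or rice < 0:
        raise ValueError("intakes must be non-negative")
    if wheat == 0 and rice == 0:
        return float("nan"), None
    if rice == 0:
        return float("inf"), "wheat"
    ratio = wheat / rice
    return ratio, "wheat" if ratio >= 1 else "rice"


def staple_ratio_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`staple_ratio` over a cohort table.

    Returns a DataFrame with ``staple_ratio`` (float, inf allowed) and
    ``staple_preference`` ('wheat'/'rice', NaN when both intakes are zero).
    """
    wheat = cohort["wheat"].to_numpy(dtype=float)
    rice = cohort["rice"].to_numpy(dtype=float)
    if (wheat < 0).any() or (rice < 0).any():
        raise ValueError("intakes must be non-negative")
    both_zero = (wheat == 0) & (rice == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(both_zero, np.nan, wheat / np.where(rice == 0, np.nan, rice))
    ratio = np.where((rice == 0) & (wheat > 0), np.inf, ratio)
    pref = np.where(ratio >= 1, "wheat", "rice")
    pref = pd.array(pref, dtype="string")
    pref[both_zero] = pd.NA
    return pd.DataFrame(
        {"staple_ratio": ratio, "staple_preference": pref},
        index=cohort.index,
    )


def derive_glycaemic_panel(
    cohort: pd.DataFrame, conversion: float = 6.945
) -> pd.DataFrame:
    """Attach derived glycaemic variables to a cohort table.

    Adds ``homa_ir_0``/``homa_ir_1`` and the incident-diabetes flag
    ``incident_t2d`` (NaN where the follow-up panel is missing).
    """
    out = cohort.copy()
    out["homa_ir_0"] = compute_homa_ir(
        out["fasting_glucose_0"], out["fasting_insulin_0"], conversion
    )
    out["homa_ir_1"] = compute_homa_ir(
        out["fasting_glucose_1"].fillna(0), out["fasting_insulin_1"].fillna(0), conversion
    )
    followed = out["fasting_glucose_1"].notna()
    out.loc[~followed, "homa_ir_1"] = np.nan
    inc = pd.Series(np.nan, index=out.index)
    idx = followed & out["hba1c_1"].notna() & out["diabetes_medication_1"].notna()
    inc[idx] = ascertain_t2d(
        out.loc[idx, "fasting_glucose_1"],
        out.loc[idx, "hba1c_1"],
        out.loc[idx, "diabetes_medication_1"],
    )
    out["incident_t2d"] = inc
    return out
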