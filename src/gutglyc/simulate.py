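"""Synthetic two-region cohort generator with planted, recoverable effects.

The generator emulates the structure the analysis assumes: ~15 provinces
nested in two regions (North/South), zero-inflated log-normal compositional
genus abundances with region-specific shifts on the log scale, covariates
drawn to match the cohort's published summary statistics, follow-up
glycaemic traits driven by planted per-SD genus effects, and a Bernoulli
incidence process with a log link so that the Poisson-regression risk-ratio
estimand equals the planted per-SD log risk ratio exactly.

Every planted parameter is emitted in a :class:`SyntheticTruth` object so
downstream estimation can be validated without access to restricted cohort
data.

Default condition set (all overridable): n = 2772 participants at baseline,
~66% retained at follow-up, 15 provinces (6 Northern, 9 Southern), 80
genera, a 25-genus signed panel, per-SD HMI log risk ratio ln(0.69) and
baseline incidence 0.067.

Notes on encoding of incident diabetes: the planted Bernoulli draw is
written into the follow-up panel so that threshold-based ascertainment
recovers it exactly - incident cases carry the diabetes-medication flag
(identification through the treatment record), while non-cases have their
follow-up glucose/HbA1c clipped just below the diagnostic thresholds (a
diabetes-free verification at follow-up). This keeps the follow-up trait
distributions intact for per-SD effect recovery, and without the clip rare
background threshold crossings unrelated to the microbiome would dilute
the planted risk ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    GenusAbundanceTable,
    COHORT_COLUMNS,
    DEMO_COVARIATES,
    FOOD_GROUPS,
)

#: Traits with freely plantable per-SD effects. HOMA-IR is derived from
#: glucose x insulin at analysis time, so its effect is implied, not planted.
PLANTABLE_TRAITS = ["fasting_glucose", "fasting_insulin", "hba1c"]

_NORTH_SHARE = 992 / 2772  # observed regional split of the emulated cohort

# Region-specific covariate calibration: (north_mean, north_sd, south_mean, south_sd)
_COVARIATE_CALIBRATION = {
    "age": (50.9, 13.2, 50.7, 12.5),
    "bmi": (24.8, 3.4, 23.7, 3.2),
    "income": (6.4, 8.6, 7.8, 11.4),
    "urbanisation_index": (69.1, 18.1, 74.5, 16.8),
    "energy": (8372.6, 2869.8, 8285.9, 2819.6),
    "physical_activity": (138.8, 141.7, 151.6, 155.5),
}

_DIET_CALIBRATION = {
    "rice": (0.2, 0.2, 0.3, 0.1),
    "wheat": (0.2, 0.2, 0.07, 0.07),
    "fruit": (0.04, 0.07, 0.04, 0.06),
    "vegetable": (0.2, 0.1, 0.3, 0.1),
    "nuts": (0.003, 0.008, 0.004, 0.01),
    "pork": (0.04, 0.04, 0.09, 0.07),
    "poultry": (0.01, 0.03, 0.02, 0.04),
    "milk": (0.02, 0.07, 0.01, 0.04),
    "egg": (0.03, 0.04, 0.02, 0.02),
    "fish": (0.02, 0.03, 0.03, 0.05),
    "vegetable_oil": (0.02, 0.02, 0.02, 0.03),
    "animal_oil": (0.0004, 0.003, 0.007, 0.01),
    # daily fibre (g): not tabulated for the emulated cohort; a typical
    # Chinese adult intake is used.
    "fibre": (10.8, 5.0, 10.8, 5.0),
}

_BASELINE_TRAITS = {  # overall mean, sd on the measured scale
    "fasting_glucose": (5.2, 0.6),
    "hba1c_percent": (5.5, 0.4),
}
_INSULIN_MEAN, _INSULIN_SD = 50.7, 44.1

# Autoregression of follow-up on baseline trait, and covariate loadings,
# all on the z scale.
_TRAIT_RHO = 0.5
_AGE_LOADING = 0.10
_BMI_LOADING = {"fasting_glucose": 0.10, "fasting_insulin": 0.15, "hba1c": 0.05}
_PROVINCE_SD = 0.05


@dataclass
class SyntheticTruth:
    """Planted parameters of one generated cohort."""

    genus_trait_betas: pd.DataFrame  # genus x PLANTABLE_TRAITS, per-SD effects
    panel: list[tuple[str, str]]  # (genus, 'favourable'|'harmful')
    hmi_log_rr: float
    baseline_incidence: float
    region_shift: pd.Series  # per-genus log-abundance shift (South - North)
    genus_occupancy: pd.Series  # per-genus carriage probability
    informative_diet_genera: dict[str, dict[str, float]]
    genus_bmi_effects: dict[str, float]
    retention: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "hmi_log_rr": self.hmi_log_rr,
            "baseline_incidence": self.baseline_incidence,
            "retention": self.retention,
            "panel": [list(e) for e in self.panel],
            "genus_trait_betas": {
                g: {t: float(v) for t, v in row.items() if v != 0.0}
                for g, row in self.genus_trait_betas.iterrows()
                if (row != 0.0).any()
            },
            "region_shift": {
                g: float(v) for g, v in self.region_shift.items() if v != 0.0
            },
            "genus_occupancy": {
                g: float(v) for g, v in self.genus_occupancy.items()
            },
            "informative_diet_genera": self.informative_diet_genera,
            "genus_bmi_effects": self.genus_bmi_effects,
        }


def _gamma_draw(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


def _lognormal_draw(rng, mean, sd, size):
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _default_truth_params(
    rng: np.random.Generator,
    genus_names: list[str],
    occupancy: np.ndarray,
    overrides: dict,
) -> dict:
    """Draw the default planted-parameter set, honouring overrides."""
    n_genera = len(genus_names)
    params: dict = {}

    panel_size = int(overrides.get("panel_size", min(25, max(2, n_genera // 3))))
    # panel genera need variable carriage, so pick mid-occupancy genera
    candidates = [g for g, p in zip(genus_names, occupancy) if 0.2 <= p <= 0.9]
    if len(candidates) < panel_size:
        candidates = [g for g, p in zip(genus_names, occupancy) if p < 0.999]
    chosen = list(rng.choice(candidates, size=min(panel_size, len(candidates)),
                             replace=False))
    n_fav = int(round(0.6 * len(chosen)))
    panel = [(g, "favourable" if i < n_fav else "harmful")
             for i, g in enumerate(chosen)]
    params["panel"] = overrides.get("panel", panel)

    betas = pd.DataFrame(0.0, index=genus_names, columns=PLANTABLE_TRAITS)
    if "genus_trait_betas" in overrides:
        user = overrides["genus_trait_betas"]
        if isinstance(user, pd.DataFrame):
            betas.loc[user.index, user.columns] = user
        else:  # nested dict genus -> trait -> beta
            for g, traits in user.items():
                for t, b in traits.items():
                    betas.loc[g, t] = b
    else:
        beta_scale = float(overrides.get("beta_scale", 0.07))
        for g, direction in params["panel"]:
            sign = -1.0 if direction == "favourable" else 1.0
            trait = rng.choice(PLANTABLE_TRAITS)
            betas.loc[g, trait] = sign * rng.uniform(0.5, 1.0) * beta_scale
    params["genus_trait_betas"] = betas

    shift = pd.Series(0.0, index=genus_names)
    if "region_shift" in overrides:
        user = overrides["region_shift"]
        if isinstance(user, pd.Series):
            shift.loc[user.index] = user
        else:
            for g, v in user.items():
                shift.loc[g] = v
    else:
        n_shift = int(overrides.get("n_region_shifted", min(12, n_genera)))
        scale = float(overrides.get("region_shift_scale", 0.8))
        shifted = rng.choice(n_genera, size=n_shift, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_shift)
        for idx, s in zip(shifted, signs):
            shift.iloc[idx] = s * scale
    params["region_shift"] = shift

    if "informative_diet_genera" in overrides:
        params["informative_diet_genera"] = overrides["informative_diet_genera"]
    elif n_genera >= 8:
        params["informative_diet_genera"] = {
            "wheat": {genus_names[5]: 0.4, genus_names[6]: -0.3},
            "vegetable": {genus_names[7]: 0.3},
        }
    else:
        params["informative_diet_genera"] = {}
    params["genus_bmi_effects"] = overrides.get("genus_bmi_effects", {})
    params["hmi_log_rr"] = float(overrides.get("hmi_log_rr", math.log(0.69)))
    params["baseline_incidence"] = float(overrides.get("baseline_incidence", 0.067))
    return params


def generate_cohort(
    n_participants: int = 2772,
    n_genera: int = 80,
    n_provinces: int = 15,
    truth: dict | None = None,
    seed: int = 0,
    retention: float = 0.66,
) -> tuple[GenusAbundanceTable, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic cohort and its planted ground truth.

    Parameters
    ----------
    n_participants, n_genera, n_provinces:
        Cohort dimensions. Provinces are partitioned into two regions
        (roughly 40% Northern); ``n_provinces >= 2`` required.
    truth:
        Optional overrides for the planted parameters. Recognised keys:
        ``hmi_log_rr``, ``baseline_incidence``, ``panel`` (list of
        (genus, direction)), ``panel_size``, ``genus_trait_betas``
        (DataFrame or nested dict), ``beta_scale``, ``region_shift``
        (Series/dict), ``n_region_shifted``, ``region_shift_scale``,
        ``informative_diet_genera``, ``genus_bmi_effects``.
    seed:
        Reproducibility seed; identical seed + config gives bit-identical
        output.
    retention:
        Probability that a participant is retained at follow-up (MCAR).

    Returns
    -------
    (GenusAbundanceTable, cohort DataFrame, SyntheticTruth)
    """
    if n_provinces < 2:
        raise ValueError("need at least 2 provinces (one per region)")
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must be in (0, 1]")
    overrides = dict(truth or {})
    rng = np.random.default_rng(seed)
    n = n_participants

    # --- geography -------------------------------------------------------
    n_north = max(1, round(n_provinces * 6 / 15))
    if n_north >= n_provinces:
        n_north = n_provinces - 1
    province_names = [f"P{i + 1:02d}" for i in range(n_provinces)]
    province_region = {
        p: ("North" if i < n_north else "South")
        for i, p in enumerate(province_names)
    }
    weights = np.array(
        [_NORTH_SHARE / n_north] * n_north
        + [(1 - _NORTH_SHARE) / (n_provinces - n_north)] * (n_provinces - n_north)
    )
    province = rng.choice(province_names, size=n, p=weights / weights.sum())
    region = np.array([province_region[p] for p in province])
    south = region == "South"

    # --- covariates ------------------------------------------------------
    cohort = pd.DataFrame(
        {"participant_id": [f"S{i + 1:05d}" for i in range(n)],
         "province": province, "region": region}
    )

    def region_normal(name, lo=None, hi=None):
        nm, ns, sm, ss = _COVARIATE_CALIBRATION[name]
        x = np.where(south, sm + ss * rng.standard_normal(n),
                     nm + ns * rng.standard_normal(n))
        return np.clip(x, lo, hi)

    cohort["age"] = region_normal("age", 18, 100)
    cohort["sex"] = np.where(rng.random(n) < 0.479, "female", "male")
    cohort["income"] = np.where(
        south,
        _lognormal_draw(rng, 7.8, 11.4, n),
        _lognormal_draw(rng, 6.4, 8.6, n),
    )
    cohort["marital"] = rng.choice(
        ["married", "single", "widowed"], size=n, p=[0.868, 0.08, 0.052]
    )
    cohort["education"] = rng.choice(
        ["middle_or_lower", "high_school", "university"],
        size=n, p=[0.650, 0.219, 0.131],
    )
    cohort["residence"] = np.where(rng.random(n) < 0.344, "urban", "rural")
    cohort["urbanisation_index"] = region_normal("urbanisation_index", 0, 100)
    cohort["energy"] = region_normal("energy", 1000, None)
    cohort["smoking"] = (rng.random(n) < 0.270).astype(int)
    cohort["alcohol"] = (rng.random(n) < 0.295).astype(int)
    pa = np.where(
        south,
        _gamma_draw(rng, 151.6, 155.5, n),
        _gamma_draw(rng, 138.8, 141.7, n),
    )
    cohort["physical_activity"] = pa

    for f in FOOD_GROUPS + ["fibre"]:
        nm, ns, sm, ss = _DIET_CALIBRATION[f]
        cohort[f] = np.where(
            south, _gamma_draw(rng, sm, ss, n), _gamma_draw(rng, nm, ns, n)
        )

    # --- genus parameters and planted truth ------------------------------
    genus_names = [f"Genus{i + 1:03d}" for i in range(n_genera)]
    # always-present core genera guarantee no all-zero rows
    n_core = min(5, max(1, n_genera // 4))
    occupancy = np.empty(n_genera)
    occupancy[:n_core] = 1.0
    occupancy[n_core:] = 0.05 + 0.93 * rng.beta(1.2, 1.8, n_genera - n_core)
    params = _default_truth_params(rng, genus_names, occupancy, overrides)

    mu = np.empty(n_genera)
    mu[:n_core] = rng.normal(-2.5, 0.5, n_core)
    mu[n_core:] = rng.normal(-5.0, 1.5, n_genera - n_core)
    sigma = rng.uniform(0.8, 1.6, n_genera)

    # --- abundances: zero-inflated log-normal, closed to sum 1 -----------
    shift = params["region_shift"].to_numpy()
    carry = rng.random((n, n_genera)) < occupancy[None, :]
    log_abund = (
        mu[None, :]
        + np.where(south, 0.5, -0.5)[:, None] * shift[None, :]
        + sigma[None, :] * rng.standard_normal((n, n_genera))
    )
    for factor, effects in params["informative_diet_genera"].items():
        fz = _zscore(cohort[factor].to_numpy())
        for g, eff in effects.items():
            log_abund[:, genus_names.index(g)] += eff * fz
    raw = np.where(carry, np.exp(log_abund), 0.0)
    closed = raw / raw.sum(axis=1, keepdims=True)
    abundance = GenusAbundanceTable(
        pd.DataFrame(closed, index=cohort["participant_id"].to_numpy(),
                     columns=genus_names)
    ).validate()
    sd = closed.std(axis=0, ddof=1)
    # a genus never carried in this draw has zero variance: its planted
    # effect cannot be expressed, so its standardized column is zero
    with np.errstate(invalid="ignore", divide="ignore"):
        genus_z = np.where(
            sd > 0, (closed - closed.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0
        )

    # optional mediation: genus acts on the trait only through BMI
    bmi_raw = rng.standard_normal(n)
    bmi_effects = params["genus_bmi_effects"]
    if bmi_effects:
        load2 = sum(e**2 for e in bmi_effects.values())
        if load2 >= 1.0:
            raise ValueError("genus_bmi_effects variance exceeds 1")
        struct = sum(
            e * genus_z[:, genus_names.index(g)] for g, e in bmi_effects.items()
        )
        bmi_z = struct + math.sqrt(1.0 - load2) * bmi_raw
    else:
        bmi_z = bmi_raw
    nm, ns, sm, ss = _COVARIATE_CALIBRATION["bmi"]
    cohort["bmi"] = np.clip(
        np.where(south, sm + ss * bmi_z, nm + ns * bmi_z), 14, 45
    )

    # --- glycaemic traits -------------------------------------------------
    age_z = _zscore(cohort["age"].to_numpy())
    bmi_zc = _zscore(cohort["bmi"].to_numpy())
    prov_effect = {p: rng.normal(0.0, _PROVINCE_SD) for p in province_names}
    prov_u = np.array([prov_effect[p] for p in province])

    betas = params["genus_trait_betas"]
    t0_z: dict[str, np.ndarray] = {}
    t1_z: dict[str, np.ndarray] = {}
    for trait in PLANTABLE_TRAITS:
        z0 = rng.standard_normal(n)
        b = betas[trait].to_numpy()
        planted = genus_z @ b
        c_bmi = _BMI_LOADING[trait]
        explained = (
            _TRAIT_RHO**2 + float(b @ b) + _AGE_LOADING**2 + c_bmi**2
            + _PROVINCE_SD**2
        )
        if explained > 0.95:
            raise ValueError(
                f"planted effects for {trait} leave residual variance "
                f"{1 - explained:.3f} < 0.05; reduce effect sizes"
            )
        z1 = (
            _TRAIT_RHO * z0
            + planted
            + _AGE_LOADING * age_z
            + c_bmi * bmi_zc
            + prov_u
            + math.sqrt(1.0 - explained) * rng.standard_normal(n)
        )
        t0_z[trait], t1_z[trait] = z0, z1

    gm, gs = _BASELINE_TRAITS["fasting_glucose"]
    hm, hs = _BASELINE_TRAITS["hba1c_percent"]
    # diabetes-free at baseline: keep baseline panel below diagnostic cuts
    cohort["fasting_glucose_0"] = np.minimum(gm + gs * t0_z["fasting_glucose"], 6.9)
    cohort["hba1c_0"] = np.minimum(
        ngsp_to_ifcc_array(hm + hs * t0_z["hba1c"]), 47.0
    )
    sigma2_i = math.log(1.0 + (_INSULIN_SD / _INSULIN_MEAN) ** 2)
    mu_i = math.log(_INSULIN_MEAN) - sigma2_i / 2.0
    s_i = math.sqrt(sigma2_i)
    cohort["fasting_insulin_0"] = np.exp(mu_i + s_i * t0_z["fasting_insulin"])

    glucose_1 = gm + gs * t1_z["fasting_glucose"]
    hba1c_1 = ngsp_to_ifcc_array(hm + hs * t1_z["hba1c"])
    insulin_1 = np.exp(mu_i + s_i * t1_z["fasting_insulin"])

    # --- incidence: log-link Bernoulli on the standardized HMI ------------
    panel = params["panel"]
    fav = np.array([d == "favourable" for _, d in panel])
    panel_idx = [genus_names.index(g) for g, _ in panel]
    carried = closed[:, panel_idx] > 0
    g_scores = np.where(fav[None, :], carried, ~carried)
    hmi = g_scores.sum(axis=1).astype(float)
    if hmi.std(ddof=1) == 0:
        raise ValueError("degenerate panel: HMI constant across cohort")
    hmi_z = _zscore(hmi)
    p_inc = params["baseline_incidence"] * np.exp(params["hmi_log_rr"] * hmi_z)
    if p_inc.max() >= 1.0:
        raise ValueError(
            f"infeasible incidence config: max per-participant probability "
            f"{p_inc.max():.3f} >= 1"
        )
    incident = rng.random(n) < p_inc

    # encode incidence in the follow-up panel (see module docstring)
    on_meds = incident
    glucose_1 = np.where(incident, glucose_1, np.minimum(glucose_1, 6.95))
    hba1c_1 = np.where(incident, hba1c_1, np.minimum(hba1c_1, 47.2))
    cohort["fasting_glucose_1"] = glucose_1
    cohort["fasting_insulin_1"] = insulin_1
    cohort["hba1c_1"] = hba1c_1
    cohort["diabetes_medication_1"] = on_meds.astype(int)
    cohort["followup_years"] = np.clip(3.0 + 0.09 * rng.standard_normal(n), 1.0, None)

    # --- MCAR loss to follow-up ------------------------------------------
    lost = rng.random(n) >= retention
    followup_cols = ["fasting_glucose_1", "fasting_insulin_1", "hba1c_1",
                     "followup_years"]
    cohort.loc[lost, followup_cols] = np.nan
    cohort.loc[lost, "diabetes_medication_1"] = np.nan

    cohort = cohort[COHORT_COLUMNS]
    truth_obj = SyntheticTruth(
        genus_trait_betas=betas,
        panel=panel,
        hmi_log_rr=params["hmi_log_rr"],
        baseline_incidence=params["baseline_incidence"],
        region_shift=params["region_shift"],
        genus_occupancy=pd.Series(occupancy, index=genus_names),
        informative_diet_genera=params["informative_diet_genera"],
        genus_bmi_effects=bmi_effects,
        retention=retention,
        seed=seed,
    )
    return abundance, cohort, truth_obj


def ngsp_to_ifcc_array(hba1c_percent: np.ndarray) -> np.ndarray:
    """Vectorized NGSP(%) -> IFCC(mmol/mol) master equation (unrounded)."""
    return (np.asarray(hba1c_percent, dtype=float) - 2.15) * 10.929


#: Cohort columns eligible for MCAR masking (never outcomes or identifiers).
MASKABLE_COLUMNS = DEMO_COVARIATES + FOOD_GROUPS + ["fibre"]


def inject_missingness(
    cohort: pd.DataFrame, rate: float, seed: int = 0
) -> pd.DataFrame:
    """Set maskable covariate cells missing independently with probability ``rate``.

    Missingness is MCAR. Outcome, identifier and geography columns are
    never masked. ``rate`` must satisfy 0 <= rate < 1.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for col in MASKABLE_COLUMNS:
        mask = rng.random(len(out)) < rate
        if out[col].dtype.kind in "iub":  # keep NaN representable
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out
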