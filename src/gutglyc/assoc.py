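"""Genus-trait association: per-region mixed models, meta-analysis, FDR, panel.

Each genus x glycaemic-trait association is estimated separately in the
Northern and Southern populations with a linear mixed-effects model (random
intercept and random genus slope by province, REML), then the two regional
estimates are pooled by DerSimonian-Laird random-effects meta-analysis.
Effects are expressed per SD: both the follow-up trait and the genus
abundance are standardized within the regional analysis sample, and the
model adjusts for the raw baseline trait plus demographic, anthropometric
and lifestyle covariates.

Genera whose pooled association reaches p < alpha for at least one trait
form the signed panel that defines the Healthy Microbiome Index: favourable
when the admitting effect is negative (lower glycaemic values), harmful
when positive. Benjamini-Hochberg q-values are reported across the whole
scan; panel admission deliberately uses the raw pooled p, with q-values
alongside for audit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .config import RunConfig
from .tables import GenusAbundanceTable, DEMO_COVARIATES, CATEGORICAL_COVARIATES, FOOD_GROUPS
from .preprocess import standardize

logger = logging.getLogger(__name__)

#: The four modelled glycaemic traits -> (baseline column, follow-up column).
TRAIT_COLUMNS = {
    "fasting_glucose": ("fasting_glucose_0", "fasting_glucose_1"),
    "fasting_insulin": ("fasting_insulin_0", "fasting_insulin_1"),
    "hba1c": ("hba1c_0", "hba1c_1"),
    "homa_ir": ("homa_ir_0", "homa_ir_1"),
}

MIN_OBSERVATIONS = 30


@dataclass
class RegionFit:
    """One regional mixed-model fit for a genus-trait pair."""

    beta: float
    se: float
    n: int
    fallback: str = "none"  # 'none' | 'intercept_only'


def _design_matrix(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Dummy-encode categorical covariates (first level dropped)."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    cat = [c for c in covariates.columns
           if covariates[c].dtype == object or str(covariates[c].dtype) == "category"]
    return pd.get_dummies(covariates, columns=cat, drop_first=True, dtype=float)


def fit_region_model(
    genus_z,
    trait_1_z,
    trait_0,
    covariates: pd.DataFrame | None,
    province,
) -> RegionFit:
    """Fixed-effect per-SD genus slope from one region's mixed model.

    Model: trait_1_z ~ genus_z + trait_0 + covariates with a random
    intercept and random genus_z slope by province (REML). If the
    random-effects fit is singular or fails to converge, the model is
    refit with a random intercept only and the fallback is recorded.
    Fewer than 30 usable observations is refused.
    """
    genus_z = np.asarray(genus_z, dtype=float)
    y = np.asarray(trait_1_z, dtype=float)
    base = np.asarray(trait_0, dtype=float)
    province = np.asarray(province)
    n = len(y)
    if n < MIN_OBSERVATIONS:
        raise ValueError(
            f"only {n} usable observations (< {MIN_OBSERVATIONS}); refusing to fit"
        )
    if len(np.unique(province)) < 2:
        raise ValueError("need >= 2 provinces for province random effects")

    parts = [np.ones(n), genus_z, base]
    names = ["const", "genus_z", "trait_0"]
    cov = _design_matrix(covariates)
    if cov is not None:
        parts.append(cov.to_numpy(dtype=float).T)
        names += list(cov.columns)
    exog = np.column_stack([p.T if p.ndim > 1 else p for p in parts])

    exog_re_full = np.column_stack([np.ones(n), genus_z])

    def _fit(exog_re, re_names):
        model = MixedLM(y, exog, groups=province, exog_re=exog_re)
        model.data.xnames = names
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            # L-BFGS can hit a numerically singular X'V^-1 X along its
            # search path with many dummy columns at small regional n;
            # fall through the optimizer cascade instead of giving up
            last_exc = None
            for method in (["lbfgs", "cg"], ["bfgs"], ["powell"]):
                try:
                    return model.fit(reml=True, method=method, maxiter=200)
                except np.linalg.LinAlgError as exc:
                    last_exc = exc
            raise last_exc

    fallback = "none"
    try:
        res = _fit(exog_re_full, ["const", "genus_z"])
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            se = float(res.bse_fe[1])
        singular = (not res.converged) or not np.isfinite(se) or se <= 0
        if not singular:
            # near-singular random-effects covariance -> unstable SEs
            cov_re = np.asarray(res.cov_re)
            eigs = np.linalg.eigvalsh(cov_re)
            if eigs.min() < -1e-8:
                singular = True
    except (np.linalg.LinAlgError, ValueError):
        singular = True
    if singular:
        fallback = "intercept_only"
        res = _fit(np.ones((n, 1)), ["const"])
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            se = float(res.bse_fe[1])
        if not np.isfinite(se) or se <= 0:
            raise RuntimeError("mixed model failed even with random intercept only")
    return RegionFit(beta=float(res.fe_params[1]), se=se, n=n, fallback=fallback)


def meta_combine(
    beta_a: float, se_a: float, beta_b: float, se_b: float
) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pooling of two stratum estimates.

    With weights w_i = 1/se_i^2: Q = sum w_i (b_i - b_fixed)^2,
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),
    then w*_i = 1/(se_i^2 + tau^2), pooled beta = sum(w* b)/sum(w*),
    pooled se = sqrt(1/sum w*), with a two-sided normal p-value.

    Returns ``(beta_pooled, se_pooled, tau2, p)``. Symmetric in the two
    strata. With only two strata tau^2 is unstable; it is reported so the
    heterogeneity can be audited.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    b = np.array([beta_a, beta_b], dtype=float)
    w = 1.0 / np.array([se_a, se_b], dtype=float) ** 2
    b_fixed = (w * b).sum() / w.sum()
    q = float((w * (b - b_fixed) ** 2).sum())
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (len(b) - 1)) / c)
    w_star = 1.0 / (1.0 / w + tau2)
    beta_pooled = float((w_star * b).sum() / w_star.sum())
    se_pooled = float(np.sqrt(1.0 / w_star.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta_pooled) / se_pooled))
    return beta_pooled, se_pooled, tau2, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def clr_transform(table: GenusAbundanceTable) -> pd.DataFrame:
    """Centred log-ratio abundances with multiplicative zero replacement.

    Zeros are replaced by half the smallest positive abundance in the
    table before row closure and the CLR (sensitivity option).
    """
    X = table.values.copy()
    positive = X[X > 0]
    if positive.size == 0:
        raise ValueError("abundance table is all zeros")
    X[X == 0] = positive.min() / 2.0
    X = X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    clr = logX - logX.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)


def _covariate_frame(df: pd.DataFrame, adjust_bmi: bool, adjust_diet: bool) -> pd.DataFrame:
    cols = [c for c in DEMO_COVARIATES if adjust_bmi or c != "bmi"]
    if adjust_diet:
        cols = cols + FOOD_GROUPS
    out = df[cols].copy()
    for c in CATEGORICAL_COVARIATES:
        if c in out.columns:
            out[c] = out[c].astype(str)
    return out


def run_association_scan(
    abundance: GenusAbundanceTable,
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
    adjust_bmi: bool = True,
    adjust_diet: bool = False,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Scan every retained genus against every glycaemic trait.

    The cohort must be preprocessed (imputed covariates, derived
    ``homa_ir_*`` columns via :func:`gutglyc.preprocess.derive_glycaemic_panel`).
    Rows with a complete follow-up trait form the analysis sample; the
    genus abundance and follow-up trait are standardized within each
    regional analysis sample. Returns one row per genus x trait with
    per-region estimates, pooled estimate, tau^2, p and BH q (family = all
    genus x trait tests of this scan variant). Genera that cannot be fit in
    one region are dropped from pooling with a logged reason.
    """
    config = config or RunConfig()
    traits = traits or list(TRAIT_COLUMNS)
    if "homa_ir" in traits and "homa_ir_1" not in cohort.columns:
        raise ValueError("cohort lacks homa_ir_* columns; run derive_glycaemic_panel")

    feature_df = clr_transform(abundance) if config.clr_transform else abundance.data
    feature_df = feature_df.reindex(cohort["participant_id"])
    if feature_df.isna().any().any():
        raise ValueError("abundance table does not cover all cohort participants")
    feature = feature_df.to_numpy(dtype=float)
    genus_names = abundance.genus_names

    records = []
    for trait in traits:
        col0, col1 = TRAIT_COLUMNS[trait]
        for genus_i, genus in enumerate(genus_names):
            fits: dict[str, RegionFit] = {}
            ok = True
            for reg in ["North", "South"]:
                mask = (
                    (cohort["region"] == reg).to_numpy()
                    & cohort[col1].notna().to_numpy()
                    & cohort[col0].notna().to_numpy()
                )
                sub = cohort.loc[mask]
                x = feature[mask, genus_i]
                try:
                    xz, _, _ = standardize(x)
                    yz, _, _ = standardize(sub[col1])
                    fits[reg] = fit_region_model(
                        xz, yz, sub[col0].to_numpy(),
                        _covariate_frame(sub, adjust_bmi, adjust_diet),
                        sub["province"].to_numpy(),
                    )
                except (ValueError, RuntimeError) as exc:
                    logger.warning(
                        "dropping %s x %s: region %s failed (%s)",
                        genus, trait, reg, exc,
                    )
                    ok = False
                    break
            if not ok:
                continue
            bn, bs = fits["North"], fits["South"]
            beta, se, tau2, p = meta_combine(bn.beta, bn.se, bs.beta, bs.se)
            records.append(
                {
                    "genus": genus, "trait": trait,
                    "beta_north": bn.beta, "se_north": bn.se, "n_north": bn.n,
                    "beta_south": bs.beta, "se_south": bs.se, "n_south": bs.n,
                    "beta_pooled": beta, "se_pooled": se, "tau2": tau2,
                    "p_pooled": p,
                    "fallback_north": bn.fallback, "fallback_south": bs.fallback,
                    "adjusted_for_bmi": adjust_bmi,
                    "adjusted_for_diet": adjust_diet,
                }
            )
    result = pd.DataFrame.from_records(records)
    if len(result):
        result["q_bh"] = bh_fdr(result["p_pooled"].to_numpy())
    return result


@dataclass
class SignedPanel:
    """Genera admitted to the Healthy Microbiome Index, with directions."""

    entries: list[tuple[str, str]]  # (genus, 'favourable' | 'harmful')
    provenance: dict[str, list[dict]] = field(default_factory=dict)

    def directions(self) -> dict[str, str]:
        return dict(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["genus", "direction"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignedPanel":
        return cls(entries=list(df[["genus", "direction"]].itertuples(index=False, name=None)))


def build_signed_panel(records: pd.DataFrame, alpha: float = 0.05) -> SignedPanel:
    """Extract the signed genus panel from an association scan.

    A genus is admitted when its pooled p is below ``alpha`` for at least
    one trait. Its direction comes from the sign of the minimum-p admitting
    association: favourable when the pooled beta is negative (lower
    glycaemic trait), harmful when positive. A genus whose admitting
    associations tie at the minimum p with conflicting signs is excluded
    with a warning.
    """
    entries: list[tuple[str, str]] = []
    provenance: dict[str, list[dict]] = {}
    for genus, grp in records.groupby("genus", sort=True):
        sig = grp[grp["p_pooled"] < alpha]
        if sig.empty:
            continue
        pmin = sig["p_pooled"].min()
        at_min = sig[sig["p_pooled"] == pmin]
        signs = set(np.sign(at_min["beta_pooled"]))
        if len(signs) > 1:
            warnings.warn(
                f"genus {genus!r} has conflicting directions at minimum p; excluded",
                stacklevel=2,
            )
            continue
        direction = "favourable" if at_min["beta_pooled"].iloc[0] < 0 else "harmful"
        entries.append((genus, direction))
        provenance[genus] = sig[["trait", "beta_pooled", "p_pooled"]].to_dict("records")
    return SignedPanel(entries=entries, provenance=provenance)
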