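"""Region classification, SHAP genus selection and diet prediction.

Geography is the dominant axis of gut microbial variation in a two-region
cohort, so three machine-learning questions are asked of the genus table:

1. Can genus abundances classify a participant's region? A gradient-boosted
   tree classifier is evaluated with a leave-one-province-out strategy -
   every fold's test set is one whole province, so no model ever sees its
   own test province (geographic leakage control). The cycle is repeated
   with distinct seeds and per-participant probabilities averaged.
2. Which genera drive that classification? Features are ranked by the mean
   absolute SHAP attribution (TreeSHAP, as implemented inside LightGBM via
   ``pred_contrib``) across all held-out samples and folds; any genus with
   mean |SHAP| above a floating-point floor is region-discriminating.
3. Do the region-discriminating genera predict dietary habit? Tenfold
   cross-validated gradient boosting, scored by Pearson correlation for
   continuous intakes and ROC AUC (with a Hanley-McNeil 95% CI) for the
   wheat-vs-rice staple preference.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .tables import GenusAbundanceTable

@contextmanager
def _quiet_predict():
    # lightgbm's sklearn wrapper records feature names even for ndarray
    # fits, making every ndarray predict warn spuriously
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        yield


#: Frozen gradient-boosting hyperparameters (library defaults, pinned).
DEFAULT_LGBM_PARAMS = {
    "n_estimators": 100,
    "num_leaves": 31,
    "learning_rate": 0.1,
    "min_child_samples": 20,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "n_jobs": 1,
    "verbosity": -1,
    "deterministic": True,
    "force_row_wise": True,
}


@dataclass
class ClassifierReport:
    """Leave-one-province-out region-classification results."""

    probabilities: pd.Series  # mean P(South) per participant across repeats
    per_repeat: pd.DataFrame  # participants x repeats
    auc: float
    n_repeats: int
    held_out_province: pd.Series  # fold definition per participant
    models: list = field(default_factory=list)  # (repeat, province, booster, row_idx)
    params: dict = field(default_factory=dict)


def _check_fold_feasibility(cohort: pd.DataFrame) -> None:
    per_region = cohort.groupby("region")["province"].nunique()
    single = per_region[per_region < 2]
    if not single.empty:
        raise ValueError(
            f"region {single.index[0]!r} has a single province; "
            "leaving it out makes the training fold single-class"
        )


def logo_region_classify(
    abundance: GenusAbundanceTable,
    cohort: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
    params: dict | None = None,
) -> ClassifierReport:
    """Classify North vs South with leave-one-province-out gradient boosting.

    Each fold trains on all provinces except one and scores the held-out
    province, so every participant is predicted exactly once per repeat by
    a model that never saw their province. The full cycle is repeated
    ``n_repeats`` times with derived seeds ``seed + r`` and probabilities
    averaged per participant. Returns the report with retained fold models
    for SHAP-based genus selection.
    """
    _check_fold_feasibility(cohort)
    X = abundance.data.reindex(cohort["participant_id"]).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("abundance table does not cover all cohort participants")
    y = (cohort["region"] == "South").to_numpy(dtype=int)
    provinces = cohort["province"].to_numpy()
    merged = {**DEFAULT_LGBM_PARAMS, **(params or {})}

    ids = cohort["participant_id"].to_numpy()
    probs = np.zeros((len(y), n_repeats))
    models = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        for prov in np.unique(provinces):
            test = provinces == prov
            train = np.flatnonzero(~test)
            # Holding out a whole province skews the training class ratio
            # towards the other region, and boosted trees leak that prior
            # into held-out scores; downsample the majority class so each
            # fold trains on equal region counts.
            pos, neg = train[y[train] == 1], train[y[train] == 0]
            m = min(len(pos), len(neg))
            train = np.sort(np.concatenate([
                rng.choice(pos, m, replace=False),
                rng.choice(neg, m, replace=False),
            ]))
            clf = lgb.LGBMClassifier(random_state=seed + r, **merged)
            clf.fit(X[train], y[train])
            with _quiet_predict():
                probs[test, r] = clf.predict_proba(X[test])[:, 1]
            models.append((r, prov, clf.booster_, np.flatnonzero(test)))
    mean_prob = probs.mean(axis=1)
    return ClassifierReport(
        probabilities=pd.Series(mean_prob, index=ids, name="p_south"),
        per_repeat=pd.DataFrame(probs, index=ids,
                                columns=[f"repeat_{r}" for r in range(n_repeats)]),
        auc=float(roc_auc_score(y, mean_prob)),
        n_repeats=n_repeats,
        held_out_province=pd.Series(provinces, index=ids, name="held_out_province"),
        models=models,
        params=merged,
    )


def select_discriminating_genera(
    report: ClassifierReport,
    abundance: GenusAbundanceTable,
    cohort: pd.DataFrame,
    tolerance: float = 1e-12,
) -> pd.DataFrame:
    """Rank genera by mean |SHAP| over all held-out samples and folds.

    Each fold model attributes its own held-out province's samples
    (TreeSHAP via LightGBM's ``pred_contrib``); attributions are pooled
    across folds and repeats. Returns a DataFrame sorted by descending
    ``mean_abs_shap`` with a ``selected`` flag (mean |SHAP| > ``tolerance``,
    a floor that only removes floating-point dust from the strict "> 0"
    rule).
    """
    X = abundance.data.reindex(cohort["participant_id"]).to_numpy(dtype=float)
    n_genera = X.shape[1]
    total = np.zeros(n_genera)
    count = 0
    for _, _, booster, rows in report.models:
        contrib = booster.predict(X[rows], pred_contrib=True)
        total += np.abs(contrib[:, :n_genera]).sum(axis=0)
        count += len(rows)
    mean_abs = total / count
    out = pd.DataFrame(
        {"genus": abundance.genus_names, "mean_abs_shap": mean_abs}
    ).sort_values("mean_abs_shap", ascending=False, ignore_index=True)
    out["selected"] = out["mean_abs_shap"] > tolerance
    return out


def _auc_ci_hanley_mcneil(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation 95% CI for an ROC AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)


def predict_diet_from_genera(
    features: pd.DataFrame,
    outcome,
    task: str = "regression",
    folds: int = 10,
    seed: int = 0,
    stratify=None,
    params: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Cross-validated prediction of a dietary factor from selected genera.

    Every participant receives exactly one out-of-fold prediction.
    ``task='regression'`` scores with the Pearson correlation between
    out-of-fold predictions and observed values; ``task='classification'``
    (binary labels) scores with ROC AUC and its Hanley-McNeil 95% CI.
    ``stratify`` (e.g. region labels) keeps fold composition balanced to
    stop a geography imbalance dominating the signal; classification
    stratifies on the label itself when not given.
    """
    if task not in {"regression", "classification"}:
        raise ValueError("task must be 'regression' or 'classification'")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome)
    if len(np.unique(y[~pd.isna(y)])) < 2:
        raise ValueError("outcome is constant; nothing to predict")
    if pd.isna(y).any():
        raise ValueError("outcome has missing values; impute first")
    merged = {**DEFAULT_LGBM_PARAMS, **(params or {})}

    if task == "classification":
        y = y.astype(int)
        strat = stratify if stratify is not None else y
    else:
        y = y.astype(float)
        strat = stratify
    if strat is not None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, np.asarray(strat))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)

    pred = np.empty(len(y), dtype=float)
    for fold_i, (train, test) in enumerate(split):
        if task == "regression":
            model = lgb.LGBMRegressor(random_state=seed + fold_i, **merged)
            model.fit(X[train], y[train])
            with _quiet_predict():
                pred[test] = model.predict(X[test])
        else:
            model = lgb.LGBMClassifier(random_state=seed + fold_i, **merged)
            model.fit(X[train], y[train])
            with _quiet_predict():
                pred[test] = model.predict_proba(X[test])[:, 1]

    if task == "regression":
        r, p = stats.pearsonr(y, pred)
        performance = {"metric": "pearson_r", "value": float(r), "p_value": float(p)}
    else:
        auc = float(roc_auc_score(y, pred))
        lo, hi = _auc_ci_hanley_mcneil(auc, int(y.sum()), int((1 - y).sum()))
        performance = {"metric": "auc", "value": auc, "ci_low": lo, "ci_high": hi}
    return pred, performance
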