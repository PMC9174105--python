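"""End-to-end orchestration: simulate -> preprocess -> ecology -> assoc ->
hmi -> region-ml -> diet-assoc, as one reproducible seeded run.

A single global seed fans out to per-stage seeds through a stable blake2s
hash of ``"{seed}:{stage}"`` (truncated to 31 bits), so any stage can be
re-run in isolation and reproduce its part of a pipeline run bit for bit.
Every stage writes its outputs into the run directory and registers them
in ``manifest.json`` together with seeds, row counts and any mixed-model
fallbacks triggered.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .tables import (
    GenusAbundanceTable,
    read_abundance_table,
    read_cohort_table,
    write_abundance_table,
    write_cohort_table,
)
from .simulate import generate_cohort
from .preprocess import (
    filter_prevalence,
    impute_missing,
    derive_glycaemic_panel,
    standardize,
)
from .ecology import bray_curtis, pcoa, permutation_test
from .assoc import run_association_scan, build_signed_panel, SignedPanel
from .hmi import compute_hmi, hmi_risk_model, subgroup_scan
from .region_ml import logo_region_classify, select_discriminating_genera, predict_diet_from_genera
from .preprocess import staple_ratio_frame
from .diet_assoc import diet_genus_scan, fibre_scan
from .tables import DEMO_COVARIATES, CATEGORICAL_COVARIATES

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "ecology", "assoc", "hmi", "region-ml", "diet-assoc"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable 31-bit per-stage seed from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig | None = None,
    outdir: str | Path = "gutglyc_run",
    abundance_path: str | Path | None = None,
    cohort_path: str | Path | None = None,
    simulate_kwargs: dict | None = None,
    ecology_max_n: int = 1500,
) -> Path:
    """Run the full analysis and return the run directory.

    Inputs are either file paths (``abundance_path`` + ``cohort_path``) or,
    when omitted, a synthetic cohort generated with ``simulate_kwargs``
    (defaults: the emulated study conditions). ``ecology_max_n`` caps the
    number of participants entering the O(n^2) dissimilarity stage
    (seeded subsample beyond that). Any stage error aborts the run with
    the stage name; outputs of completed stages persist.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.random_seed
    from . import __version__ as pkg_version

    manifest: dict = {
        "package_version": pkg_version,
        "global_seed": seed,
        "stages": {},
        "config": config.__dict__.copy(),
    }
    manifest_path = outdir / "manifest.json"

    def record(stage: str, info: dict, outputs: list[Path]) -> None:
        info = dict(info)
        info["seed"] = stage_seed(seed, stage)
        info["outputs"] = {p.name: _sha256(p) for p in outputs}
        manifest["stages"][stage] = info
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def run_stage(stage: str, fn):
        t0 = time.time()
        try:
            info, outputs = fn()
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        info["elapsed_s"] = round(time.time() - t0, 3)
        record(stage, info, outputs)

    state: dict = {}

    # ---- simulate / load -------------------------------------------------
    def _simulate():
        if abundance_path and cohort_path:
            table = read_abundance_table(abundance_path,
                                         renormalize=config.renormalize_abundance)
            cohort = read_cohort_table(cohort_path)
            truth = None
        else:
            kwargs = dict(simulate_kwargs or {})
            kwargs.setdefault("seed", stage_seed(seed, "simulate"))
            table, cohort, truth = generate_cohort(**kwargs)
        state.update(table=table, cohort=cohort, truth=truth)
        out_t = outdir / "abundance.tsv"
        out_c = outdir / "cohort.tsv"
        write_abundance_table(table, out_t)
        write_cohort_table(cohort, out_c)
        outs = [out_t, out_c]
        if truth is not None:
            out_j = outdir / "truth.json"
            out_j.write_text(json.dumps(truth.to_dict(), indent=2))
            outs.append(out_j)
        return {"n_participants": table.n_participants,
                "n_genera": table.n_genera,
                "source": "synthetic" if truth is not None else "files"}, outs

    run_stage("simulate", _simulate)

    # ---- preprocess ------------------------------------------------------
    def _preprocess():
        table, dropped = filter_prevalence(state["table"], config.prevalence_threshold)
        cohort = impute_missing(state["cohort"])
        cohort = derive_glycaemic_panel(cohort, config.insulin_conversion)
        state.update(table=table, cohort=cohort)
        out_t = outdir / "abundance.filtered.tsv"
        out_c = outdir / "cohort.preprocessed.tsv"
        write_abundance_table(table, out_t)
        write_cohort_table(cohort, out_c)
        return {"n_genera_kept": table.n_genera, "n_genera_dropped": len(dropped),
                "dropped": dropped}, [out_t, out_c]

    run_stage("preprocess", _preprocess)

    # ---- ecology ---------------------------------------------------------
    def _ecology():
        table, cohort = state["table"], state["cohort"]
        s = stage_seed(seed, "ecology")
        if table.n_participants > ecology_max_n:
            rng = np.random.default_rng(s)
            keep = np.sort(rng.choice(table.n_participants, ecology_max_n, replace=False))
            sub = GenusAbundanceTable(table.data.iloc[keep])
            groups = cohort["region"].to_numpy()[keep]
        else:
            sub, groups = table, cohort["region"].to_numpy()
        d = bray_curtis(sub.renormalized())
        coords, explained = pcoa(d, k=2)
        f_stat, p = permutation_test(d, groups, config.n_permutations, seed=s)
        out_o = outdir / "pcoa.tsv"
        with open(out_o, "w") as fh:
            fh.write("# explained: " + ", ".join(f"{e:.4f}" for e in explained) + "\n")
            coords.to_csv(fh, sep="\t", index_label="participant_id")
        return {"pseudo_F": f_stat, "p_value": p, "n_used": d.n,
                "explained": [float(e) for e in explained]}, [out_o]

    run_stage("ecology", _ecology)

    # ---- assoc -----------------------------------------------------------
    def _assoc():
        records = run_association_scan(state["table"], state["cohort"], config)
        panel = build_signed_panel(records, config.alpha)
        state.update(records=records, panel=panel)
        out_r = outdir / "associations.tsv"
        out_p = outdir / "signed_panel.tsv"
        records.to_csv(out_r, sep="\t", index=False)
        panel.to_frame().to_csv(out_p, sep="\t", index=False)
        fallbacks = int((records["fallback_north"] != "none").sum()
                        + (records["fallback_south"] != "none").sum())
        return {"n_tests": len(records), "panel_size": len(panel.entries),
                "n_fallbacks": fallbacks}, [out_r, out_p]

    run_stage("assoc", _assoc)

    # ---- hmi -------------------------------------------------------------
    def _hmi():
        cohort = state["cohort"]
        panel: SignedPanel = state["panel"]
        followed = cohort["incident_t2d"].notna()
        if not panel.entries:
            raise ValueError("signed panel is empty; cannot score the HMI")
        sub_table = GenusAbundanceTable(
            state["table"].data.loc[cohort.loc[followed, "participant_id"]]
        )
        scores = compute_hmi(sub_table, panel, config.carriage_threshold)
        sub = cohort.loc[followed]
        cov = sub[DEMO_COVARIATES].copy()
        for c in CATEGORICAL_COVARIATES:
            cov[c] = cov[c].astype(str)
        overall = hmi_risk_model(
            scores["hmi_z"], sub["incident_t2d"], cov,
            robust=config.robust_poisson_se,
        )
        strata = subgroup_scan(
            sub.reset_index(drop=True), scores["hmi_z"].to_numpy(),
            sub["incident_t2d"].to_numpy(),
            age_cutpoint=config.age_cutpoint, bmi_cutpoint=config.bmi_cutpoint,
            robust=config.robust_poisson_se,
        )
        rows = [overall] + strata
        est = pd.DataFrame(
            [{"subgroup": e.subgroup, "rr": e.rr, "ci_low": e.ci_low,
              "ci_high": e.ci_high, "n": e.n, "n_events": e.n_events}
             for e in rows]
        )
        out_s = outdir / "hmi_scores.tsv"
        out_e = outdir / "hmi_risk.tsv"
        scores.to_csv(out_s, sep="\t", index_label="participant_id")
        est.to_csv(out_e, sep="\t", index=False)
        state["hmi_scores"] = scores
        return {"overall_rr": overall.rr, "ci": [overall.ci_low, overall.ci_high],
                "n": overall.n, "n_events": overall.n_events}, [out_s, out_e]

    run_stage("hmi", _hmi)

    # ---- region-ml -------------------------------------------------------
    def _region_ml():
        table, cohort = state["table"], state["cohort"]
        s = stage_seed(seed, "region-ml")
        report = logo_region_classify(
            table, cohort, n_repeats=config.n_classifier_repeats, seed=s,
            params=config.lgbm_params,
        )
        disc = select_discriminating_genera(report, table, cohort)
        selected = disc.loc[disc["selected"], "genus"].tolist()
        feats = table.data.reindex(cohort["participant_id"])[selected]
        staple = staple_ratio_frame(cohort)
        labelled = staple["staple_preference"].notna().to_numpy()
        y = (staple["staple_preference"] == "wheat").to_numpy()[labelled]
        _, perf = predict_diet_from_genera(
            feats.iloc[labelled], y.astype(int), task="classification",
            folds=config.cv_folds, seed=s,
        )
        out_p = outdir / "region_probabilities.tsv"
        out_g = outdir / "discriminating_genera.tsv"
        report.probabilities.to_frame().to_csv(out_p, sep="\t",
                                               index_label="participant_id")
        disc.to_csv(out_g, sep="\t", index=False)
        return {"region_auc": report.auc, "n_selected": len(selected),
                "staple_auc": perf["value"],
                "staple_auc_ci": [perf["ci_low"], perf["ci_high"]]}, [out_p, out_g]

    run_stage("region-ml", _region_ml)

    # ---- diet-assoc ------------------------------------------------------
    def _diet_assoc():
        table, cohort = state["table"], state["cohort"]
        panel: SignedPanel = state["panel"]
        data = table.data.reindex(cohort["participant_id"])
        outcomes = pd.DataFrame(index=cohort.index)
        for genus, _ in panel.entries:
            outcomes[genus], _, _ = standardize(data[genus].rename(genus))
        hmi_all = compute_hmi(GenusAbundanceTable(data), panel,
                              config.carriage_threshold)
        outcomes["HMI"] = hmi_all["hmi_z"].to_numpy()
        scan = diet_genus_scan(cohort, outcomes, fdr_q=config.fdr_q)
        fib = fibre_scan(cohort, outcomes, fdr_q=config.fdr_q)
        out_d = outdir / "diet_associations.tsv"
        out_f = outdir / "fibre_associations.tsv"
        scan.to_csv(out_d, sep="\t", index=False)
        fib.to_csv(out_f, sep="\t", index=False)
        n_sig = int(scan["significant"].sum())
        return {"n_pairs_tested": len(scan), "n_significant": n_sig}, [out_d, out_f]

    run_stage("diet-assoc", _diet_assoc)

    return outdir
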