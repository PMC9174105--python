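import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutglyc import (
    carries,
    compute_hmi,
    hmi_risk_model,
    subgroup_scan,
    generate_cohort,
)
from gutglyc.assoc import SignedPanel
from gutglyc.preprocess import derive_glycaemic_panel
from gutglyc.tables import GenusAbundanceTable, DEMO_COVARIATES, CATEGORICAL_COVARIATES
from conftest import make_table


def _panel(*entries):
    return SignedPanel(entries=list(entries))


class TestCarries:
    def test_detection_boundary(self):
        assert carries(0.0) == 0
        assert carries(1e-6) == 1

    def test_configurable_threshold(self):
        assert carries(5e-5, threshold=1e-4) == 0
        assert carries(2e-4, threshold=1e-4) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            carries(-0.1)


class TestComputeHmi:
    def test_favourable_carried_and_harmful_absent_both_score(self):
        table = make_table([[0.2, 0.0]], genera=["A", "B"])
        panel = _panel(("A", "favourable"), ("B", "harmful"))
        assert compute_hmi(table, panel)["hmi"].iloc[0] == 2
        table2 = make_table([[0.0, 0.2]], genera=["A", "B"])
        assert compute_hmi(table2, panel)["hmi"].iloc[0] == 0

    def test_maximum_attained_on_full_panel(self):
        genera = [f"g{i}" for i in range(25)]
        fav = genera[:15]
        X = np.zeros((2, 25))
        X[0, :15] = 0.9 / 15  # carries all favourable, none harmful
        X[1, 15:] = 0.9 / 10  # the exact complement
        table = make_table(X, genera=genera)
        panel = _panel(*[(g, "favourable") for g in fav],
                       *[(g, "harmful") for g in genera[15:]])
        scores = compute_hmi(table, panel)["hmi"]
        assert scores.iloc[0] == 25 and scores.iloc[1] == 0

    def test_panel_genus_absent_from_table_counts_as_not_carried(self):
        table = make_table([[0.5], [0.4]], genera=["A"])
        panel = _panel(("A", "favourable"), ("missing", "harmful"))
        assert (compute_hmi(table, panel)["hmi"] == 2).all()

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            compute_hmi(make_table([[1.0]]), SignedPanel(entries=[]))

    def test_adding_a_satisfied_favourable_genus_adds_exactly_one(self):
        X = np.random.default_rng(0).random((6, 3)) / 3
        table = make_table(X, genera=["a", "b", "c"])
        p1 = _panel(("a", "favourable"))
        p2 = _panel(("a", "favourable"), ("b", "favourable"))
        h1 = compute_hmi(table, p1)["hmi"]
        h2 = compute_hmi(table, p2)["hmi"]
        assert ((h2 - h1) == 1).all()  # b is carried by every row here

    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    @settings(max_examples=40, deadline=None)
    def test_reversing_directions_complements_the_score(self, bits1, bits2):
        m = 12
        rows = np.array([
            [(bits1 >> j) & 1 for j in range(m)],
            [(bits2 >> j) & 1 for j in range(m)],
            [1] * m,
        ], dtype=float) * 0.05
        genera = [f"g{j}" for j in range(m)]
        table = make_table(rows, genera=genera)
        directions = ["favourable" if j % 3 else "harmful" for j in range(m)]
        panel = _panel(*zip(genera, directions))
        flipped = _panel(*zip(
            genera,
            ["harmful" if d == "favourable" else "favourable" for d in directions],
        ))
        h = compute_hmi(table, panel)["hmi"]
        hf = compute_hmi(table, flipped)["hmi"]
        assert ((h + hf) == m).all()
        assert ((0 <= h) & (h <= m)).all()


class TestRiskModel:
    def test_two_level_saturated_identity(self):
        """With a balanced two-level score the Poisson MLE has a closed
        form: RR per unit = sqrt of the rate ratio between levels."""
        rng = np.random.default_rng(0)
        z = np.repeat([-1.0, 1.0], 500)
        p = np.where(z > 0, 0.05, 0.15)
        y = (rng.random(1000) < p).astype(float)
        est = hmi_risk_model(z, y, covariates=None, robust=False)
        r_hi = y[z > 0].mean()
        r_lo = y[z < 0].mean()
        assert est.rr == pytest.approx(np.sqrt(r_hi / r_lo), abs=1e-10)

    def test_zero_and_rare_events_rejected(self):
        z = np.random.default_rng(1).standard_normal(200)
        with pytest.raises(ValueError, match="no incident events"):
            hmi_risk_model(z, np.zeros(200))
        y = np.zeros(200)
        y[:5] = 1
        with pytest.raises(ValueError, match="events"):
            hmi_risk_model(z, y)

    def test_non_binary_outcome_rejected(self):
        z = np.zeros(100)
        with pytest.raises(ValueError, match="binary"):
            hmi_risk_model(z, np.full(100, 2.0))

    def test_planted_rr_recovered_with_covariate_adjustment(self):
        tab, coh, truth = generate_cohort(
            n_participants=20000, seed=12,
            truth={"hmi_log_rr": math.log(0.69), "baseline_incidence": 0.067},
        )
        coh = derive_glycaemic_panel(coh)
        sub = coh.loc[coh["incident_t2d"].notna()]
        panel = SignedPanel(entries=truth.panel)
        scores = compute_hmi(
            GenusAbundanceTable(tab.data.loc[sub["participant_id"]]), panel
        )
        cov = sub[DEMO_COVARIATES].copy()
        for c in CATEGORICAL_COVARIATES:
            cov[c] = cov[c].astype(str)
        est = hmi_risk_model(scores["hmi_z"], sub["incident_t2d"], cov)
        assert est.ci_low <= 0.69 <= est.ci_high
        assert est.rr == pytest.approx(0.69, abs=0.06)

    def test_rr_invariant_to_covariate_column_order(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(2000)
        y = (rng.random(2000) < 0.08 * np.exp(-0.3 * z)).astype(float)
        cov = pd.DataFrame({"a": rng.standard_normal(2000),
                            "b": rng.standard_normal(2000)})
        e1 = hmi_risk_model(z, y, cov)
        e2 = hmi_risk_model(z, y, cov[["b", "a"]])
        assert e1.rr == pytest.approx(e2.rr, rel=1e-10)


class TestSubgroups:
    def test_homogeneous_effect_covered_in_both_regions(self):
        tab, coh, truth = generate_cohort(
            n_participants=20000, seed=21,
            truth={"hmi_log_rr": math.log(0.69), "baseline_incidence": 0.067},
        )
        coh = derive_glycaemic_panel(coh)
        sub = coh.loc[coh["incident_t2d"].notna()].reset_index(drop=True)
        panel = SignedPanel(entries=truth.panel)
        scores = compute_hmi(
            GenusAbundanceTable(tab.data.loc[sub["participant_id"]]), panel
        )
        estimates = subgroup_scan(sub, scores["hmi_z"].to_numpy(),
                                  sub["incident_t2d"].to_numpy())
        by_name = {e.subgroup: e for e in estimates}
        for reg in ["region=North", "region=South"]:
            assert by_name[reg].ci_low <= 0.69 <= by_name[reg].ci_high
        # every default stratification dimension appears
        dims = {e.subgroup.split("=")[0] for e in estimates}
        assert dims == {"region", "age_group", "sex", "bmi_level", "urbanisation"}

    def test_stratum_without_events_skipped_with_log(self, caplog, small_cohort):
        _, cohort, _ = small_cohort
        sub = cohort.loc[cohort["incident_t2d"].notna()].reset_index(drop=True)
        incident = np.zeros(len(sub))
        north = (sub["region"] == "North").to_numpy()
        rng = np.random.default_rng(0)
        incident[(~north) & (rng.random(len(sub)) < 0.2)] = 1  # South only
        z = rng.standard_normal(len(sub))
        import logging

        with caplog.at_level(logging.WARNING, logger="gutglyc.hmi"):
            estimates = subgroup_scan(sub, z, incident)
        names = {e.subgroup for e in estimates}
        assert "region=North" not in names
        assert any("region=North" in r.message for r in caplog.records)
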