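import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gutglyc import (
    generate_cohort,
    fit_region_model,
    meta_combine,
    bh_fdr,
    run_association_scan,
    build_signed_panel,
)
from gutglyc.assoc import _covariate_frame
from gutglyc.preprocess import derive_glycaemic_panel, standardize


def brute_force_bh(p):
    """Direct step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestMetaCombine:
    def test_homogeneous_reduces_to_fixed_effect(self):
        beta, se, tau2, p = meta_combine(2.0, 1.0, 2.0, 1.0)
        assert beta == pytest.approx(2.0)
        assert tau2 == 0.0
        assert se == pytest.approx(1 / np.sqrt(2))

    def test_heterogeneous_closed_form(self):
        # w=(1,1), fixed beta 2, Q=2, C=1 -> tau2=1, w*=(1/2,1/2), se=1
        beta, se, tau2, p = meta_combine(1.0, 1.0, 3.0, 1.0)
        assert (beta, tau2) == (pytest.approx(2.0), pytest.approx(1.0))
        assert se == pytest.approx(1.0)

    def test_symmetric_in_strata(self):
        assert meta_combine(0.5, 0.2, -0.1, 0.4) == meta_combine(-0.1, 0.4, 0.5, 0.2)

    def test_zero_tau2_equals_inverse_variance_pooling(self):
        b1, s1, b2, s2 = 0.30, 0.10, 0.32, 0.15
        beta, se, tau2, _ = meta_combine(b1, s1, b2, s2)
        assert tau2 == 0.0
        w1, w2 = 1 / s1**2, 1 / s2**2
        assert beta == pytest.approx((w1 * b1 + w2 * b2) / (w1 + w2))
        assert se == pytest.approx(np.sqrt(1 / (w1 + w2)))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_combine(1.0, 0.0, 1.0, 1.0)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.1), (0.01, 0.1)),
            ((0.5,), (0.5,)),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.2, 1.3])


def _region_frame(n=600, seed=0, beta=0.0, prov_sd=0.0, n_prov=6):
    """Direct single-region construction with known structure."""
    rng = np.random.default_rng(seed)
    prov = rng.integers(0, n_prov, n)
    u = rng.normal(0, prov_sd, n_prov)
    x = rng.standard_normal(n)
    base = rng.standard_normal(n)
    y = beta * x + 0.4 * base + u[prov] + rng.standard_normal(n) * 0.8
    return x, y, base, np.array([f"P{p}" for p in prov])


class TestFitRegionModel:
    def test_reduces_to_ols_without_province_variance(self):
        x, y, base, prov = _region_frame(n=800, seed=2, beta=0.25, prov_sd=0.0)
        fit = fit_region_model(x, y, base, None, prov)
        ols = sm.OLS(y, np.column_stack([np.ones_like(x), x, base])).fit()
        assert fit.beta == pytest.approx(ols.params[1], abs=1e-3)

    def test_null_genus_rarely_significant(self):
        hits = 0
        for seed in range(20):
            x, y, base, prov = _region_frame(n=400, seed=seed, beta=0.0, prov_sd=0.3)
            fit = fit_region_model(x, y, base, None, prov)
            hits += abs(fit.beta) > 3 * fit.se
        assert hits <= 1

    def test_too_few_observations_refused(self):
        x, y, base, prov = _region_frame(n=20, seed=0)
        with pytest.raises(ValueError, match="observations"):
            fit_region_model(x, y, base, None, prov)

    def test_single_province_refused(self):
        x, y, base, _ = _region_frame(n=100, seed=0)
        with pytest.raises(ValueError, match="province"):
            fit_region_model(x, y, base, None, np.repeat("P0", 100))

    def test_planted_beta_recovery_with_covariates(self):
        """Within-region per-SD effect is recovered through the full
        generator -> standardize -> mixed-model path."""
        betas = {"Genus020": {"fasting_glucose": 0.10}}
        covered = 0
        for seed in range(12):
            tab, coh, _ = generate_cohort(
                n_participants=2000, n_provinces=8, seed=seed,
                truth={"genus_trait_betas": betas, "hmi_log_rr": 0.0,
                       "panel_size": 8},
            )
            coh = derive_glycaemic_panel(coh)
            m = coh["fasting_glucose_1"].notna()
            sub = coh.loc[m]
            xz, _, _ = standardize(tab.data["Genus020"].to_numpy()[m.to_numpy()])
            yz, _, _ = standardize(sub["fasting_glucose_1"])
            fit = fit_region_model(
                xz, yz, sub["fasting_glucose_0"].to_numpy(),
                _covariate_frame(sub, True, False), sub["province"].to_numpy(),
            )
            covered += (fit.beta - 1.96 * fit.se
                        <= 0.10 <= fit.beta + 1.96 * fit.se)
        assert covered >= 10  # nominal 95% CI coverage over 12 seeds

    def test_bmi_mediated_effect_appears_only_without_bmi_adjustment(self):
        """A genus acting on the trait only through BMI is detected by the
        no-BMI variant and attenuated by BMI adjustment."""
        tab, coh, _ = generate_cohort(
            n_participants=4000, n_provinces=8, seed=33,
            truth={"genus_trait_betas": {}, "hmi_log_rr": 0.0,
                   "genus_bmi_effects": {"Genus010": 0.8}, "panel_size": 8},
        )
        coh = derive_glycaemic_panel(coh)
        m = coh["fasting_insulin_1"].notna()
        sub = coh.loc[m]
        xz, _, _ = standardize(tab.data["Genus010"].to_numpy()[m.to_numpy()])
        yz, _, _ = standardize(np.log(sub["fasting_insulin_1"]))
        base = np.log(sub["fasting_insulin_0"]).to_numpy()
        prov = sub["province"].to_numpy()
        without = fit_region_model(
            xz, yz, base, _covariate_frame(sub, adjust_bmi=False,
                                           adjust_diet=False), prov)
        with_bmi = fit_region_model(
            xz, yz, base, _covariate_frame(sub, adjust_bmi=True,
                                           adjust_diet=False), prov)
        assert abs(without.beta) > 2 * without.se
        assert abs(with_bmi.beta) < 0.5 * abs(without.beta)


class TestScanAndPanel:
    def test_scan_schema_and_q_monotonicity(self, small_cohort):
        table, cohort, _ = small_cohort
        sub = table.data.iloc[:, :6]
        from gutglyc.tables import GenusAbundanceTable

        records = run_association_scan(
            GenusAbundanceTable(sub), cohort, traits=["fasting_glucose", "hba1c"]
        )
        assert len(records) == 6 * 2
        assert (records["q_bh"] >= records["p_pooled"] - 1e-15).all()
        assert (records["se_pooled"] > 0).all()
        assert records["adjusted_for_bmi"].all()
        assert not records["adjusted_for_diet"].any()

    def test_effects_invariant_to_affine_abundance_rescaling(self):
        # standardization absorbs any affine map of the raw abundance
        x = np.random.default_rng(0).random(500)
        z1, _, _ = standardize(x)
        z2, _, _ = standardize(1000.0 * x + 3.0)
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["genus", "trait", "beta_pooled", "p_pooled"]
        )

    def test_panel_admission_direction_and_exclusion(self):
        records = self._records([
            ("A", "fasting_glucose", -0.10, 0.01),   # favourable
            ("A", "hba1c", 0.02, 0.50),
            ("B", "fasting_glucose", 0.10, 0.001),   # harmful, two traits
            ("B", "fasting_insulin", 0.08, 0.04),
            ("C", "fasting_glucose", 0.05, 0.20),    # never significant
        ])
        panel = build_signed_panel(records, alpha=0.05)
        assert panel.directions() == {"A": "favourable", "B": "harmful"}
        assert {r["trait"] for r in panel.provenance["B"]} == \
            {"fasting_glucose", "fasting_insulin"}

    def test_conflicting_direction_at_tied_minimum_p_excluded(self):
        records = self._records([
            ("X", "fasting_glucose", -0.1, 0.01),
            ("X", "hba1c", 0.1, 0.01),
        ])
        with pytest.warns(UserWarning, match="conflicting"):
            panel = build_signed_panel(records, alpha=0.05)
        assert panel.entries == []
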