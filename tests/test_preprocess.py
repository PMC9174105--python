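import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutglyc import (
    apply_exclusions,
    filter_prevalence,
    impute_missing,
    compute_homa_ir,
    ngsp_to_ifcc,
    ascertain_t2d,
    standardize,
    staple_ratio,
    generate_cohort,
    inject_missingness,
)
from gutglyc.preprocess import staple_ratio_frame, CONTINUOUS_IMPUTABLE
from conftest import make_table


def _flags(n, antibiotics=(), intestinal=(), t2d=()):
    f = pd.DataFrame({
        "antibiotics": np.zeros(n, bool),
        "intestinal_disease": np.zeros(n, bool),
        "prevalent_t2d": np.zeros(n, bool),
    })
    f.loc[list(antibiotics), "antibiotics"] = True
    f.loc[list(intestinal), "intestinal_disease"] = True
    f.loc[list(t2d), "prevalent_t2d"] = True
    return f


class TestExclusions:
    def test_disjoint_cascade_accounting(self):
        n = 3248
        cohort = pd.DataFrame({"participant_id": [f"p{i}" for i in range(n)]})
        flags = _flags(n, antibiotics=range(0, 71),
                       intestinal=range(71, 97), t2d=range(97, 476))
        kept, report = apply_exclusions(cohort, flags)
        assert (report.n_excluded_antibiotics,
                report.n_excluded_intestinal_disease,
                report.n_excluded_prevalent_t2d) == (71, 26, 379)
        assert report.n_retained == len(kept) == 2772

    def test_no_flags_is_identity(self):
        cohort = pd.DataFrame({"participant_id": list("abc")})
        kept, report = apply_exclusions(cohort, _flags(3))
        assert report.n_retained == 3
        pd.testing.assert_frame_equal(kept, cohort)

    def test_double_flagged_counted_once_at_first_criterion(self):
        cohort = pd.DataFrame({"participant_id": list("abcd")})
        flags = _flags(4, antibiotics=[0], intestinal=[0, 1], t2d=[1, 2])
        kept, report = apply_exclusions(cohort, flags)
        assert report.n_excluded_antibiotics == 1
        assert report.n_excluded_intestinal_disease == 1  # b only
        assert report.n_excluded_prevalent_t2d == 1  # c only
        assert report.n_retained == 1
        assert list(kept["participant_id"]) == ["d"]


class TestPrevalenceFilter:
    def test_boundary_is_inclusive(self):
        X = np.zeros((100, 1))
        X[:10, 0] = 0.5  # exactly 10% prevalence
        kept, dropped = filter_prevalence(make_table(X), 0.10)
        assert kept.n_genera == 1 and dropped == []

    def test_fixed_prevalence_grid(self):
        n = 100
        prevs = [0.0, 0.05, 0.09, 0.10, 0.5, 1.0]
        X = np.zeros((n, len(prevs)))
        for j, p in enumerate(prevs):
            X[: int(p * n), j] = 0.1
        kept, dropped = filter_prevalence(make_table(X), 0.10)
        assert kept.n_genera == 3
        assert set(dropped) == {"g0", "g1", "g2"}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.random((30, 8)) * (rng.random((30, 8)) < 0.4)
            X = X / np.maximum(X.sum(axis=1, keepdims=True), 1.0)
            table = make_table(X)
            kept, dropped = filter_prevalence(table, 0.25)
            expected = [
                g for j, g in enumerate(table.genus_names)
                if sum(1 for i in range(30) if X[i, j] > 0) / 30 >= 0.25
            ]
            assert kept.genus_names == expected
            assert set(dropped) == set(table.genus_names) - set(expected)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_prevalence(make_table(np.empty((0, 0))), 0.1)


class TestImputation:
    def test_continuous_filled_with_region_mean(self, small_cohort):
        _, cohort, _ = small_cohort
        masked = inject_missingness(cohort, 0.15, seed=4)
        filled = impute_missing(masked)
        assert not filled["bmi"].isna().any()
        for reg in ["North", "South"]:
            obs_mean = masked.loc[masked["region"] == reg, "bmi"].mean()
            was_na = masked["bmi"].isna() & (masked["region"] == reg)
            assert np.allclose(filled.loc[was_na, "bmi"], obs_mean)
        # observed cells untouched
        obs = masked["bmi"].notna()
        np.testing.assert_array_equal(filled.loc[obs, "bmi"], masked.loc[obs, "bmi"])

    def test_no_missing_is_identity(self, small_cohort):
        _, cohort, _ = small_cohort
        pd.testing.assert_frame_equal(impute_missing(cohort), cohort)

    def test_categorical_mode_with_lexicographic_tie(self):
        df = pd.DataFrame({
            "region": ["North"] * 5,
            "sex": ["b", "b", "a", "a", None],
        })
        for col in CONTINUOUS_IMPUTABLE:
            df[col] = 1.0
        for col in ["marital", "education", "residence", "alcohol", "smoking"]:
            df[col] = "x"
        out = impute_missing(df)
        assert out.loc[4, "sex"] == "a"

    def test_all_missing_region_column_is_error(self, small_cohort):
        _, cohort, _ = small_cohort
        broken = cohort.copy()
        broken.loc[broken["region"] == "North", "bmi"] = np.nan
        with pytest.raises(ValueError, match="bmi.*North"):
            impute_missing(broken)


class TestDerivedVariables:
    def test_homa_ir_mean_panel_worked_example(self):
        assert round(compute_homa_ir(5.2, 50.7, 6.945), 1) == 1.7

    def test_homa_ir_hand_arithmetic(self):
        # 7.0 mmol/l with 10 uU/ml equivalent (69.45 pmol/l): 7*10/22.5
        assert compute_homa_ir(7.0, 69.45, 6.945) == pytest.approx(3.1111, abs=1e-3)

    def test_homa_ir_zero_insulin_and_negative_rejection(self):
        assert compute_homa_ir(5.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            compute_homa_ir(-1.0, 10.0)

    @pytest.mark.parametrize("pct,expected", [(6.5, 47.5), (5.5, 36.6), (2.15, 0.0)])
    def test_ngsp_to_ifcc_paired_values(self, pct, expected):
        assert ngsp_to_ifcc(pct) == expected

    @pytest.mark.parametrize(
        "glucose,hba1c,meds,expected",
        [
            (7.0, 30.0, 0, 1),   # glucose threshold inclusive
            (5.0, 47.5, 0, 1),   # hba1c threshold inclusive
            (5.0, 36.0, 1, 1),   # medication alone suffices
            (5.0, 36.0, 0, 0),
            (6.999, 47.499, 0, 0),
        ],
    )
    def test_ascertainment_thresholds(self, glucose, hba1c, meds, expected):
        assert ascertain_t2d(glucose, hba1c, meds) == expected

    @given(
        g=st.floats(0, 15), h=st.floats(0, 100),
        dg=st.floats(0, 5), dh=st.floats(0, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_ascertainment_monotone_in_continuous_inputs(self, g, h, dg, dh):
        assert ascertain_t2d(g + dg, h + dh, 0) >= ascertain_t2d(g, h, 0)

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError):
            ascertain_t2d(np.nan, 36.0, 0)


class TestStandardize:
    def test_simple_vector(self):
        z, mean, sd = standardize(np.array([1.0, 2.0, 3.0]))
        assert (mean, sd) == (2.0, 1.0)
        np.testing.assert_allclose(z, [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 2, 100)
        z1, _, _ = standardize(x)
        z2, m, s = standardize(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        assert abs(m) < 1e-12 and abs(s - 1) < 1e-12

    def test_scaling_constants_recover_planted_moments(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5.0, 2.0, 10_000)
        _, mean, sd = standardize(x)
        assert abs(mean - 5.0) < 3 * 2.0 / 100
        assert abs(sd - 2.0) < 3 * 2.0 / 100

    def test_constant_column_is_named_in_error(self):
        with pytest.raises(ValueError, match="bmi"):
            standardize(pd.Series([1.0, 1.0, 1.0], name="bmi"))


class TestStapleRatio:
    @pytest.mark.parametrize(
        "wheat,rice,ratio,label",
        [
            (0.2, 0.2, 1.0, "wheat"),   # ratio >= 1 is wheat preference
            (0.0, 0.3, 0.0, "rice"),
            (0.3, 0.0, np.inf, "wheat"),
            (0.1, 0.4, 0.25, "rice"),
        ],
    )
    def test_labelling(self, wheat, rice, ratio, label):
        r, lab = staple_ratio(wheat, rice)
        assert lab == label
        assert r == ratio

    def test_both_zero_flagged_undefined(self):
        r, lab = staple_ratio(0.0, 0.0)
        assert lab is None and np.isnan(r)

    def test_frame_version_matches_scalar(self):
        df = pd.DataFrame({"wheat": [0.2, 0.0, 0.3, 0.0],
                           "rice": [0.2, 0.3, 0.0, 0.0]})
        out = staple_ratio_frame(df)
        assert list(out["staple_preference"].fillna("NA")) == \
            ["wheat", "rice", "wheat", "NA"]
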