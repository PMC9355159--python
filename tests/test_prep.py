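import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lifescore as ls
from lifescore.codebook import CodebookError
from lifescore.prep import SchemaError


class TestEgfrMdrd:
    def test_reference_value(self):
        # Scr 88.4 umol/L = 1.0 mg/dL, age 50, male, non-Black:
        # 175 * 50^-0.203 = 79.10
        got = ls.egfr_mdrd(88.4, 50, "male")
        assert got == pytest.approx(175.0 * 50 ** -0.203, rel=1e-12)
        assert got == pytest.approx(79.10, abs=0.01)

    def test_female_multiplier_exact(self):
        m = ls.egfr_mdrd(100.0, 60, "male")
        f = ls.egfr_mdrd(100.0, 60, "female")
        assert f == pytest.approx(0.742 * m, rel=1e-12)

    def test_black_multiplier_exact(self):
        base = ls.egfr_mdrd(100.0, 60, "male")
        black = ls.egfr_mdrd(100.0, 60, "male", black_ethnicity=True)
        assert black == pytest.approx(1.212 * base, rel=1e-12)

    def test_creatinine_power_law(self):
        one = ls.egfr_mdrd(88.4, 50, "male")
        two = ls.egfr_mdrd(176.8, 50, "male")
        assert two == pytest.approx(one * 2 ** -1.154, rel=1e-12)

    @pytest.mark.parametrize("scr,age", [(0.0, 50), (-5, 50), (88.4, 0), (88.4, -1)])
    def test_domain_errors(self, scr, age):
        with pytest.raises(ValueError):
            ls.egfr_mdrd(scr, age, "male")

    @given(
        scr=st.floats(30, 300),
        delta=st.floats(1.0, 50.0),
        age=st.floats(40, 69),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_creatinine_and_age(self, scr, delta, age):
        assert ls.egfr_mdrd(scr + delta, age, "male") < ls.egfr_mdrd(scr, age, "male")
        assert ls.egfr_mdrd(scr, age + 1.0, "male") < ls.egfr_mdrd(scr, age, "male")


class TestMetMinutes:
    def test_walking_arithmetic(self):
        out = ls.met_minutes(walking_min_per_day=60, walking_days_per_week=7)
        assert out["walking"] == pytest.approx(3.3 * 60 * 7)  # 1386
        assert out["moderate"] == 0 and out["vigorous"] == 0

    def test_all_zero(self):
        out = ls.met_minutes()
        assert all(v == 0 for v in out.values())

    def test_high_walking_crosses_2000_stratum(self, codebook37):
        out = ls.met_minutes(walking_min_per_day=90, walking_days_per_week=7)
        assert out["walking"] == pytest.approx(2079.0)
        spec = codebook37["walking_met"]
        assert spec.is_exposed(pd.Series([out["walking"]]))[0]
        assert not spec.is_exposed(pd.Series([1999.0]))[0]

    def test_weights(self):
        out = ls.met_minutes(moderate_min_per_day=10, moderate_days_per_week=1,
                             vigorous_min_per_day=10, vigorous_days_per_week=1)
        assert out["moderate"] == pytest.approx(40.0)
        assert out["vigorous"] == pytest.approx(80.0)

    def test_invalid_days(self):
        with pytest.raises(ValueError):
            ls.met_minutes(walking_min_per_day=10, walking_days_per_week=8)


class TestExclusions:
    def _toy(self):
        return pd.DataFrame(
            {
                "participant_id": [1, 2, 3, 4, 5],
                "creatinine": [80.0, 200.0, 80.0, 80.0, 80.0],  # 200 -> eGFR ~ 32
                "age": [55.0] * 5,
                "sex": ["male"] * 5,
                "ethnicity": ["white"] * 5,
            }
        )

    def test_egfr_rule(self):
        retained, log = ls.apply_exclusions(self._toy())
        assert len(retained) == 4
        assert log["baseline_egfr"] == 1
        assert log["retained"] == 4

    def test_all_eligible_identity(self):
        toy = self._toy()
        toy["creatinine"] = 80.0
        retained, log = ls.apply_exclusions(toy)
        pd.testing.assert_frame_equal(retained, toy)
        assert log.drop("retained").sum() == 0

    def test_first_matching_rule_attribution(self):
        toy = self._toy()
        toy["baseline_codes"] = [None, "N18", "N18", None, None]
        retained, log = ls.apply_exclusions(toy)
        # row 2 hits the eGFR rule first; only row 3 is attributed to codes
        assert log["baseline_egfr"] == 1
        assert log["prevalent_ckd"] == 1
        assert len(retained) == 3

    def test_prior_rrt_rule(self):
        toy = self._toy()
        toy["creatinine"] = 80.0
        toy["prior_rrt"] = [False, True, False, False, False]
        retained, log = ls.apply_exclusions(toy)
        assert log["prior_rrt"] == 1 and len(retained) == 4

    def test_missing_lifestyle_rule(self, codebook37):
        cohort = ls.generate_cohort(
            ls.SimulationConfig(n_participants=300, seed=8, missing_rate=0.0,
                                high_missing_fraction=0.0, prevalent_ckd_rate=0.0,
                                prior_rrt_rate=0.0),
            codebook37,
        )
        factor_cols = [c for c in codebook37.names if c in cohort.columns]
        # wipe all but one direct factor field for the first row (~3% present)
        for col in factor_cols[1:]:
            if cohort[col].dtype == object:
                cohort.loc[0, col] = None
            elif isinstance(cohort[col].dtype, pd.CategoricalDtype):
                cohort.loc[0, col] = pd.NA
            else:
                cohort[col] = cohort[col].astype("Int64")
                cohort.loc[0, col] = pd.NA
        pid = cohort.loc[0, "participant_id"]
        retained, log = ls.apply_exclusions(cohort, codebook=codebook37)
        assert log["lifestyle_missingness"] == 1
        assert pid not in set(retained["participant_id"])

    def test_partition_property(self, small_cohort, codebook37):
        retained, log = ls.apply_exclusions(small_cohort, codebook=codebook37)
        assert log["retained"] == len(retained)
        assert log.drop("retained").sum() + log["retained"] == len(small_cohort)

    def test_missing_creatinine_column(self):
        with pytest.raises(SchemaError):
            ls.apply_exclusions(pd.DataFrame({"age": [50]}))


class TestDeriveFactors:
    def test_sleep_window(self, analysis_small):
        h = analysis_small["sleep_duration_h"].astype(float)
        ok = analysis_small["adequate_sleep"].astype("Int64")
        inside = h.between(7, 9)
        mask = h.notna()
        assert (ok[mask].astype(bool) == inside[mask]).all()

    @pytest.mark.parametrize("hours,expected", [(8.0, 1), (6.5, 0), (7.0, 1), (9.0, 1), (9.5, 0)])
    def test_sleep_examples(self, codebook37, hours, expected, small_cohort):
        row = small_cohort.iloc[[0]].copy()
        row["sleep_duration_h"] = hours
        out = ls.derive_factors(row, codebook37)
        assert out["adequate_sleep"].iloc[0] == expected

    def test_former_smoker_is_non_current(self, codebook37, small_cohort):
        row = small_cohort.iloc[[0]].copy()
        for status, expected in [("never", 0), ("former", 0), ("current", 1)]:
            row["smoking_status"] = status
            out = ls.derive_factors(row, codebook37)
            assert out["current_smoking"].iloc[0] == expected

    def test_psychological_health_requires_no_adversity(self, codebook37, small_cohort):
        row = small_cohort.iloc[[0]].copy()
        for f in ["illness_2y", "injury_2y", "bereavement_2y", "stress_2y"]:
            row[f] = 0
        assert ls.derive_factors(row, codebook37)["psychological_health"].iloc[0] == 1
        row["stress_2y"] = 1
        assert ls.derive_factors(row, codebook37)["psychological_health"].iloc[0] == 0

    def test_met_columns_match_direct_arithmetic(self, analysis_small):
        sub = analysis_small.dropna(subset=["walking_min_day", "walking_days_wk", "walking_met"]).head(50)
        expected = (3.3 * sub["walking_min_day"].astype(float) * sub["walking_days_wk"].astype(float)).round()
        assert (sub["walking_met"].astype(float) == expected).all()

    def test_unknown_category_label_raises(self, codebook37, small_cohort):
        row = small_cohort.iloc[[0]].copy()
        row["processed_meat"] = "thrice_daily"
        with pytest.raises(CodebookError, match="processed_meat"):
            ls.derive_factors(row, codebook37)


class TestDefineOutcome:
    def _cohort(self, n=3):
        return pd.DataFrame(
            {
                "participant_id": range(1, n + 1),
                "followup_end": [10.0] * n,
            }
        )

    def test_first_occurrence_rule(self):
        records = pd.DataFrame(
            {
                "participant_id": [1, 1],
                "kind": ["egfr", "icd10"],
                "code": ["", "N18"],
                "time": [4.0, 6.0],
                "value": [58.0, np.nan],
            }
        )
        out = ls.define_outcome(self._cohort(1), records)
        assert out["event_type"].iloc[0] == "ckd"
        assert out["event_time"].iloc[0] == 4.0

    def test_no_record_censored_at_admin_end(self):
        out = ls.define_outcome(self._cohort(1), pd.DataFrame(
            columns=["participant_id", "kind", "code", "time", "value"]))
        assert out["event_type"].iloc[0] == "censored"
        assert out["event_time"].iloc[0] == 10.0

    def test_rrt_code_z49_is_ckd_event(self):
        records = pd.DataFrame(
            {"participant_id": [1], "kind": ["rrt"], "code": ["Z49"],
             "time": [3.0], "value": [np.nan]}
        )
        out = ls.define_outcome(self._cohort(1), records)
        assert out["event_type"].iloc[0] == "ckd"
        assert out["event_time"].iloc[0] == 3.0

    def test_non_qualifying_egfr_value_ignored(self):
        records = pd.DataFrame(
            {"participant_id": [1], "kind": ["egfr"], "code": [""],
             "time": [2.0], "value": [75.0]}
        )
        out = ls.define_outcome(self._cohort(1), records)
        assert out["event_type"].iloc[0] == "censored"

    def test_threshold_dialect_flag(self):
        records = pd.DataFrame(
            {"participant_id": [1], "kind": ["egfr"], "code": [""],
             "time": [2.0], "value": [60.0]}
        )
        inclusive = ls.define_outcome(self._cohort(1), records, ls.OutcomeDefinition())
        strict = ls.define_outcome(
            self._cohort(1), records, ls.OutcomeDefinition(inclusive_threshold=False)
        )
        assert inclusive["event_type"].iloc[0] == "ckd"
        assert strict["event_type"].iloc[0] == "censored"

    def test_record_before_baseline_rejected(self):
        records = pd.DataFrame(
            {"participant_id": [1], "kind": ["icd10"], "code": ["N18"],
             "time": [0.0], "value": [np.nan]}
        )
        with pytest.raises(ValueError, match="baseline"):
            ls.define_outcome(self._cohort(1), records)

    def test_followup_always_positive(self, small_cohort):
        records = ls.event_records(small_cohort, seed=1)
        stripped = small_cohort.drop(columns=["event_type", "event_time", "ckd_event",
                                              "death_event", "death_time", "cvd_event", "cvd_time"])
        out = ls.define_outcome(stripped, records)
        assert (out["event_time"] > 0).all()
        assert (out["death_time"] > 0).all()
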