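"""Exclusion cascade, dichotomization rules and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sesmediate import prep
from sesmediate.errors import EstimationError
from sesmediate.simulate import EXCLUSION_REASONS


def make_raw(i=0, **over):
    row = {
        "id": f"T{i:03d}", "age": 47.0, "sex": "female",
        "education_level": "university", "occupational_class": "skilled",
        "family_history": 0, "comorbidity": 0, "poor_health": 0,
        "smoker_current": 0, "alcohol_cl_day": 0.5,
        "physical_activity": "average", "fruitveg_freq": "1_per_day",
        "bmi": 24.0, "fpg": 4.6, "sbp": 120.0, "dbp": 75.0,
        "antihypertensive_use": 0, "incident_t2d": 0,
    }
    row.update({r: 0 for r in EXCLUSION_REASONS})
    row.update(over)
    return row


def raw_frame(rows):
    return pd.DataFrame(rows)


class TestExclusions:
    def test_hand_counted_cascade(self):
        df = raw_frame([
            make_raw(0, prevalent_t2d=1),
            make_raw(1, missing_ses=1),
            make_raw(2, died=1),
            make_raw(3), make_raw(4), make_raw(5),
        ])
        kept, tally = prep.apply_exclusions(df)
        assert len(kept) == 3
        assert tally.counts == {"prevalent_t2d": 1, "missing_ses": 1,
                                "missing_covariates": 0, "t1d_or_lada": 0,
                                "emigrated": 0, "died": 1}
        assert tally.conserved()

    def test_multi_reason_record_tallied_under_first(self):
        df = raw_frame([make_raw(0, prevalent_t2d=1, died=1)])
        _, tally = prep.apply_exclusions(df)
        assert tally.counts["prevalent_t2d"] == 1
        assert tally.counts["died"] == 0

    def test_empty_input(self):
        kept, tally = prep.apply_exclusions(raw_frame([make_raw(0)]).iloc[:0])
        assert kept.empty and tally.n_in == tally.n_out == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(*[st.booleans()] * 6), min_size=0, max_size=40))
    def test_tally_conservation(self, flag_rows):
        rows = [
            make_raw(i, **{r: int(f) for r, f in zip(EXCLUSION_REASONS, flags)})
            for i, flags in enumerate(flag_rows)
        ]
        df = raw_frame(rows) if rows else raw_frame([make_raw(0)]).iloc[:0]
        _, tally = prep.apply_exclusions(df)
        assert tally.conserved()


class TestAlcoholCutoffs:
    def test_uniform_nine_values(self):
        rows = [make_raw(i, alcohol_cl_day=float(v)) for i, v in enumerate(range(1, 10))]
        cut = prep.alcohol_cutoffs(raw_frame(rows))
        assert cut["female"] == pytest.approx(6 + 1 / 3)
        high = prep.dichotomize(raw_frame(rows), cut)["high_alcohol"]
        assert high.tolist() == [0] * 6 + [1] * 3

    def test_degenerate_all_equal(self):
        rows = [make_raw(i, alcohol_cl_day=2.0) for i in range(5)]
        cut = prep.alcohol_cutoffs(raw_frame(rows))
        assert cut["female"] == 2.0
        assert prep.dichotomize(raw_frame(rows), cut)["high_alcohol"].sum() == 0

    def test_sex_specific_thresholds(self):
        rows = [make_raw(i, alcohol_cl_day=float(v)) for i, v in enumerate(range(1, 10))]
        rows += [make_raw(10 + i, sex="male", alcohol_cl_day=float(10 * v))
                 for i, v in enumerate(range(1, 10))]
        cut = prep.alcohol_cutoffs(raw_frame(rows))
        assert cut["male"] == pytest.approx(10 * cut["female"])

    def test_small_stratum_errors(self):
        rows = [make_raw(0), make_raw(1), make_raw(2), make_raw(3, sex="male")]
        with pytest.raises(EstimationError, match="male"):
            prep.alcohol_cutoffs(raw_frame(rows))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 20.0, allow_nan=False), min_size=3, max_size=60))
    def test_high_share_bounded_by_third(self, values):
        rows = [make_raw(i, alcohol_cl_day=v) for i, v in enumerate(values)]
        df = raw_frame(rows)
        adf = prep.dichotomize(df, prep.alcohol_cutoffs(df))
        assert adf["high_alcohol"].mean() <= 1 / 3 + 1 / len(df)


class TestDichotomize:
    CUT = {"female": 1.0, "male": 2.0}

    def _one(self, **over):
        return prep.dichotomize(raw_frame([make_raw(0, **over)]), self.CUT).iloc[0]

    @pytest.mark.parametrize("field,value,col,expect", [
        ("bmi", 30.0, "obesity", 1),
        ("bmi", 29.999, "obesity", 0),
        ("fpg", 5.6, "high_fpg", 1),
        ("fpg", 5.59, "high_fpg", 0),
        ("education_level", "basic", "x_edu", 1),
        ("education_level", "vocational_or_upper_secondary", "x_edu", 0),
        ("occupational_class", "semiskilled", "x_occ", 1),
        ("occupational_class", "assistant_nonmanual", "x_occ", 0),
        ("physical_activity", "lower", "low_physical_activity", 1),
        ("physical_activity", "average", "low_physical_activity", 0),
        ("fruitveg_freq", "1_per_week", "low_fruitveg", 1),
        ("fruitveg_freq", "2_3_per_week", "low_fruitveg", 0),
    ])
    def test_boundaries(self, field, value, col, expect):
        assert self._one(**{field: value})[col] == expect

    def test_hypertension_is_a_disjunction(self):
        assert self._one(sbp=135.0, dbp=90.0)["hypertension"] == 1
        assert self._one(sbp=140.0, dbp=70.0)["hypertension"] == 1
        assert self._one(sbp=120.0, dbp=70.0, antihypertensive_use=1)["hypertension"] == 1
        assert self._one(sbp=139.9, dbp=89.9)["hypertension"] == 0

    def test_missing_field_names_field(self):
        with pytest.raises(EstimationError, match="bmi"):
            prep.dichotomize(raw_frame([make_raw(0, bmi=np.nan)]), self.CUT)
        df = raw_frame([make_raw(0)]).drop(columns=["fpg"])
        with pytest.raises(EstimationError, match="fpg"):
            prep.dichotomize(df, self.CUT)

    def test_deterministic_and_order_independent(self):
        rows = [make_raw(i, bmi=20.0 + i) for i in range(6)]
        df = raw_frame(rows)
        a = prep.dichotomize(df, self.CUT)
        b = prep.dichotomize(df.iloc[::-1].reset_index(drop=True), self.CUT)
        merged = a.merge(b, on="id", suffixes=("_a", "_b"))
        assert (merged["obesity_a"] == merged["obesity_b"]).all()


class TestDescribe:
    def test_single_record_sentinels(self):
        adf = prep.dichotomize(raw_frame([make_raw(0, education_level="basic")]),
                               {"female": 1.0})
        t = prep.describe(adf, group_by="x_edu")
        age = t[t.variable == "age"].iloc[0]
        assert np.isnan(age["total_sd"])
        women = t[t.variable == "women"].iloc[0]
        assert women["total_pct"] in (0.0, 100.0)

    def test_hand_computed_four_records(self):
        rows = [
            make_raw(0, education_level="basic", age=40.0, smoker_current=1),
            make_raw(1, education_level="basic", age=50.0),
            make_raw(2, age=44.0), make_raw(3, age=46.0),
        ]
        adf = prep.dichotomize(raw_frame(rows), {"female": 1.0})
        t = prep.describe(adf, group_by="x_edu").set_index("variable")
        assert t.loc["smoking", "total_pct"] == pytest.approx(25.0)
        assert t.loc["smoking", "x_edu=1_pct"] == pytest.approx(50.0)
        age = t.loc["age"]
        assert age["total_mean"] == pytest.approx(45.0)
        assert age["x_edu=1_mean"] == pytest.approx(45.0)
        assert age["x_edu=1_sd"] == pytest.approx(np.std([40, 50], ddof=1))

    def test_schema_on_synthetic_cohort(self, kept_cohort, analysis_frame):
        t = prep.describe(analysis_frame, group_by="x_edu", raw=kept_cohort)
        expect = {"age", "bmi", "fpg", "sbp", "dbp", "women", "family_history",
                  "comorbidity", "poor_health", "smoking", "high_alcohol",
                  "low_physical_activity", "low_fruitveg", "obesity", "high_fpg",
                  "hypertension", "incident_t2d"}
        assert set(t.variable) == expect
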