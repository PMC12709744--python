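"""Cohort reading, validation, standardisation and follow-up summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pmstability_tte import (
    CohortSchema,
    DegeneratePredictorError,
    PredictorSpec,
    SchemaError,
    StateError,
    ValidationError,
    destandardise,
    read_cohort,
    standardise,
    summarise_followup,
    write_cohort,
)

from conftest import make_cohort


def write_csv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


AGE_SCHEMA = CohortSchema(
    predictors=(PredictorSpec("age"),), time="time", event="event"
)


class TestReadCohort:
    def test_parses_simple_file_with_followup(self, tmp_path):
        f = write_csv(tmp_path / "c.csv", "age,time,event\n40,1.0,1\n50,2.5,0\n60,3.0,1\n")
        cohort = read_cohort(f, AGE_SCHEMA)
        assert (cohort.n, cohort.p) == (3, 1)
        assert cohort.has_followup
        np.testing.assert_allclose(cohort.time, [1.0, 2.5, 3.0])

    def test_nonpositive_time_names_the_row(self, tmp_path):
        f = write_csv(tmp_path / "c.csv", "age,time,event\n40,1.0,1\n50,0.0,0\n60,3.0,1\n")
        with pytest.raises(ValidationError, match="row 1"):
            read_cohort(f, AGE_SCHEMA)

    def test_missing_cell_names_the_row(self, tmp_path):
        f = write_csv(tmp_path / "c.csv", "age,time,event\n40,1.0,1\n,2.5,0\n")
        with pytest.raises(ValidationError, match="'age' at row 1"):
            read_cohort(f, AGE_SCHEMA)

    def test_undeclared_column_is_schema_error(self, tmp_path):
        f = write_csv(tmp_path / "c.csv", "height,time,event\n1.8,1.0,1\n")
        with pytest.raises(SchemaError, match="age"):
            read_cohort(f, AGE_SCHEMA)

    def test_event_must_be_binary(self, tmp_path):
        f = write_csv(tmp_path / "c.csv", "age,time,event\n40,1.0,2\n")
        with pytest.raises(ValidationError, match="event"):
            read_cohort(f, AGE_SCHEMA)

    def test_filter_predicate_subsets_rows(self, tmp_path):
        f = write_csv(
            tmp_path / "c.csv",
            "age,er,tam,time,event\n40,1,1,1.0,1\n50,0,1,2.0,0\n60,1,1,3.0,1\n55,1,0,4.0,0\n",
        )
        schema = CohortSchema(
            predictors=(PredictorSpec("age"),),
            time="time",
            event="event",
            filter="er == 1 and tam == 1",
        )
        assert read_cohort(f, schema).n == 2

    def test_categorical_dummy_coding_against_reference(self, tmp_path):
        f = write_csv(
            tmp_path / "c.csv", "grade,time,event\n1,1.0,1\n2,2.0,0\n3,3.0,1\n2,4.0,0\n"
        )
        schema = CohortSchema(
            predictors=(PredictorSpec("grade", kind="categorical", reference="1"),),
            time="time",
            event="event",
        )
        cohort = read_cohort(f, schema)
        assert set(cohort.predictors.columns) == {"grade_2", "grade_3"}
        np.testing.assert_allclose(cohort.predictors["grade_2"], [0, 1, 0, 1])
        np.testing.assert_allclose(cohort.predictors["grade_3"], [0, 0, 1, 0])


class TestStandardise:
    def test_symmetric_case_sample_sd(self):
        cohort = make_cohort(x=[1.0, 2.0, 3.0])
        out = standardise(cohort, ["x"])
        np.testing.assert_allclose(out.predictors["x"], [-1.0, 0.0, 1.0])
        info = out.columns["x"]
        assert (info.mean, info.sd) == (2.0, 1.0)  # sample SD, n-1 denominator

    def test_restandardising_leaves_values_unchanged(self):
        out1 = standardise(make_cohort(x=[1.0, 5.0, 9.0, 2.0]), ["x"])
        out2 = standardise(out1, ["x"])
        np.testing.assert_allclose(
            out2.predictors["x"], out1.predictors["x"], atol=1e-12
        )
        # composed metadata still maps the raw scale to the current values
        np.testing.assert_allclose(out2.columns["x"].mean, out1.columns["x"].mean)

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegeneratePredictorError):
            standardise(make_cohort(x=[2.0, 2.0, 2.0]), ["x"])

    def test_destandardise_round_trip(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(30.0, 7.0, size=50)
        cohort = make_cohort(x=raw)
        back = destandardise(standardise(cohort, ["x"]), ["x"])
        np.testing.assert_allclose(back.predictors["x"], raw, atol=1e-12)


class TestFollowupSummary:
    def test_hand_arithmetic(self, simple_followup_cohort):
        s = summarise_followup(simple_followup_cohort)
        assert (s.n, s.events, s.person_years) == (3, 2, 6.0)
        assert s.mean_followup == 2.0
        assert s.max_followup == 3.0
        assert s.event_rate == pytest.approx(1 / 3)
        assert s.event_rate * s.person_years == s.events  # exact identity

    def test_all_events_at_identical_time(self):
        cohort = make_cohort(
            time=np.full(4, 2.5), event=np.ones(4), x=np.arange(4.0)
        )
        s = summarise_followup(cohort)
        assert s.mean_followup == 2.5
        assert s.event_rate == pytest.approx(1 / 2.5)

    def test_requires_followup(self):
        with pytest.raises(StateError):
            summarise_followup(make_cohort(x=[1.0, 2.0]))


def test_read_write_read_round_trip_is_bit_identical(tmp_path):
    rng = np.random.default_rng(42)
    f = tmp_path / "orig.csv"
    pd.DataFrame(
        {
            "age": rng.normal(53, 10, 30),
            "size": rng.gamma(3.0, 9.0, 30),
            "time": rng.exponential(3.0, 30) + 0.01,
            "event": rng.integers(0, 2, 30),
        }
    ).to_csv(f, index=False)
    schema = CohortSchema(
        predictors=(PredictorSpec("age"), PredictorSpec("size")),
        time="time",
        event="event",
    )
    first = read_cohort(f, schema)
    g = tmp_path / "rewritten.csv"
    write_cohort(first, g)
    second = read_cohort(g, schema)
    for col in ("age", "size"):
        assert (first.predictors[col].to_numpy() == second.predictors[col].to_numpy()).all()
    assert (first.time == second.time).all()
    assert (first.event == second.event).all()
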