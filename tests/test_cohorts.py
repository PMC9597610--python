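"""Eligibility rules, follow-up, subsampling, covariates and scores."""
import numpy as np
import pandas as pd
import pytest

from conftest import dose, event, make_db, person

from vaxsafety.cohorts import (
    CHA2DS2_VASC,
    ROMANO_CHARLSON,
    CovariateExtractionSpec,
    EligibilityRules,
    ScoreDefinition,
    build_cohort,
    compute_score,
    extract_covariates,
    subsample_cohort,
)
from vaxsafety.config import ConfigValidationError
from vaxsafety.errors import CohortError, UnknownBrandError
from vaxsafety.synthetic import generate_database
from vaxsafety.config import SimulationConfig


def eligible_person(pid, **kw):
    return person(pid, **kw)


class TestEligibility:
    def test_basic_inclusion(self):
        db = make_db([person(1)], [dose(1)])
        cohort = build_cohort(db, "ChAdOx1-S", 1)
        assert list(cohort["person_id"]) == [1]
        assert cohort.loc[0, "index_day"] == 50
        assert cohort.loc[0, "follow_up_end_day"] == 78
        assert cohort.loc[0, "censor_reason"] == "window_end"

    def test_short_history_excluded(self):
        # 200 days of history before index: below the one-year minimum
        db = make_db([person(1, obs_start=-150)], [dose(1, day=50)])
        assert build_cohort(db, "ChAdOx1-S", 1).empty

    def test_short_dose_gap_excludes_both_cohorts(self):
        db = make_db(
            [person(1)],
            [dose(1, day=50), dose(1, dose_number=2, day=60)],
        )
        assert build_cohort(db, "ChAdOx1-S", 1).empty
        assert build_cohort(db, "ChAdOx1-S", 2).empty

    def test_gap_of_15_days_retained(self):
        db = make_db([person(1)], [dose(1, day=50), dose(1, dose_number=2, day=65)])
        assert len(build_cohort(db, "ChAdOx1-S", 1)) == 1

    def test_death_censors_follow_up(self):
        db = make_db([person(1, obs_end=55, death=55.0)], [dose(1, day=50)])
        cohort = build_cohort(db, "ChAdOx1-S", 1)
        assert cohort.loc[0, "follow_up_end_day"] == 55
        assert cohort.loc[0, "censor_reason"] == "death"

    def test_disenrolment_censors_follow_up(self):
        db = make_db([person(1, obs_end=60)], [dose(1, day=50)])
        cohort = build_cohort(db, "ChAdOx1-S", 1)
        assert cohort.loc[0, "follow_up_end_day"] == 60
        assert cohort.loc[0, "censor_reason"] == "observation_end"

    def test_under_18_excluded(self):
        db = make_db([person(1, birth_year=2010.0)], [dose(1)])
        assert build_cohort(db, "ChAdOx1-S", 1).empty

    def test_missing_sex_excluded(self):
        db = make_db([person(1, sex=None)], [dose(1)])
        assert build_cohort(db, "ChAdOx1-S", 1).empty

    def test_unspecified_brand_record_excludes_person(self):
        # person 1's second dose has no recorded brand; person 2 is clean
        db = make_db(
            [person(1), person(2)],
            [dose(1, day=50), dose(1, dose_number=2, day=120, brand="unknown"), dose(2)],
        )
        assert list(build_cohort(db, "ChAdOx1-S", 1)["person_id"]) == [2]

    def test_dose2_brand_mismatch_excluded(self):
        db = make_db(
            [person(1)],
            [dose(1, brand="ChAdOx1-S", day=50), dose(1, brand="BNT162b2", dose_number=2, day=120)],
        )
        assert build_cohort(db, "BNT162b2", 2).empty

    def test_unknown_brand_label_raises(self):
        db = make_db([person(1)], [dose(1)])
        with pytest.raises(UnknownBrandError):
            build_cohort(db, "NotAVaccine", 1)

    def test_bad_dose_number_raises(self):
        db = make_db([person(1)], [dose(1)])
        with pytest.raises(CohortError):
            build_cohort(db, "ChAdOx1-S", 3)

    def test_idempotent_and_bounded_person_time(self):
        db = generate_database(SimulationConfig(n_persons=2000, n_negative_controls=0), 4)
        c1 = build_cohort(db, "ChAdOx1-S", 1)
        c2 = build_cohort(db, "ChAdOx1-S", 1)
        pd.testing.assert_frame_equal(c1, c2)
        days = c1["follow_up_end_day"] - c1["index_day"]
        assert ((days >= 0) & (days <= 28)).all()


class TestSubsample:
    def test_fraction_one_is_identity(self, cohort_of):
        cohort = cohort_of([(i, 0, 28) for i in range(10)])
        pd.testing.assert_frame_equal(subsample_cohort(cohort, 1.0, 0), cohort)

    def test_exact_rounded_size(self, cohort_of):
        cohort = cohort_of([(i, 0, 28) for i in range(1000)])
        assert len(subsample_cohort(cohort, 0.2, 3)) == 200

    def test_seed_contract(self, cohort_of):
        cohort = cohort_of([(i, 0, 28) for i in range(500)])
        a = subsample_cohort(cohort, 0.2, 1)
        b = subsample_cohort(cohort, 0.2, 2)
        assert len(a) == len(b) == 100
        assert set(a["person_id"]) != set(b["person_id"])

    def test_out_of_range_fraction(self, cohort_of):
        cohort = cohort_of([(1, 0, 28)])
        with pytest.raises(CohortError):
            subsample_cohort(cohort, 0.0, 0)


class TestCovariates:
    def test_condition_on_index_day_not_counted(self, cohort_of):
        db = make_db([person(1)], [dose(1)], [event(1, "hypertension", 50)])
        covs = extract_covariates(db, cohort_of([(1, 50, 78)]))
        assert covs.column("condition_hypertension")[0] == 0

    def test_condition_before_index_counted(self, cohort_of):
        db = make_db([person(1)], [dose(1)], [event(1, "hypertension", -400)])
        covs = extract_covariates(db, cohort_of([(1, 50, 78)]))
        assert covs.column("condition_hypertension")[0] == 1

    def test_one_hot_index_date(self, cohort_of):
        db = make_db([person(1)], [dose(1, day=70)])
        covs = extract_covariates(db, cohort_of([(1, 70, 98)]))
        frame = covs.to_frame()
        months = frame.filter(like="index_month_")
        years = frame.filter(like="index_year_")
        assert months.to_numpy().sum() == 1 and years.to_numpy().sum() == 1
        assert months.columns[months.iloc[0].astype(bool)][0] == "index_month_03"

    def test_utilisation_window_arithmetic(self, cohort_of):
        rows = [event(1, "drug_record", 50 - d) for d in range(1, 8)]  # 7 in window
        rows += [event(1, "drug_record", 50 - 200), event(1, "drug_record", 50 - 181)]  # 2 older
        db = make_db([person(1)], [dose(1)], rows)
        covs = extract_covariates(db, cohort_of([(1, 50, 78)]))
        assert covs.column("count_drug_record")[0] == 7

    def test_missing_person_raises(self, cohort_of):
        db = make_db([person(1)], [dose(1)])
        with pytest.raises(CohortError):
            extract_covariates(db, cohort_of([(2, 50, 78)]))

    def test_pure_function_of_inputs(self, cohort_of):
        db = make_db([person(1)], [dose(1)], [event(1, "diabetes", -100)])
        cohort = cohort_of([(1, 50, 78)])
        a = extract_covariates(db, cohort)
        b = extract_covariates(db, cohort)
        assert (a.matrix != b.matrix).nnz == 0
        pd.testing.assert_frame_equal(a.meta, b.meta)


class TestScores:
    def test_no_components_zero(self):
        assert compute_score({}, CHA2DS2_VASC, age=40, sex="male") == 0

    def test_stroke_score_published_weights(self):
        # female, 76, hypertension only: 2 (age) + 1 (sex) + 1 (hypertension)
        flags = {"hypertension": 1}
        assert compute_score(flags, CHA2DS2_VASC, age=76, sex="female") == 4

    def test_weighted_sum(self):
        defn = ScoreDefinition("toy", weights={"a": 1, "b": 1, "c": 2})
        assert compute_score({"a": 1, "b": 1, "c": 1}, defn, age=40, sex="male") == 4

    def test_absent_components_count_zero(self):
        assert compute_score({"unrelated": 1}, ROMANO_CHARLSON, age=50, sex="male") == 0

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigValidationError):
            ScoreDefinition("bad", weights={"a": -1})
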