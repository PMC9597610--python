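"""Risk-window ascertainment, composites, prior history, and the TTS phenotype."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import dose, event, make_db, measurement, person

from vaxsafety.errors import UnknownOutcomeError
from vaxsafety.outcomes import (
    OutcomeDefinition,
    OutcomeRegistry,
    TTSDefinition,
    ascertain_first_event,
    classify_tts,
    default_registry,
    detect_thrombocytopenia_days,
    exclude_prior_history,
    first_event_days,
    tts_event_days,
)

REG = default_registry()


def entry(pid=1, index=50, fu=78):
    return pd.Series({"person_id": pid, "index_day": index, "follow_up_end_day": fu})


class TestAscertainment:
    def test_composite_takes_earliest_member(self):
        db = make_db(
            [person(1)], [dose(1)],
            [event(1, "deep_vein_thrombosis", 55), event(1, "pulmonary_embolism", 53)],
        )
        assert ascertain_first_event(db, entry(), "venous_thromboembolism", REG) == 53

    def test_event_after_window_ignored(self):
        db = make_db([person(1)], [dose(1)], [event(1, "deep_vein_thrombosis", 79)])
        assert ascertain_first_event(db, entry(), "deep_vein_thrombosis", REG) is None

    def test_event_after_censoring_ignored(self):
        db = make_db([person(1)], [dose(1)], [event(1, "deep_vein_thrombosis", 60)])
        assert ascertain_first_event(db, entry(fu=57), "deep_vein_thrombosis", REG) is None

    def test_event_on_index_day_ignored(self):
        db = make_db([person(1)], [dose(1)], [event(1, "deep_vein_thrombosis", 50)])
        assert ascertain_first_event(db, entry(), "deep_vein_thrombosis", REG) is None

    def test_unknown_outcome_raises(self):
        db = make_db([person(1)], [dose(1)])
        with pytest.raises(UnknownOutcomeError):
            ascertain_first_event(db, entry(), "nonexistent", REG)

    def test_vectorised_matches_scalar(self, cohort_of):
        rng = np.random.default_rng(0)
        events = [
            event(int(pid), "deep_vein_thrombosis", int(day))
            for pid, day in zip(rng.integers(1, 20, 40), rng.integers(30, 110, 40))
        ]
        db = make_db([person(i) for i in range(1, 20)], [], events)
        cohort = cohort_of([(i, 50, 78) for i in range(1, 20)])
        vec = first_event_days(db, cohort, "deep_vein_thrombosis", REG)
        for _, row in cohort.iterrows():
            scalar = ascertain_first_event(db, row, "deep_vein_thrombosis", REG)
            got = vec.loc[row["person_id"]]
            assert (scalar is None and np.isnan(got)) or scalar == got


class TestPriorHistory:
    def test_prior_event_excluded_for_that_outcome(self, cohort_of):
        db = make_db([person(1)], [dose(1)], [event(1, "deep_vein_thrombosis", -700)])
        cohort = cohort_of([(1, 50, 78)])
        assert exclude_prior_history(cohort, db, "deep_vein_thrombosis", REG).empty

    def test_other_outcomes_unaffected(self, cohort_of):
        db = make_db([person(1)], [dose(1)], [event(1, "deep_vein_thrombosis", -700)])
        cohort = cohort_of([(1, 50, 78)])
        assert len(exclude_prior_history(cohort, db, "myocardial_infarction", REG)) == 1

    def test_no_events_no_change(self, cohort_of):
        db = make_db([person(1)], [dose(1)])
        cohort = cohort_of([(1, 50, 78)])
        pd.testing.assert_frame_equal(exclude_prior_history(cohort, db, "deep_vein_thrombosis", REG), cohort)

    def test_never_removes_person_without_prior_member_event(self, cohort_of):
        rng = np.random.default_rng(1)
        events = [
            event(int(pid), "deep_vein_thrombosis", int(day))
            for pid, day in zip(rng.integers(1, 30, 60), rng.integers(-200, 100, 60))
        ]
        db = make_db([person(i) for i in range(1, 30)], [], events)
        cohort = cohort_of([(i, 50, 78) for i in range(1, 30)])
        kept = exclude_prior_history(cohort, db, "deep_vein_thrombosis", REG)
        removed = set(cohort["person_id"]) - set(kept["person_id"])
        with_prior = {
            e["person_id"] for e in events if e["day"] < 50
        }
        assert removed <= with_prior
        assert not (with_prior & set(kept["person_id"]))


class TestThrombocytopeniaEvidence:
    def test_measurement_below_threshold(self):
        db = make_db([person(1)], [dose(1)], [], [measurement(1, 60, 120.0)])
        assert detect_thrombocytopenia_days(db, 1, 150.0) == {60}

    def test_strict_threshold(self):
        db = make_db([person(1)], [dose(1)], [], [measurement(1, 60, 120.0)])
        assert detect_thrombocytopenia_days(db, 1, 100.0) == set()

    def test_diagnosis_code_alone_counts(self):
        db = make_db([person(1)], [dose(1)], [event(1, "thrombocytopenia", 61)])
        assert detect_thrombocytopenia_days(db, 1, 150.0) == {61}

    def test_same_day_evidence_counts_once(self):
        db = make_db(
            [person(1)], [dose(1)],
            [event(1, "thrombocytopenia", 60)], [measurement(1, 60, 90.0)],
        )
        assert detect_thrombocytopenia_days(db, 1, 150.0) == {60}


MAIN_TTS = TTSDefinition("vte_tts", "venous_thromboembolism")
FIVE_DAY = TTSDefinition("vte_tts_5d", "venous_thromboembolism", concurrency_window_days=5)


class TestClassifyTTS:
    def test_low_platelets_within_window(self):
        assert classify_tts(70, {75}, MAIN_TTS)

    def test_outside_window(self):
        assert not classify_tts(70, {82}, MAIN_TTS)

    def test_sensitivity_window(self):
        assert not classify_tts(70, {63}, FIVE_DAY)
        assert classify_tts(70, {65}, FIVE_DAY)

    @given(
        thrombo=st.integers(0, 60),
        days=st.sets(st.integers(-20, 90), max_size=12),
        window=st.integers(1, 15),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_pair_scan_oracle(self, thrombo, days, window):
        tts = TTSDefinition("t", "venous_thromboembolism", concurrency_window_days=window)
        oracle = False
        for d in days:  # brute-force scan over all pairs
            if thrombo - window <= d <= thrombo + window:
                oracle = True
        assert classify_tts(thrombo, days, tts) == oracle


class TestTTSVectorised:
    def test_concurrency_may_extend_past_risk_window(self, cohort_of):
        # thrombo on day 76 (in window), platelets low on day 84 (outside it)
        db = make_db(
            [person(1)], [dose(1)],
            [event(1, "pulmonary_embolism", 76)], [measurement(1, 84, 100.0)],
        )
        days = tts_event_days(db, cohort_of([(1, 50, 78)]), MAIN_TTS, REG)
        assert days.loc[1] == 76

    def test_agrees_with_scalar_route(self, cohort_of):
        rng = np.random.default_rng(2)
        n = 25
        events, meas = [], []
        for pid in range(1, n + 1):
            for day in rng.integers(40, 100, rng.integers(0, 3)):
                events.append(event(pid, "deep_vein_thrombosis", int(day)))
            for day in rng.integers(40, 110, rng.integers(0, 3)):
                meas.append(measurement(pid, int(day), float(rng.choice([90.0, 250.0]))))
        db = make_db([person(i) for i in range(1, n + 1)], [], events, meas)
        cohort = cohort_of([(i, 50, 78) for i in range(1, n + 1)])
        vec = tts_event_days(db, cohort, MAIN_TTS, REG)
        first = first_event_days(db, cohort, "venous_thromboembolism", REG)
        for pid in cohort["person_id"]:
            thrombo = first.loc[pid]
            if np.isnan(thrombo):
                assert np.isnan(vec.loc[pid])
            else:
                tcp = detect_thrombocytopenia_days(db, pid, MAIN_TTS.platelet_threshold)
                expected = classify_tts(int(thrombo), tcp, MAIN_TTS)
                assert (not np.isnan(vec.loc[pid])) == expected


class TestRegistry:
    def test_composite_must_reference_known_members(self):
        with pytest.raises(Exception):
            OutcomeRegistry([OutcomeDefinition("c", composite_of=("missing",))])

    def test_negative_control_cannot_be_composite(self):
        with pytest.raises(Exception):
            OutcomeDefinition("nc", composite_of=("a",), is_negative_control=True)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "outcomes.yaml"
        path.write_text(
            "- name: dvt\n  concepts: [deep_vein_thrombosis]\n"
            "- name: pe\n  concepts: [pulmonary_embolism]\n"
            "- name: vte\n  composite_of: [dvt, pe]\n"
            "- name: nc_x\n  concepts: [nc_x]\n  is_negative_control: true\n"
        )
        reg = OutcomeRegistry.from_yaml(str(path))
        assert reg.member_concepts("vte") == {"deep_vein_thrombosis", "pulmonary_embolism"}
        assert reg.negative_controls() == ["nc_x"]
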