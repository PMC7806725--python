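import dataclasses

import pytest

from pcto.decision_points import (
    detect_treatment_decision,
    determine_outcome,
    extract_decision_points,
    split_train_score,
)
from tests.conftest import bp, day, dx, enc, meas, med, timeline_of
from tests.oracles import brute_force_lab_dps, brute_force_pair_dps, random_timelines


def extract_one(timeline, config, codes):
    return extract_decision_points({timeline.patient_id: timeline}, config, codes)


class TestPairRule:
    def test_two_uncontrolled_readings_yield_one_dp(self, htn_config, codes):
        tl = timeline_of(bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92), codes)
        dps = extract_one(tl, htn_config, codes)
        assert len(dps) == 1
        assert dps.iloc[0]["index_date"] == day(30)

    def test_second_reading_controlled_yields_no_dp(self, htn_config, codes):
        tl = timeline_of(bp("P1", 0, 150, 95) + bp("P1", 30, 135, 85), codes)
        assert len(extract_one(tl, htn_config, codes)) == 0

    def test_dbp_alone_triggers_uncontrolled(self, htn_config, codes):
        tl = timeline_of(bp("P1", 0, 130, 95) + bp("P1", 30, 132, 92), codes)
        assert len(extract_one(tl, htn_config, codes)) == 1

    def test_separation_beyond_365_days_yields_no_dp(self, htn_config, codes):
        tl = timeline_of(bp("P1", 0, 150, 95) + bp("P1", 400, 145, 92), codes)
        assert len(extract_one(tl, htn_config, codes)) == 0

    def test_same_day_pair_yields_no_dp(self, htn_config, codes):
        tl = timeline_of(bp("P1", 30, 150, 95) + bp("P1", 30, 145, 92), codes)
        assert len(extract_one(tl, htn_config, codes)) == 0

    def test_minor_yields_no_dp(self, htn_config, codes):
        tl = timeline_of(bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92), codes, birth_year=1993)
        # age 17 at the 2010 index date
        assert len(extract_one(tl, htn_config, codes)) == 0

    def test_recent_pregnancy_excluded(self, htn_config, codes):
        events = bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92) + [dx("P1", 10, "DX_PREGNANCY")]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, htn_config, codes)) == 0

    def test_old_pregnancy_not_excluded(self, htn_config, codes):
        events = bp("P1", 400, 150, 95) + bp("P1", 430, 145, 92) + [dx("P1", 10, "DX_PREGNANCY")]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, htn_config, codes)) == 1

    def test_refill_only_encounter_excluded(self, htn_config, codes):
        events = bp("P1", 0, 150, 95) + [
            enc("P1", 30, "refill"),
            meas("P1", 30, "SBP", 145),
            meas("P1", 30, "DBP", 92),
        ]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, htn_config, codes)) == 0

    def test_three_uncontrolled_readings_yield_two_dps(self, htn_config, codes):
        events = bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92) + bp("P1", 90, 160, 100)
        tl = timeline_of(events, codes)
        dps = extract_one(tl, htn_config, codes)
        assert list(dps["index_date"]) == [day(30), day(90)]

    def test_outside_study_period_excluded(self, htn_config, codes):
        config = dataclasses.replace(htn_config, study_period=(day(1000), day(2000)))
        tl = timeline_of(bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92), codes)
        assert len(extract_one(tl, config, codes)) == 0


class TestLabRules:
    def test_t2dm_diagnosis_then_high_lab(self, t2dm_config, codes):
        events = [dx("P1", 0, "DX_T2DM"), enc("P1", 100), meas("P1", 90, "HBA1C", 7.5)]
        tl = timeline_of(events, codes)
        dps = extract_one(tl, t2dm_config, codes)
        assert list(dps["index_date"]) == [day(100)]

    def test_t2dm_lab_below_threshold_no_dp(self, t2dm_config, codes):
        events = [dx("P1", 0, "DX_T2DM"), enc("P1", 100), meas("P1", 90, "HBA1C", 6.9)]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, t2dm_config, codes)) == 0

    def test_t2dm_lab_outside_lookback_no_dp(self, t2dm_config, codes):
        events = [dx("P1", 0, "DX_T2DM"), enc("P1", 500), meas("P1", 90, "HBA1C", 8.0)]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, t2dm_config, codes)) == 0

    def test_t2dm_fallback_consecutive_lab_pair_sets_index(self, t2dm_config, codes):
        events = [
            enc("P1", 0),
            meas("P1", 0, "HBA1C", 6.6),
            enc("P1", 60),
            meas("P1", 60, "HBA1C", 6.7),
            enc("P1", 200),
            meas("P1", 180, "HBA1C", 7.4),
        ]
        tl = timeline_of(events, codes)
        dps = extract_one(tl, t2dm_config, codes)
        # index date = day 60 (second of the >= 6.5 pair); DP at day 200
        assert list(dps["index_date"]) == [day(200)]

    def test_hl_requires_diagnosis(self, hl_config, codes):
        events = [enc("P1", 100), meas("P1", 90, "LDL", 150)]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, hl_config, codes)) == 0

    def test_hl_dp_with_420_day_lookback(self, hl_config, codes):
        events = [dx("P1", 0, "DX_HL"), enc("P1", 500), meas("P1", 100, "LDL", 150)]
        tl = timeline_of(events, codes)
        assert list(extract_one(tl, hl_config, codes)["index_date"]) == [day(500)]

    def test_hl_ldl_exactly_130_is_controlled(self, hl_config, codes):
        events = [dx("P1", 0, "DX_HL"), enc("P1", 200), meas("P1", 100, "LDL", 130)]
        tl = timeline_of(events, codes)
        assert len(extract_one(tl, hl_config, codes)) == 0


class TestTreatmentDecision:
    def test_no_medication_events_is_no_change(self, htn_config, codes):
        tl = timeline_of(bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92), codes)
        label, n_meds = detect_treatment_decision(tl, day(30), htn_config, codes)
        assert label == "no_change"
        assert n_meds == 0

    def test_start_within_buffer_detected(self, htn_config, codes):
        events = bp("P1", 30, 145, 92) + [med("P1", 35, "RX_LISINOPRIL", "start")]
        tl = timeline_of(events, codes)
        label, n_meds = detect_treatment_decision(tl, day(30), htn_config, codes)
        assert label == "ACEI_Lisinopril+"
        assert n_meds == 1

    def test_start_after_buffer_not_detected(self, htn_config, codes):
        events = bp("P1", 30, 145, 92) + [med("P1", 50, "RX_LISINOPRIL", "start")]
        tl = timeline_of(events, codes)
        label, _ = detect_treatment_decision(tl, day(30), htn_config, codes)
        assert label == "no_change"

    def test_within_class_switch_sorted_join(self, t2dm_config, codes):
        events = [
            med("P1", 0, "RX_GLYBURIDE", "start"),
            med("P1", 103, "RX_GLYBURIDE", "stop"),
            med("P1", 103, "RX_GLIPIZIDE", "start"),
        ]
        tl = timeline_of(events, codes)
        label, n_meds = detect_treatment_decision(tl, day(100), t2dm_config, codes)
        assert label == "Sulfonylurea_Glipizide+|Sulfonylurea_Glyburide-"
        assert n_meds == 1

    def test_non_universe_medication_ignored(self, htn_config, codes):
        events = bp("P1", 30, 145, 92) + [med("P1", 35, "RX_METFORMIN", "start")]
        tl = timeline_of(events, codes)
        label, n_meds = detect_treatment_decision(tl, day(30), htn_config, codes)
        assert label == "no_change"
        assert n_meds == 0


class TestOutcome:
    def test_no_change_controlled_reading(self, htn_config, codes):
        events = bp("P1", 0, 150, 95) + bp("P1", 30, 145, 92) + bp("P1", 90, 130, 80)
        tl = timeline_of(events, codes)
        assert determine_outcome(tl, day(30), "no_change", htn_config) == "controlled"

    def test_changed_treatment_skips_early_reading(self, htn_config, codes):
        events = bp("P1", 30, 145, 92) + bp("P1", 37, 150, 85) + bp("P1", 60, 135, 80)
        tl = timeline_of(events, codes)
        # day-37 reading is inside the 14-day blanking window
        assert determine_outcome(tl, day(30), "ACEI_Lisinopril+", htn_config) == "controlled"
        # without a treatment change the day-37 reading counts
        assert determine_outcome(tl, day(30), "no_change", htn_config) == "not_controlled"

    def test_no_followup_measurement_is_missing(self, htn_config, codes):
        tl = timeline_of(bp("P1", 30, 145, 92), codes)
        assert determine_outcome(tl, day(30), "no_change", htn_config) == "missing"

    def test_reading_beyond_window_is_missing(self, htn_config, codes):
        events = bp("P1", 30, 145, 92) + bp("P1", 500, 130, 80)
        tl = timeline_of(events, codes)
        assert determine_outcome(tl, day(30), "no_change", htn_config) == "missing"


class TestSplit:
    def test_split_sizes_disjoint_exhaustive(self, htn_config, codes):
        tl = random_timelines(0, n_patients=30, codes=codes)
        dps = extract_decision_points(tl, htn_config, codes)
        train, score = split_train_score(dps, 30, seed=5)
        assert len(train) == 30
        assert len(train) + len(score) == len(dps)
        assert set(train["dp_id"]).isdisjoint(score["dp_id"])
        assert set(train["dp_id"]) | set(score["dp_id"]) == set(dps["dp_id"])

    def test_split_deterministic(self, htn_config, codes):
        tl = random_timelines(0, n_patients=20, codes=codes)
        dps = extract_decision_points(tl, htn_config, codes)
        t1, _ = split_train_score(dps, 10, seed=5)
        t2, _ = split_train_score(dps, 10, seed=5)
        assert list(t1["dp_id"]) == list(t2["dp_id"])

    def test_zero_train(self, htn_config, codes):
        tl = random_timelines(1, n_patients=10, codes=codes)
        dps = extract_decision_points(tl, htn_config, codes)
        train, score = split_train_score(dps, 0, seed=0)
        assert len(train) == 0
        assert len(score) == len(dps)


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pair_rule_matches_enumeration(self, seed, htn_config, codes):
        timelines = random_timelines(seed, n_patients=25, codes=codes)
        dps = extract_decision_points(timelines, htn_config, codes)
        got = {(r.patient_id, r.index_date) for r in dps.itertuples()}
        expected = {
            (pid, d)
            for pid, tl in timelines.items()
            for d in brute_force_pair_dps(tl, htn_config)
        }
        assert got == expected

    @pytest.mark.parametrize("config_name", ["t2dm_config", "hl_config"])
    def test_lab_rules_match_enumeration(self, config_name, request, codes):
        config = request.getfixturevalue(config_name)
        timelines = random_timelines(7, n_patients=25, codes=codes)
        dps = extract_decision_points(timelines, config, codes)
        got = {(r.patient_id, r.index_date) for r in dps.itertuples()}
        expected = {
            (pid, d)
            for pid, tl in timelines.items()
            for d in brute_force_lab_dps(tl, config, codes)
        }
        assert got == expected

    def test_threshold_monotonicity(self, htn_config, codes):
        timelines = random_timelines(3, n_patients=30, codes=codes)
        counts = []
        for sbp in [140.0, 150.0, 160.0]:
            thresholds = [
                dataclasses.replace(htn_config.thresholds[0], value=sbp),
                htn_config.thresholds[1],
            ]
            config = dataclasses.replace(htn_config, thresholds=thresholds)
            counts.append(len(extract_decision_points(timelines, config, codes)))
        assert counts == sorted(counts, reverse=True)
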