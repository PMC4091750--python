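from datetime import date, timedelta

import pytest

from pipscreen.engine import (
    EngineConfig,
    build_drug_eras,
    detect_duplication,
    evaluate_criterion,
    screen_cohort,
    screen_record,
)
from pipscreen.simulate import SimConfig, default_planting_rates, generate_cohort

from conftest import WINDOW, make_dx, make_record, make_rx


class TestEraConstruction:
    def test_small_gap_merges_into_one_era(self, codebook):
        # two 28-day scripts, second issued 10 days after first expires
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 2, 1), strength=30),
            make_rx("P1", "d_simvastatin", date(2007, 3, 11), strength=30),
        ]
        eras = build_drug_eras(rxs, codebook, max_gap_days=14)
        assert len(eras) == 1
        assert eras[0].days == 66  # 28 + 10-day bridged gap + 28

    def test_large_gap_splits_eras(self, codebook):
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 2, 1), strength=30),
            make_rx("P1", "d_simvastatin", date(2007, 4, 30), strength=30),  # 60-day gap
        ]
        eras = build_drug_eras(rxs, codebook, max_gap_days=14)
        assert len(eras) == 2

    def test_avg_ddd_per_day(self, codebook):
        # omeprazole DDD=20; 20 mg x 2/day for 28 days -> 2 DDD/day
        rxs = [make_rx("P1", "d_omeprazole", date(2007, 2, 1), strength=20, daily_units=2)]
        (era,) = build_drug_eras(rxs, codebook)
        assert era.avg_ddd_per_day == pytest.approx(2.0)
        assert era.avg_mass_per_day == pytest.approx(40.0)

    def test_unknown_code_skipped(self, codebook):
        rxs = [make_rx("P1", "d_mystery", date(2007, 2, 1), strength=10)]
        assert build_drug_eras(rxs, codebook) == []

    def test_class_level_pools_codes(self, codebook):
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 2, 1), strength=30),
            make_rx("P1", "d_atorvastatin", date(2007, 2, 10), strength=20),
        ]
        assert len(build_drug_eras(rxs, codebook, level="class")) == 1
        assert len(build_drug_eras(rxs, codebook, level="code")) == 2


class TestCriterionEvaluation:
    def test_no_prescriptions_fires_nothing(self, codebook, pack):
        record = make_record(diagnoses=[make_dx("P1", "c_gout", date(2005, 1, 1))])
        assert screen_record(record, pack, codebook, WINDOW) == []

    def test_thiazide_with_gout_fires(self, codebook, pack):
        record = make_record(
            prescriptions=[make_rx("P1", "d_bendroflumethiazide", date(2007, 3, 1), strength=2.5)],
            diagnoses=[make_dx("P1", "c_gout", date(2004, 6, 1))],
        )
        criterion = pack.get("cv_thiazide_gout")
        eras = build_drug_eras(record.prescriptions, codebook)
        (event,) = evaluate_criterion(record, criterion, eras, WINDOW, codebook)
        assert event.first_trigger_date == date(2007, 3, 1)

    def test_thiazide_without_gout_silent(self, codebook, pack):
        record = make_record(
            prescriptions=[make_rx("P1", "d_bendroflumethiazide", date(2007, 3, 1), strength=2.5)]
        )
        criterion = pack.get("cv_thiazide_gout")
        eras = build_drug_eras(record.prescriptions, codebook)
        assert evaluate_criterion(record, criterion, eras, WINDOW, codebook) == []

    @pytest.mark.parametrize(
        "daily_units,should_fire",
        [(1.9, False), (2.0, True)],  # "maximum therapeutic dosage" boundary at 2 DDD/day
    )
    def test_ppi_max_dose_duration_boundary(self, codebook, pack, daily_units, should_fire):
        # 70-day omeprazole era (20 mg units, DDD 20) with a peptic ulcer history;
        # rule needs >8 weeks at >=2.0 DDD/day
        rxs = [
            make_rx("P1", "d_omeprazole", date(2007, 2, 1) + timedelta(days=35 * i),
                    strength=20, daily_units=daily_units, days=35)
            for i in range(2)
        ]
        record = make_record(
            prescriptions=rxs, diagnoses=[make_dx("P1", "c_peptic_ulcer", date(2003, 1, 1))]
        )
        criterion = pack.get("gi_ppi_max_dose_8w")
        eras = build_drug_eras(record.prescriptions, codebook)
        events = evaluate_criterion(record, criterion, eras, WINDOW, codebook)
        assert bool(events) is should_fire
        if should_fire:
            # 57th day of qualifying exposure
            assert events[0].first_trigger_date == date(2007, 2, 1) + timedelta(days=56)

    def test_digoxin_strictly_above_threshold(self, codebook, pack):
        criterion = pack.get("cv_digoxin_high_dose")
        at_threshold = make_record(
            prescriptions=[make_rx("P1", "d_digoxin", date(2007, 3, 1), strength=125)]
        )
        eras = build_drug_eras(at_threshold.prescriptions, codebook)
        assert evaluate_criterion(at_threshold, criterion, eras, WINDOW, codebook) == []
        above = make_record(
            prescriptions=[make_rx("P1", "d_digoxin", date(2007, 3, 1), strength=250)]
        )
        eras = build_drug_eras(above.prescriptions, codebook)
        assert len(evaluate_criterion(above, criterion, eras, WINDOW, codebook)) == 1

    def test_protective_co_drug_suppresses(self, codebook, pack):
        # aspirin + warfarin fires; adding a concurrent PPI legitimately suppresses it
        base = [
            make_rx("P1", "d_aspirin", date(2007, 3, 1), strength=75, days=56),
            make_rx("P1", "d_warfarin", date(2007, 3, 1), strength=3, days=56),
        ]
        criterion = pack.get("cv_aspirin_warfarin_no_gastro")
        record = make_record(prescriptions=base)
        eras = build_drug_eras(record.prescriptions, codebook)
        assert len(evaluate_criterion(record, criterion, eras, WINDOW, codebook)) == 1
        shielded = make_record(
            prescriptions=base + [make_rx("P1", "d_omeprazole", date(2007, 2, 20), strength=20, days=90)]
        )
        eras = build_drug_eras(shielded.prescriptions, codebook)
        assert evaluate_criterion(shielded, criterion, eras, WINDOW, codebook) == []

    def test_fall_recency_window(self, codebook, pack):
        criterion = pack.get("falls_benzodiazepine")
        rx = [make_rx("P1", "d_diazepam", date(2007, 6, 1), strength=10)]
        recent = make_record(prescriptions=rx, diagnoses=[make_dx("P1", "c_fall", date(2007, 4, 15))])
        eras = build_drug_eras(recent.prescriptions, codebook)
        assert len(evaluate_criterion(recent, criterion, eras, WINDOW, codebook)) == 1
        stale = make_record(prescriptions=rx, diagnoses=[make_dx("P1", "c_fall", date(2006, 6, 1))])
        eras = build_drug_eras(stale.prescriptions, codebook)
        assert evaluate_criterion(stale, criterion, eras, WINDOW, codebook) == []

    def test_sex_restriction(self, codebook, pack):
        criterion = pack.get("uri_alpha_blocker_incontinence")
        rx = [make_rx("P1", "d_doxazosin", date(2007, 5, 1), strength=4)]
        dx = [make_dx("P1", "c_incontinence", date(2006, 1, 1))]
        male = make_record(prescriptions=rx, diagnoses=dx, sex="male")
        eras = build_drug_eras(male.prescriptions, codebook)
        assert len(evaluate_criterion(male, criterion, eras, WINDOW, codebook)) == 1
        female = make_record(prescriptions=rx, diagnoses=dx, sex="female")
        assert evaluate_criterion(female, criterion, eras, WINDOW, codebook) == []

    def test_excluded_condition_blocks_aspirin_rule(self, codebook, pack):
        criterion = pack.get("cv_aspirin_no_indication")
        rx = [make_rx("P1", "d_aspirin", date(2007, 3, 1), strength=75)]
        unindicated = make_record(prescriptions=rx)
        eras = build_drug_eras(rx, codebook)
        assert len(evaluate_criterion(unindicated, criterion, eras, WINDOW, codebook)) == 1
        indicated = make_record(prescriptions=rx, diagnoses=[make_dx("P1", "c_mi", date(2001, 1, 1))])
        assert evaluate_criterion(indicated, criterion, eras, WINDOW, codebook) == []


class TestDuplication:
    def _eras(self, codebook, rxs):
        return build_drug_eras(rxs, codebook, level="code")

    def _groups(self, codebook, eras):
        return {e.key: g for e in eras if (g := codebook.duplication_group(e.key)) is not None}

    def test_two_statins_overlapping_40_days_fire(self, codebook, pack):
        criterion = pack.get("dup_therapeutic_duplication")
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 3, 1), strength=30, days=60),
            make_rx("P1", "d_atorvastatin", date(2007, 3, 21), strength=20, days=40),
        ]
        record = make_record(prescriptions=rxs)
        eras = self._eras(codebook, rxs)
        (event,) = detect_duplication(record, eras, self._groups(codebook, eras), 28, WINDOW, criterion)
        # overlap starts 21 March; 28th overlapping day
        assert event.first_trigger_date == date(2007, 3, 21) + timedelta(days=27)

    def test_same_drug_twice_is_not_duplication(self, codebook, pack):
        criterion = pack.get("dup_therapeutic_duplication")
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 3, 1), strength=30, days=60),
            make_rx("P1", "d_simvastatin", date(2007, 3, 10), strength=30, days=60),
        ]
        record = make_record(prescriptions=rxs)
        eras = self._eras(codebook, rxs)
        assert detect_duplication(record, eras, self._groups(codebook, eras), 28, WINDOW, criterion) == []

    def test_switch_artifact_below_floor_silent(self, codebook, pack):
        criterion = pack.get("dup_therapeutic_duplication")
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 3, 1), strength=30, days=28),
            make_rx("P1", "d_atorvastatin", date(2007, 3, 22), strength=20, days=28),  # 7-day overlap
        ]
        record = make_record(prescriptions=rxs)
        eras = self._eras(codebook, rxs)
        assert detect_duplication(record, eras, self._groups(codebook, eras), 28, WINDOW, criterion) == []

    def test_different_groups_never_pair(self, codebook, pack):
        criterion = pack.get("dup_therapeutic_duplication")
        rxs = [
            make_rx("P1", "d_simvastatin", date(2007, 3, 1), strength=30, days=60),
            make_rx("P1", "d_citalopram", date(2007, 3, 1), strength=20, days=60),
        ]
        record = make_record(prescriptions=rxs)
        eras = self._eras(codebook, rxs)
        assert detect_duplication(record, eras, self._groups(codebook, eras), 28, WINDOW, criterion) == []


class TestCohortScreening:
    def test_subset_events_contained_in_full_pack(self, codebook, pack, pack28):
        cfg = SimConfig(n_patients=60, seed=9, planting_rates=default_planting_rates(pack))
        cohort, _ = generate_cohort(cfg, codebook, pack)
        full = screen_cohort(cohort, pack, codebook, WINDOW)
        sub = screen_cohort(cohort, pack28, codebook, WINDOW)
        full_set = {(e.patient_id, e.criterion_id) for e in full.events}
        sub_set = {(e.patient_id, e.criterion_id) for e in sub.events}
        assert sub_set <= full_set

    def test_deterministic_rerun(self, codebook, pack):
        cfg = SimConfig(n_patients=30, seed=12, planting_rates=default_planting_rates(pack))
        cohort, _ = generate_cohort(cfg, codebook, pack)
        first = screen_cohort(cohort, pack, codebook, WINDOW)
        second = screen_cohort(cohort, pack, codebook, WINDOW)
        assert first.events == second.events

    def test_empty_cohort(self, codebook, pack):
        result = screen_cohort({}, pack, codebook, WINDOW)
        assert result.events == [] and result.n_patients == 0

    def test_at_most_one_event_per_patient_criterion(self, codebook, pack):
        cfg = SimConfig(n_patients=80, seed=21, planting_rates=default_planting_rates(pack))
        cohort, _ = generate_cohort(cfg, codebook, pack)
        result = screen_cohort(cohort, pack, codebook, WINDOW)
        keys = [(e.patient_id, e.criterion_id) for e in result.events]
        assert len(keys) == len(set(keys))
        for event in result.events:
            assert WINDOW.start <= event.first_trigger_date < WINDOW.end
            assert event.evidence


class TestMonotonicity:
    def test_adding_prescriptions_never_removes_nondose_events(self, codebook, pack):
        """Extra exposure can only add events, except protective suppression
        (tested above) and dose rules, whose era-average dose an extra
        low-dose script can dilute."""
        rxs = [
            make_rx("P1", "d_bendroflumethiazide", date(2007, 3, 1), strength=2.5),
            make_rx("P1", "d_amitriptyline", date(2007, 5, 1), strength=75),
        ]
        record = make_record(
            prescriptions=rxs,
            diagnoses=[make_dx("P1", "c_gout", date(2004, 6, 1)), make_dx("P1", "c_constipation", date(2005, 2, 1))],
        )
        before = {e.criterion_id for e in screen_record(record, pack, codebook, WINDOW)}
        extra = make_rx("P1", "d_codeine", date(2007, 5, 1), strength=30, days=28)
        grown = make_record(
            prescriptions=rxs + [extra],
            diagnoses=list(record.diagnoses),
        )
        after = {e.criterion_id for e in screen_record(grown, pack, codebook, WINDOW)}
        assert before <= after
        assert "cns_tca_opioid_or_ccb" in after - before  # the co-prescription now present
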