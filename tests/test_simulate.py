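import filecmp

import pytest
from scipy.stats import binom

from pipscreen.engine import screen_cohort
from pipscreen.model import PatientRecord
from pipscreen.simulate import (
    CohortGenerator,
    SimConfig,
    SimConfigError,
    TruthLabels,
    default_planting_rates,
    generate_cohort,
    write_synthetic,
)

from conftest import WINDOW, make_patient


def binomial_bounds_99(n: int, p: float) -> tuple[int, int]:
    """Exact binomial central 99% bounds on the observed count."""
    return int(binom.ppf(0.005, n, p)), int(binom.ppf(0.995, n, p))


class TestConfigValidation:
    def test_unknown_criterion_key_rejected(self, codebook, pack):
        cfg = SimConfig(n_patients=5, planting_rates={"no_such_rule": 0.5})
        with pytest.raises(SimConfigError, match="no_such_rule"):
            CohortGenerator(cfg, codebook, pack)

    def test_rate_outside_unit_interval_rejected(self, codebook, pack):
        cfg = SimConfig(n_patients=5, planting_rates={"dup_therapeutic_duplication": 1.5})
        with pytest.raises(SimConfigError):
            CohortGenerator(cfg, codebook, pack)

    def test_weights_must_sum_to_one(self, codebook, pack):
        cfg = SimConfig(n_patients=5, sex_weights={"male": 0.5, "female": 0.4, "missing": 0.0})
        with pytest.raises(SimConfigError):
            CohortGenerator(cfg, codebook, pack)


class TestNegativeControls:
    def test_no_planting_yields_no_events(self, codebook, pack):
        cfg = SimConfig(n_patients=100, seed=7, planting_rates={})
        cohort, truth = generate_cohort(cfg, codebook, pack)
        result = screen_cohort(cohort, pack, codebook, cfg.window)
        assert result.events == []
        assert truth.expected_events() == set()

    def test_near_misses_do_not_fire(self, codebook, pack):
        cfg = SimConfig(n_patients=100, seed=13, planting_rates={}, near_miss_rate=1.0)
        cohort, _ = generate_cohort(cfg, codebook, pack)
        result = screen_cohort(cohort, pack, codebook, cfg.window)
        assert result.events == []


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path, codebook, pack):
        cfg = SimConfig(n_patients=40, seed=5, planting_rates=default_planting_rates(pack))
        for run in ("a", "b"):
            cohort, truth = generate_cohort(cfg, codebook, pack)
            write_synthetic(cohort, truth, tmp_path / run)
        for name in ("patient.csv", "therapy.csv", "clinical.csv", "truth_labels.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path, codebook, pack):
        rates = default_planting_rates(pack)
        a, _ = generate_cohort(SimConfig(n_patients=40, seed=5, planting_rates=rates), codebook, pack)
        b, _ = generate_cohort(SimConfig(n_patients=40, seed=6, planting_rates=rates), codebook, pack)
        assert any(a[p].prescriptions != b[p].prescriptions for p in a)


class TestConstructivePlanting:
    def test_every_criterion_is_plantable_and_fires(self, codebook, pack):
        """Planting is constructive and engine-verified for each rule."""
        import numpy as np

        cfg = SimConfig(n_patients=1, seed=0)
        generator = CohortGenerator(cfg, codebook, pack)
        for criterion in pack:
            sex = criterion.sex_restriction or "female"
            record = PatientRecord(patient=make_patient(pid="PX", sex=sex))
            rng = np.random.default_rng(42)
            generator.plant_criterion(record, criterion, rng)
            fired = generator._fired_among(record, [criterion.criterion_id])
            assert fired == {criterion.criterion_id}, criterion.criterion_id

    def test_truth_labels_roundtrip_json(self, tmp_path, codebook, pack):
        cfg = SimConfig(n_patients=20, seed=3, planting_rates=default_planting_rates(pack))
        cohort, truth = generate_cohort(cfg, codebook, pack)
        paths = write_synthetic(cohort, truth, tmp_path)
        back = TruthLabels.from_json(paths["truth"])
        assert back == truth


class TestMarginalRecovery:
    def test_age_sex_frequencies_within_binomial_bounds(self, codebook, pack):
        n = 500
        cfg = SimConfig(n_patients=n, seed=17)
        cohort, _ = generate_cohort(cfg, codebook, pack)
        from pipscreen.covariates import age_band

        bands = [age_band(r.patient.birth_year, WINDOW) for r in cohort.values()]
        for band, p in cfg.age_band_weights.items():
            low, high = binomial_bounds_99(n, p)
            assert low <= bands.count(band) <= high, band
        sexes = [r.patient.sex for r in cohort.values()]
        for sex, p in cfg.sex_weights.items():
            low, high = binomial_bounds_99(n, p)
            assert low <= sexes.count(sex) <= high, sex

    def test_condition_prevalence_within_binomial_bounds(self, codebook, pack):
        n = 500
        cfg = SimConfig(n_patients=n, seed=19)
        cohort, _ = generate_cohort(cfg, codebook, pack)
        for concept in ("cond:diabetes", "cond:hypertension", "cond:copd"):
            count = sum(
                1
                for record in cohort.values()
                if any(codebook.resolve_concept(d.condition_code) == concept for d in record.diagnoses)
            )
            low, high = binomial_bounds_99(n, cfg.condition_prevalences[concept])
            assert low <= count <= high, concept
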