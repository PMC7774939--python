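"""Engine correctness: oracles, reproducibility, cross-engine agreement."""

import dataclasses

import numpy as np
import pytest

import opmdsim as om
from opmdsim.engine import C_POST_EARLY, N_COMP
from opmdsim.parameters import Param


def _disease_free(params):
    p = params
    for name in (
        "prevalence_malignant", "prevalence_mild", "prevalence_moderate",
        "prevalence_severe", "p_regress_mild_benign", "p_mild_to_moderate",
        "p_mt_moderate", "p_mt_low_risk", "p_mt_high_risk", "p_mt_severe",
        "p_early_to_late", "p_late_to_mets", "p_death_mets",
    ):
        p = dataclasses.replace(p, **{name: Param(0.0, 0.0, 1.0)})
    return p


class TestCohortEngine:
    def test_disease_off_equals_actuarial_oracle(self, params, table, calib):
        """With all disease dynamics disabled, the engine reduces to the
        closed-form actuarial life expectancy."""
        p = _disease_free(params)
        res = om.run_cohort_expectation(p, om.make_strategy(1), table, calibration=calib)
        assert res.life_years_mean == pytest.approx(
            om.remaining_life_expectancy(table, 60), abs=1e-9
        )

    def test_base_case_strategy3_regression_pin(self, params, table, calib):
        res = om.run_cohort_expectation(params, om.make_strategy(3), table, calibration=calib)
        assert res.life_years_mean == pytest.approx(20.8467254, abs=1e-6)

    def test_le_bounded_by_background(self, cohort_results, table):
        background = om.remaining_life_expectancy(table, 60)
        for r in cohort_results:
            assert 0 < r.life_years_mean <= background

    def test_events_are_nonnegative_and_consistent(self, cohort_results):
        for r in cohort_results:
            assert all(v >= -1e-15 for v in r.events_per_patient.values())
            ev = r.events_per_patient
            assert ev["biopsy_benign"] <= ev["biopsy"] + 1e-12
            treated = ev["treated_dysplasia"] + ev["treated_early"] + ev["treated_late"]
            assert treated <= ev["surgery"] + 1e-12

    def test_absorbing_only_dynamics(self, params, table):
        """A cohort entering at certain monthly death lives half a cycle."""
        init = np.zeros(N_COMP)
        init[C_POST_EARLY] = 1.0
        calib = om.CalibratedMortality(early=1.0, late=1.0)
        res = om.run_cohort_expectation(
            params, om.make_strategy(1), table, calibration=calib, initial_mass=init
        )
        assert res.life_years_mean == pytest.approx(0.0416667, abs=1e-6)

    def test_monotone_in_severe_transformation_rate(self, params, table):
        les = []
        for v in (0.042, 0.084, 0.168):
            q = params.with_overrides(p_mt_severe=v)
            les.append(om.run_cohort_expectation(q, om.make_strategy(8), table).life_years_mean)
        assert les[0] >= les[1] >= les[2]

    @pytest.mark.parametrize("sid", [3, 6, 8])
    def test_monotone_in_adherence(self, params, table, calib, sid):
        les = []
        for a in (0.5, 0.75, 1.0):
            q = params.with_overrides(joint_adherence=a)
            les.append(
                om.run_cohort_expectation(q, om.make_strategy(sid), table, calibration=calib).life_years_mean
            )
        assert les[0] <= les[1] <= les[2]


class TestMicrosimulation:
    def test_seeded_bit_reproducibility(self, params, table, calib):
        a = om.run_microsimulation(params, om.make_strategy(6), table, n=2000, seed=7, calibration=calib)
        b = om.run_microsimulation(params, om.make_strategy(6), table, n=2000, seed=7, calibration=calib)
        assert a.life_years_mean == b.life_years_mean
        assert (a.life_years == b.life_years).all()
        assert a.events_per_patient == b.events_per_patient

    def test_common_random_numbers_share_background_deaths(self, params, table, calib):
        """Disease-free patients die at identical ages across strategies run
        at the same seed (shared initial-state and background streams)."""
        p = _disease_free(params)
        r1 = om.run_microsimulation(p, om.make_strategy(1), table, n=3000, seed=9, calibration=calib)
        r2 = om.run_microsimulation(p, om.make_strategy(2), table, n=3000, seed=9, calibration=calib)
        assert (r1.life_years == r2.life_years).all()

    def test_disease_off_matches_oracle_within_mc_error(self, params, table, calib):
        p = _disease_free(params)
        res = om.run_microsimulation(p, om.make_strategy(1), table, n=100_000, seed=5, calibration=calib)
        oracle = om.remaining_life_expectancy(table, 60)
        assert abs(res.life_years_mean - oracle) < 3 * res.life_years_se

    def test_person_months_accounting(self, params, table, calib):
        res = om.run_microsimulation(params, om.make_strategy(3), table, n=5000, seed=3, calibration=calib)
        assert res.life_years_mean == pytest.approx(float(res.life_years.mean()))
        assert np.all(res.life_years >= 0.5 / 12 - 1e-12)
        assert np.all(res.life_years <= 50.2)
        # every patient dies exactly once
        deaths = (
            res.events_per_patient["death_other"]
            + res.events_per_patient["death_cancer"]
            + res.events_per_patient["death_surgical"]
        )
        assert deaths == pytest.approx(1.0, abs=1e-12)


class TestValidationSubmodel:
    def test_no_disease_no_hr_reduces_to_background(self, table):
        le = om.huang_validation_submodel(table, non_cancer_hr=1.0, stage_survival=1.0)
        assert le == pytest.approx(om.remaining_life_expectancy(table, 53), abs=1e-9)

    def test_hr_reduces_life_expectancy(self, table):
        assert om.huang_validation_submodel(table) < om.huang_validation_submodel(
            table, non_cancer_hr=1.0
        )

    def test_pinned_value(self, table):
        assert om.huang_validation_submodel(table) == pytest.approx(19.7972, abs=1e-4)
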