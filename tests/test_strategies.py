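"""Strategy catalog, surveillance scheduling, and decision-flow behaviour."""

import numpy as np
import pytest

import opmdsim as om
from opmdsim.engine import EVENTS
from opmdsim.states import HealthState as S
from opmdsim.strategies import (
    PHASE_DONE,
    InitialAction,
    SurveillanceSchedule,
    SurveillanceTest,
    initial_branches,
    management_branches,
    treatment_branches,
    visit_branches,
)

_EV = {name: i for i, name in enumerate(EVENTS)}


def _perfect(params):
    """All tests perfect, all adherence certain."""
    return params.with_overrides(
        adherence_biopsy=1.0,
        adherence_surveillance=1.0,
        p_rebiopsy_prior_benign=1.0,
        sens_biopsy=1.0,
        sens_pococt_benign_mild=1.0,
        spec_pococt_benign_mild=1.0,
        sens_pococt_mild_moderate=1.0,
        spec_pococt_mild_moderate=1.0,
        sens_visual_cancer=1.0,
        sens_visual_dysplasia=1.0,
        spec_visual=1.0,
        visual_sens_severe=1.0,
    )


class TestCatalog:
    def test_deferral_has_no_surveillance(self):
        s = om.make_strategy(1)
        assert s.initial_action == InitialAction.DEFER and s.schedule is None

    def test_strategy_2_no_surveillance_option(self):
        s = om.make_strategy(2)
        assert s.initial_action == InitialAction.REFER_BIOPSY
        assert s.surveillance_test == SurveillanceTest.NONE and s.schedule is None

    def test_strategy_3_biopsy_any_dysplasia_visual(self):
        s = om.make_strategy(3)
        assert s.initial_action == InitialAction.REFER_BIOPSY
        assert s.treatment_threshold == S.MILD_DYSPLASIA
        assert s.surveillance_test == SurveillanceTest.VISUAL

    def test_strategy_6_pairs_split_and_threshold(self):
        s = om.make_strategy(6)
        assert s.split == om.SplitName.MILD_MODERATE
        assert s.treatment_threshold == S.MODERATE_DYSPLASIA_LOW
        assert s.surveillance_test == SurveillanceTest.POCOCT

    def test_strategy_8_severe_threshold(self):
        s = om.make_strategy(8)
        assert s.split == om.SplitName.MODERATE_SEVERE
        assert s.treatment_threshold == S.SEVERE_DYSPLASIA

    @pytest.mark.parametrize("sid", [5, 6, 7, 8])
    def test_pococt_strategies_surveil_with_pococt(self, sid):
        assert om.make_strategy(sid).surveillance_test == SurveillanceTest.POCOCT

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            om.make_strategy(9)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            SurveillanceSchedule(visit_months=(6, 6, 24, 36, 48, 60))
        with pytest.raises(ValueError):
            SurveillanceSchedule(visit_months=(6, 12, 24))
        assert SurveillanceSchedule().visit_months == (6, 12, 24, 36, 48, 60)


class TestBranches:
    def test_branch_probabilities_sum_to_one(self, params):
        for sid in range(1, 9):
            strat = om.make_strategy(sid)
            for lesion in (S.BENIGN, S.MILD_DYSPLASIA, S.SEVERE_DYSPLASIA, S.LATE_CANCER_UNDETECTED):
                br = initial_branches(lesion, strat, params)
                assert sum(p for p, _ in br) == pytest.approx(1.0, abs=1e-12)
                if strat.schedule is not None:
                    br = visit_branches(lesion, False, strat, 0, params)
                    assert sum(p for p, _ in br) == pytest.approx(1.0, abs=1e-12)

    def test_no_management_on_off_months(self, params):
        strat = om.make_strategy(6)
        assert management_branches(S.MILD_DYSPLASIA, 0, False, strat, 3, params) is None
        assert management_branches(S.MILD_DYSPLASIA, 1, False, strat, 6, params) is None
        assert management_branches(S.MILD_DYSPLASIA, 0, False, strat, 6, params) is not None

    def test_negative_initial_pococt_enters_surveillance_as_benign(self, params):
        """A negative cycle-0 POCOCT result schedules surveillance at month 6
        with the lesion categorized benign."""
        p = _perfect(params)
        br = initial_branches(S.BENIGN, om.make_strategy(6), p)
        [(prob, outcome)] = br
        assert prob == 1.0
        assert outcome[0] == "cont" and outcome[1] == 0 and outcome[2] is True

    def test_treatment_outcomes(self, params):
        br = dict()
        for p, (kind, state, evs) in treatment_branches(S.MILD_DYSPLASIA, params):
            br[state] = p
        assert br[S.POST_TREATMENT_DYSPLASIA] == pytest.approx(0.998)
        assert br[S.DEAD_OTHER] == pytest.approx(0.002)

    def test_certain_surgical_mortality(self, params):
        p = params.with_overrides(p_surgical_mortality=1.0)
        rng = np.random.default_rng(0)
        assert om.apply_treatment(S.SEVERE_DYSPLASIA, p, rng) == S.DEAD_OTHER

    def test_treating_the_dead_is_an_error(self, params):
        with pytest.raises(ValueError):
            om.apply_treatment(S.DEAD_CANCER, params, np.random.default_rng(0))

    def test_next_action_samples_treatment_under_perfect_conditions(self, params):
        p = _perfect(params)
        rng = np.random.default_rng(1)
        act = om.next_action(S.MODERATE_DYSPLASIA_HIGH, 0, False, om.make_strategy(6), 0, p, rng)
        assert act.treated and act.new_state == S.POST_TREATMENT_DYSPLASIA


class TestSimulatedPolicies:
    def test_strategy_2_false_negatives_never_retested(self, params, table, calib):
        """Without a surveillance option, no biopsy or test ever happens
        after cycle 0."""
        res = om.run_cohort_expectation(params, om.make_strategy(2), table, calibration=calib)
        assert res.events_by_month[1:, _EV["biopsy"]].sum() == 0.0
        assert res.events_by_month[1:, _EV["test"]].sum() == 0.0

    @pytest.mark.parametrize("sid", [3, 6, 8])
    def test_surveillance_ends_at_month_60(self, params, table, calib, sid):
        res = om.run_cohort_expectation(params, om.make_strategy(sid), table, calibration=calib)
        assert res.events_by_month[61:, _EV["test"]].sum() == 0.0
        assert res.events_by_month[61:, _EV["biopsy"]].sum() == 0.0

    def test_strategies_3_and_5_coincide_under_perfect_tests(self, params, table, calib):
        """With perfect tests and adherence the biopsy-vs-POCOCT distinction
        vanishes: identical life expectancy and treatment flows."""
        p = _perfect(params)
        r3 = om.run_cohort_expectation(p, om.make_strategy(3), table, calibration=calib)
        r5 = om.run_cohort_expectation(p, om.make_strategy(5), table, calibration=calib)
        assert r3.life_years_mean == pytest.approx(r5.life_years_mean, abs=1e-12)
        for ev in ("treated_dysplasia", "treated_early", "treated_late", "death_cancer"):
            assert r3.events_per_patient[ev] == pytest.approx(r5.events_per_patient[ev], abs=1e-12)

    def test_perfect_conditions_treat_all_high_grade_by_month_6(self, params, table, calib):
        """Every patient at or above the treatment threshold reaches surgery
        immediately at cycle 0 when tests and adherence are perfect."""
        p = _perfect(params)
        res = om.run_cohort_expectation(p, om.make_strategy(6), table, calibration=calib)
        treated_m0 = res.events_by_month[0, [_EV["treated_dysplasia"], _EV["treated_early"], _EV["treated_late"]]].sum()
        eligible = 0.0440 + 0.0288 + 0.05
        survives_cycle = 1.0 - om.monthly_background_mortality(table, 60.0)
        expected = eligible * survives_cycle * (1.0 - 0.002)
        assert treated_m0 == pytest.approx(expected, abs=1e-12)

    def test_deferral_presentation_rate(self, params):
        """Undetected localized cancer presents at the monthly equivalent of
        the 13% annual visual-exam probability."""
        br = management_branches(S.EARLY_CANCER_UNDETECTED, PHASE_DONE, False, om.make_strategy(1), 17, params)
        p_present = sum(p for p, o in br if "presentation" in o[-1])
        assert p_present == pytest.approx(om.annual_to_monthly(0.13), abs=1e-12)
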