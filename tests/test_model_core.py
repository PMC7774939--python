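"""Parameter handling, initial mixture, and natural-history dynamics."""

import dataclasses

import pytest

import opmdsim as om
from opmdsim.parameters import PARAM_FIELDS, Param, ParameterSet
from opmdsim.states import HealthState as S
from opmdsim.states import LESION_STATES, TransitionContext
from opmdsim.transitions import natural_history_step, progression_branches


class TestParameterSet:
    def test_packaged_yaml_matches_defaults(self, params):
        assert params == ParameterSet()

    def test_prevalence_benign_is_complement(self, params):
        assert params.prevalence_benign == pytest.approx(0.7618, abs=1e-12)

    def test_invalid_prevalences_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(prevalence_malignant=Param(0.9, 0.0, 1.0))

    def test_base_outside_range_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(p_mt_severe=Param(0.2, 0.0, 0.1))

    def test_with_overrides_keeps_ranges(self, params):
        q = params.with_overrides(p_mt_severe=0.1)
        assert q.p_mt_severe.value == 0.1
        assert (q.p_mt_severe.low, q.p_mt_severe.high) == (0.042, 0.168)

    def test_joint_adherence_override(self, params):
        q = params.with_overrides(joint_adherence=0.88)
        assert q.adherence_surveillance.value == (0.88, 0.88, 0.88)
        assert q.adherence_biopsy.value == 0.88

    def test_override_widens_range_when_needed(self, params):
        q = params.with_overrides(p_rebiopsy_prior_benign=0.8)
        assert q.p_rebiopsy_prior_benign.value == 0.8

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(KeyError):
            params.with_overrides(not_a_param=0.5)

    def test_adherence_visit_mapping(self, params):
        assert [params.adherence_for_visit(k) for k in range(6)] == [
            0.92, 0.82, 0.72, 0.72, 0.72, 0.72,
        ]

    def test_yaml_roundtrip(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        params.to_yaml(path)
        assert ParameterSet.from_yaml(path) == params

    def test_dsa_ranges_cover_every_tabulated_parameter(self, params):
        assert set(params.dsa_ranges()) == set(PARAM_FIELDS)


class TestInitialDistribution:
    def test_base_case_masses(self, params):
        dist = om.initial_state_distribution(params)
        assert dist[S.BENIGN] == pytest.approx(0.7618, abs=1e-12)
        assert dist[S.EARLY_CANCER_UNDETECTED] == pytest.approx(0.013655, abs=1e-12)
        assert dist[S.LATE_CANCER_UNDETECTED] == pytest.approx(0.05 * 0.7269, abs=1e-12)
        assert dist[S.MODERATE_DYSPLASIA_LOW] == pytest.approx(0.0220, abs=1e-12)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_prevalences_all_benign(self, params):
        p = params
        for name in ("prevalence_malignant", "prevalence_mild", "prevalence_moderate", "prevalence_severe"):
            p = dataclasses.replace(p, **{name: Param(0.0, 0.0, 1.0)})
        dist = om.initial_state_distribution(p)
        assert dist[S.BENIGN] == 1.0


class TestNaturalHistory:
    @pytest.mark.parametrize("state", list(LESION_STATES) + [S.METASTATIC])
    def test_rows_sum_to_one(self, params, state):
        ctx = TransitionContext()
        dist = natural_history_step(state, params, ctx, 0.002)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in dist.values())

    def test_severe_transforms_at_monthly_rate(self, params):
        """Ignoring background death, severe dysplasia -> early cancer at
        the monthly equivalent of the 0.084 annual transformation rate."""
        dist = natural_history_step(S.SEVERE_DYSPLASIA, params, TransitionContext(), 0.0)
        assert dist[S.EARLY_CANCER_UNDETECTED] == pytest.approx(0.0072845, abs=1e-6)

    def test_benign_is_static(self, params):
        dist = natural_history_step(S.BENIGN, params, TransitionContext(), 0.002)
        assert set(dist) == {S.BENIGN, S.DEAD_OTHER}

    def test_certain_mets_death(self, params):
        p = dataclasses.replace(params, p_death_mets=Param(1.0, 0.0, 1.0))
        dist = natural_history_step(S.METASTATIC, p, TransitionContext(), 0.0)
        assert dist[S.DEAD_CANCER] == 1.0

    def test_absorbing_states_are_point_masses(self, params):
        for state in (S.DEAD_CANCER, S.DEAD_OTHER):
            assert natural_history_step(state, params, TransitionContext(), 0.5) == {state: 1.0}

    def test_context_scales_background_hazard(self, params):
        ctx = TransitionContext(non_cancer_mortality_hr=2.0)
        d1 = natural_history_step(S.BENIGN, params, TransitionContext(), 0.01)
        d2 = natural_history_step(S.BENIGN, params, ctx, 0.01)
        assert d2[S.DEAD_OTHER] == pytest.approx(1 - (1 - d1[S.DEAD_OTHER]) ** 2, abs=1e-12)

    def test_mild_branches(self, params):
        branches = {s: p for p, s, _ in progression_branches(S.MILD_DYSPLASIA, params)}
        assert branches[S.BENIGN] == pytest.approx(
            om.annual_to_monthly(0.04), rel=1e-3
        )
        assert S.MODERATE_DYSPLASIA_LOW in branches and S.MODERATE_DYSPLASIA_HIGH in branches


class TestTransitionContext:
    def test_validation(self):
        with pytest.raises(ValueError):
            TransitionContext(age_years=10)
        with pytest.raises(ValueError):
            TransitionContext(charlson_multiplier=0.0)
        with pytest.raises(ValueError):
            TransitionContext(sex="other")
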