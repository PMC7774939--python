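"""Monthly natural-history dynamics of untreated oral lesions.

Implements the state diagram: mild dysplasia regresses to benign or
progresses to moderate; moderate (low/high risk) and severe dysplasia
transform to undetected early cancer; early cancer progresses to late; late
cancer metastasizes; metastatic disease kills.  Every live state is exposed
to background (non-cancer) mortality.  All published annual probabilities
are converted to 1-month probabilities by constant-hazard compounding.
"""

from __future__ import annotations

from .parameters import ParameterSet
from .probability import annual_to_monthly, apply_competing_risks, scale_probability
from .states import ABSORBING_STATES, HealthState, TransitionContext

S = HealthState

#: Event tags attached to transition branches (consumed by the engines).
EV_MT = "mt"  # dysplasia transformed to cancer
EV_EARLY_TO_LATE = "early_to_late"
EV_NEW_METS = "new_mets"


def initial_state_distribution(params: ParameterSet) -> dict[HealthState, float]:
    """Initial true-state mixture of the simulated OPMD cohort.

    Cancer mass is split early/late by ``p_early_given_cancer``; moderate
    dysplasia splits low/high risk by ``moderate_low_fraction``.  Sums to 1
    within 1e-12.
    """
    p_mal = params.prevalence_malignant.value
    f_low = params.moderate_low_fraction
    dist = {
        S.BENIGN: params.prevalence_benign,
        S.MILD_DYSPLASIA: params.prevalence_mild.value,
        S.MODERATE_DYSPLASIA_LOW: params.prevalence_moderate.value * f_low,
        S.MODERATE_DYSPLASIA_HIGH: params.prevalence_moderate.value * (1.0 - f_low),
        S.SEVERE_DYSPLASIA: params.prevalence_severe.value,
        S.EARLY_CANCER_UNDETECTED: p_mal * params.p_early_given_cancer.value,
        S.LATE_CANCER_UNDETECTED: p_mal * (1.0 - params.p_early_given_cancer.value),
    }
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"initial distribution sums to {total}, not 1")
    return dist


def monthly_late_to_mets(params: ParameterSet) -> float:
    """Monthly late-cancer -> metastasis probability (override-aware)."""
    if params.monthly_late_to_mets_override is not None:
        return params.monthly_late_to_mets_override
    return annual_to_monthly(params.p_late_to_mets.value)


def monthly_mets_death(params: ParameterSet) -> float:
    p = params.p_death_mets.value
    return annual_to_monthly(p) if params.p_death_mets_is_annual else p


def progression_branches(
    state: HealthState, params: ParameterSet
) -> list[tuple[float, HealthState, tuple[str, ...]]]:
    """One-cycle lesion-progression distribution, conditional on survival.

    Returns ``(probability, next_state, event_tags)`` branches; death is
    handled separately by the engines so the branches here sum to 1.
    Metastatic and post-treatment states have no non-death moves.
    """
    a2m = annual_to_monthly
    f_low = params.moderate_low_fraction

    if state == S.BENIGN:
        p_up = a2m(params.p_benign_to_mild)
        if p_up == 0.0:
            return [(1.0, S.BENIGN, ())]
        return [(p_up, S.MILD_DYSPLASIA, ()), (1.0 - p_up, S.BENIGN, ())]

    if state == S.MILD_DYSPLASIA:
        dist = apply_competing_risks(
            [
                (S.BENIGN, a2m(params.p_regress_mild_benign.value)),
                ("moderate", a2m(params.p_mild_to_moderate.value)),
            ],
            stay=S.MILD_DYSPLASIA,
        )
        out = [(dist[S.MILD_DYSPLASIA], S.MILD_DYSPLASIA, ())]
        if dist.get(S.BENIGN, 0.0) > 0:
            out.append((dist[S.BENIGN], S.BENIGN, ()))
        p_mod = dist.get("moderate", 0.0)
        if p_mod > 0:
            out.append((p_mod * f_low, S.MODERATE_DYSPLASIA_LOW, ()))
            out.append((p_mod * (1.0 - f_low), S.MODERATE_DYSPLASIA_HIGH, ()))
        return out

    mt_rates = {
        S.MODERATE_DYSPLASIA_LOW: params.p_mt_low_risk.value,
        S.MODERATE_DYSPLASIA_HIGH: params.p_mt_high_risk.value,
        S.SEVERE_DYSPLASIA: params.p_mt_severe.value,
    }
    if state in mt_rates:
        p = a2m(mt_rates[state])
        return [
            (p, S.EARLY_CANCER_UNDETECTED, (EV_MT,)),
            (1.0 - p, state, ()),
        ]

    if state == S.EARLY_CANCER_UNDETECTED:
        p = a2m(params.p_early_to_late.value)
        return [
            (p, S.LATE_CANCER_UNDETECTED, (EV_EARLY_TO_LATE,)),
            (1.0 - p, state, ()),
        ]

    if state == S.LATE_CANCER_UNDETECTED:
        p = monthly_late_to_mets(params)
        return [(p, S.METASTATIC, (EV_NEW_METS,)), (1.0 - p, state, ())]

    # metastatic / post-treatment / absorbing: no non-death moves
    return [(1.0, state, ())]


def disease_death_prob(state: HealthState, params: ParameterSet, calibration=None) -> float:
    """Monthly cancer-specific death probability for a state.

    Metastatic disease uses the published metastatic death rate; treated
    cancer states use the calibrated stage-pooled monthly mortality (an
    object with ``early``/``late`` attributes).
    """
    if state == S.METASTATIC:
        return monthly_mets_death(params)
    if state == S.POST_TREATMENT_CANCER_EARLY:
        if calibration is None:
            raise ValueError("treated-cancer mortality requires a calibration")
        return calibration.early
    if state == S.POST_TREATMENT_CANCER_LATE:
        if calibration is None:
            raise ValueError("treated-cancer mortality requires a calibration")
        return calibration.late
    return 0.0


def natural_history_step(
    state: HealthState,
    params: ParameterSet,
    ctx: TransitionContext,
    background_monthly_mortality: float,
    calibration=None,
) -> dict[HealthState, float]:
    """One-cycle transition distribution for an untreated, unmonitored patient.

    ``background_monthly_mortality`` is the *unscaled* monthly probability of
    non-cancer death; the context's hazard multipliers are applied here.
    Deaths (background and disease) are combined as competing risks; the
    survivors follow :func:`progression_branches`.  Absorbing states return a
    point mass on themselves.  The result sums to 1 within 1e-12.
    """
    if state in ABSORBING_STATES:
        return {state: 1.0}

    p_other = scale_probability(background_monthly_mortality, ctx.mortality_multiplier)
    p_cancer = disease_death_prob(state, params, calibration)
    deaths = apply_competing_risks(
        [(S.DEAD_OTHER, p_other), (S.DEAD_CANCER, p_cancer)], stay="alive"
    )
    alive = deaths.pop("alive")

    dist: dict[HealthState, float] = {k: v for k, v in deaths.items() if v > 0}
    for p, nxt, _ in progression_branches(state, params):
        if p > 0:
            dist[nxt] = dist.get(nxt, 0.0) + alive * p
    return dist
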