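"""The eight OPMD management policies, surveillance scheduling and adherence.

A strategy is an initial action (defer / refer for biopsy / point-of-care
cytology at a diagnostic split), a histologic treatment threshold, and an
optional five-year surveillance schedule with per-visit adherence.  The
decision flow for one patient-month is expressed as *branches*: mutually
exclusive outcomes with probabilities and event tags, which both the
deterministic cohort engine and the microsimulation consume.

Branch outcomes are either
``("cont", phase, prior_benign, events)`` - the lesion remains untreated and
management bookkeeping is updated - or
``("moved", HealthState, events)`` - the patient was treated (post-treatment
state) or died of surgery.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .diagnostics import (
    SplitName,
    biopsy_call_branches,
    make_split,
    pococt_p_positive,
    visual_p_positive,
)
from .parameters import ParameterSet
from .probability import annual_to_monthly
from .states import HealthState

S = HealthState

#: Phase codes: 0..5 = awaiting surveillance visit with that index,
#: PHASE_DONE = no further scheduled testing ever.
N_VISITS = 6
PHASE_DONE = 6

# event tags
EV_TEST = "test"
EV_PRESENTATION = "presentation"
EV_BIOPSY = "biopsy"
EV_BIOPSY_BENIGN = "biopsy_benign"
EV_SURGERY = "surgery"
EV_DEATH_SURGICAL = "death_surgical"
EV_TREATED_BENIGN = "treated_benign"
EV_TREATED_DYSPLASIA = "treated_dysplasia"
EV_TREATED_EARLY = "treated_early"
EV_TREATED_LATE = "treated_late"


class InitialAction(Enum):
    DEFER = "defer"
    REFER_BIOPSY = "refer_biopsy"
    POCOCT = "pococt"


class SurveillanceTest(Enum):
    NONE = "none"
    VISUAL = "visual"
    POCOCT = "pococt"


@dataclass(frozen=True)
class SurveillanceSchedule:
    """Visits at 6 and 12 months, then annually to 5 years."""

    visit_months: tuple[int, ...] = (6, 12, 24, 36, 48, 60)

    def __post_init__(self) -> None:
        vm = self.visit_months
        if any(b <= a for a, b in zip(vm, vm[1:])):
            raise ValueError("visit months must be strictly increasing")
        if vm[-1] != 60:
            raise ValueError("surveillance must end at month 60")


@dataclass(frozen=True)
class Strategy:
    id: int
    label: str
    initial_action: InitialAction
    split: SplitName | None = None
    treatment_threshold: HealthState | None = None
    surveillance_test: SurveillanceTest = SurveillanceTest.NONE
    schedule: SurveillanceSchedule | None = None


_CATALOG: dict[int, Strategy] = {
    1: Strategy(
        1,
        "Deferral of evaluation; carcinomas present clinically",
        InitialAction.DEFER,
    ),
    2: Strategy(
        2,
        "Initial biopsy for all OPMDs, surgery for any dysplasia or carcinoma, no surveillance",
        InitialAction.REFER_BIOPSY,
        treatment_threshold=S.MILD_DYSPLASIA,
    ),
    3: Strategy(
        3,
        "Initial biopsy for all OPMDs, surgery for any dysplasia or carcinoma, visual surveillance of benign lesions",
        InitialAction.REFER_BIOPSY,
        treatment_threshold=S.MILD_DYSPLASIA,
        surveillance_test=SurveillanceTest.VISUAL,
        schedule=SurveillanceSchedule(),
    ),
    4: Strategy(
        4,
        "Initial biopsy for all OPMDs, surgery for moderate or worse, visual surveillance of benign/mild",
        InitialAction.REFER_BIOPSY,
        treatment_threshold=S.MODERATE_DYSPLASIA_LOW,
        surveillance_test=SurveillanceTest.VISUAL,
        schedule=SurveillanceSchedule(),
    ),
    5: Strategy(
        5,
        "POCOCT benign|mild split, surgery for any dysplasia or carcinoma, POCOCT surveillance of benign",
        InitialAction.POCOCT,
        split=SplitName.BENIGN_MILD,
        treatment_threshold=S.MILD_DYSPLASIA,
        surveillance_test=SurveillanceTest.POCOCT,
        schedule=SurveillanceSchedule(),
    ),
    6: Strategy(
        6,
        "POCOCT mild|moderate split, surgery for moderate or worse, POCOCT surveillance of benign/mild",
        InitialAction.POCOCT,
        split=SplitName.MILD_MODERATE,
        treatment_threshold=S.MODERATE_DYSPLASIA_LOW,
        surveillance_test=SurveillanceTest.POCOCT,
        schedule=SurveillanceSchedule(),
    ),
    7: Strategy(
        7,
        "POCOCT low|high risk split, surgery for high-risk dysplasia or carcinoma, POCOCT surveillance",
        InitialAction.POCOCT,
        split=SplitName.LOW_HIGH,
        treatment_threshold=S.MODERATE_DYSPLASIA_HIGH,
        surveillance_test=SurveillanceTest.POCOCT,
        schedule=SurveillanceSchedule(),
    ),
    8: Strategy(
        8,
        "POCOCT moderate|severe split, surgery for severe dysplasia or carcinoma, POCOCT surveillance",
        InitialAction.POCOCT,
        split=SplitName.MODERATE_SEVERE,
        treatment_threshold=S.SEVERE_DYSPLASIA,
        surveillance_test=SurveillanceTest.POCOCT,
        schedule=SurveillanceSchedule(),
    ),
}


def make_strategy(strategy_id: int) -> Strategy:
    """Catalog lookup for strategies 1-8."""
    try:
        return _CATALOG[strategy_id]
    except KeyError:
        raise ValueError(f"unknown strategy id {strategy_id}") from None


def all_strategies() -> list[Strategy]:
    return [make_strategy(i) for i in range(1, 9)]


# ----------------------------------------------------------------------
# branch construction


def treatment_branches(lesion: HealthState, params: ParameterSet):
    """Outcome of indicated surgery/cancer treatment for a true state.

    Surgical mortality applies per procedure and is classified as non-cancer
    death.  Surviving dysplasia patients are lesion-free afterwards; cancer
    patients carry the calibrated stage-pooled mortality of their stage at
    treatment.  Metastatic disease is not a surgical candidate.
    """
    if lesion == S.METASTATIC:
        return [(1.0, ("cont", PHASE_DONE, False, ()))]
    p_surg = params.p_surgical_mortality.value
    if lesion == S.EARLY_CANCER_UNDETECTED:
        post, ev = S.POST_TREATMENT_CANCER_EARLY, EV_TREATED_EARLY
    elif lesion == S.LATE_CANCER_UNDETECTED:
        post, ev = S.POST_TREATMENT_CANCER_LATE, EV_TREATED_LATE
    elif lesion == S.BENIGN:
        post, ev = S.POST_TREATMENT_DYSPLASIA, EV_TREATED_BENIGN
    else:
        post, ev = S.POST_TREATMENT_DYSPLASIA, EV_TREATED_DYSPLASIA
    branches = [(1.0 - p_surg, ("moved", post, (EV_SURGERY, ev)))]
    if p_surg > 0:
        branches.append((p_surg, ("moved", S.DEAD_OTHER, (EV_SURGERY, EV_DEATH_SURGICAL))))
    return branches


def _decide_from_biopsy(
    lesion: HealthState,
    strategy: Strategy,
    params: ParameterSet,
    after_phase: int,
    prefix: tuple[str, ...],
):
    """Histology call, threshold comparison, and treatment if indicated."""
    out = []
    thr = strategy.treatment_threshold
    for p_call, call in biopsy_call_branches(lesion, params):
        ev = prefix + (EV_BIOPSY,) + ((EV_BIOPSY_BENIGN,) if call == S.BENIGN else ())
        if call != S.BENIGN and thr is not None and call >= thr:
            for p_t, (kind, payload, t_ev) in treatment_branches(lesion, params):
                out.append((p_call * p_t, (kind, payload, ev + t_ev)))
        else:
            out.append((p_call, ("cont", after_phase, call == S.BENIGN, ev)))
    return out


def initial_branches(lesion: HealthState, strategy: Strategy, params: ParameterSet):
    """Cycle-0 decision flow (initial referral or point-of-care test)."""
    surv_phase = 0 if strategy.schedule is not None else PHASE_DONE

    if strategy.initial_action == InitialAction.DEFER:
        return [(1.0, ("cont", PHASE_DONE, False, ()))]

    if strategy.initial_action == InitialAction.REFER_BIOPSY:
        adh = params.adherence_biopsy.value
        out = []
        if adh < 1.0:
            out.append((1.0 - adh, ("cont", surv_phase, False, ())))
        for p, o in _decide_from_biopsy(lesion, strategy, params, surv_phase, ()):
            out.append((adh * p, o))
        return out

    # POCOCT initial characterization (chairside; no referral needed)
    split = make_split(strategy.split, params)
    p_pos = pococt_p_positive(lesion, split)
    adh = params.adherence_biopsy.value
    out = []
    if p_pos < 1.0:
        # a negative result categorizes the lesion as benign/low-risk
        out.append((1.0 - p_pos, ("cont", surv_phase, True, (EV_TEST,))))
    if p_pos > 0.0:
        if adh < 1.0:
            out.append((p_pos * (1.0 - adh), ("cont", surv_phase, False, (EV_TEST,))))
        for p, o in _decide_from_biopsy(lesion, strategy, params, surv_phase, (EV_TEST,)):
            out.append((p_pos * adh * p, o))
    return out


def visit_branches(
    lesion: HealthState,
    prior_benign: bool,
    strategy: Strategy,
    visit_index: int,
    params: ParameterSet,
):
    """Decision flow at a scheduled surveillance visit.

    Attendance is an independent per-visit draw; missing a visit does not
    cancel later ones.  A positive follow-up test leads to confirmatory
    biopsy subject to biopsy adherence, additionally gated by the
    re-biopsy-recommendation probability when the lesion was previously
    categorized benign.
    """
    nxt = visit_index + 1 if visit_index + 1 < N_VISITS else PHASE_DONE
    a = params.adherence_for_visit(visit_index)
    if strategy.surveillance_test == SurveillanceTest.VISUAL:
        p_pos = visual_p_positive(lesion, params)
    else:
        p_pos = pococt_p_positive(lesion, make_split(strategy.split, params))
    gate = params.adherence_biopsy.value * (
        params.p_rebiopsy_prior_benign.value if prior_benign else 1.0
    )

    out = []
    if a < 1.0:
        out.append((1.0 - a, ("cont", nxt, prior_benign, ())))
    p_no_biopsy = a * ((1.0 - p_pos) + p_pos * (1.0 - gate))
    if p_no_biopsy > 0:
        out.append((p_no_biopsy, ("cont", nxt, prior_benign, (EV_TEST,))))
    p_biopsy = a * p_pos * gate
    if p_biopsy > 0:
        for p, o in _decide_from_biopsy(lesion, strategy, params, nxt, (EV_TEST,)):
            out.append((p_biopsy * p, o))
    return out


def deferral_monthly_branches(lesion: HealthState, phase: int, params: ParameterSet):
    """Symptomatic presentation of undetected cancer in the deferral policy.

    Localized (early) cancer presents for a visual-tactile exam at annual
    probability 0.13, late-stage at 0.30; a positive exam leads directly to
    biopsy and treatment.  Returns None for states that do not present.
    """
    if lesion == S.EARLY_CANCER_UNDETECTED:
        p_pres = annual_to_monthly(params.p_visual_exam_no_screen_localized.value)
    elif lesion == S.LATE_CANCER_UNDETECTED:
        p_pres = annual_to_monthly(params.p_present_visual_no_screen_symptomatic.value)
    else:
        return None
    p_vis = visual_p_positive(lesion, params)
    out = [(1.0 - p_pres, ("cont", phase, False, ()))]
    if p_pres * (1.0 - p_vis) > 0:
        out.append((p_pres * (1.0 - p_vis), ("cont", phase, False, (EV_PRESENTATION, EV_TEST))))
    p_path = p_pres * p_vis
    if p_path > 0:
        for p_call, call in biopsy_call_branches(lesion, params):
            ev = (EV_PRESENTATION, EV_TEST, EV_BIOPSY) + (
                (EV_BIOPSY_BENIGN,) if call == S.BENIGN else ()
            )
            if call == S.BENIGN:
                out.append((p_path * p_call, ("cont", phase, False, ev)))
            else:
                for p_t, (kind, payload, t_ev) in treatment_branches(lesion, params):
                    out.append((p_path * p_call * p_t, (kind, payload, ev + t_ev)))
    return out


def management_branches(
    lesion: HealthState,
    phase: int,
    prior_benign: bool,
    strategy: Strategy,
    month: int,
    params: ParameterSet,
):
    """Management branches for one patient-month, or None if no event is due.

    Metastatic disease is never a management target (treatment would not
    change its mortality), so only untreated lesion states are handled.
    """
    if lesion == S.METASTATIC:
        return None
    if strategy.initial_action == InitialAction.DEFER:
        return deferral_monthly_branches(lesion, phase, params)
    if month == 0:
        return initial_branches(lesion, strategy, params)
    if (
        strategy.schedule is not None
        and phase < N_VISITS
        and month == strategy.schedule.visit_months[phase]
    ):
        return visit_branches(lesion, prior_benign, strategy, phase, params)
    return None


# ----------------------------------------------------------------------
# sampling wrapper


@dataclass(frozen=True)
class Action:
    """A sampled management outcome for one patient-month."""

    events: tuple[str, ...]
    treated: bool
    new_state: HealthState | None
    phase: int
    prior_benign: bool


def next_action(
    lesion: HealthState,
    phase: int,
    prior_benign: bool,
    strategy: Strategy,
    cycle: int,
    params: ParameterSet,
    rng: np.random.Generator,
) -> Action:
    """Sample the management decision flow for one patient-month."""
    branches = management_branches(lesion, phase, prior_benign, strategy, cycle, params)
    if branches is None:
        return Action((), False, None, phase, prior_benign)
    probs = np.array([p for p, _ in branches])
    idx = int(rng.choice(len(branches), p=probs / probs.sum()))
    kind, *payload = branches[idx][1]
    if kind == "cont":
        new_phase, pb, events = payload
        return Action(tuple(events), False, None, new_phase, pb)
    state, events = payload
    return Action(tuple(events), True, state, phase, prior_benign)


def apply_treatment(
    lesion: HealthState, params: ParameterSet, rng: np.random.Generator
) -> HealthState:
    """Sample the outcome of indicated treatment for a true state."""
    if lesion in (S.DEAD_CANCER, S.DEAD_OTHER):
        raise ValueError("cannot treat a dead patient")
    branches = treatment_branches(lesion, params)
    probs = np.array([p for p, _ in branches])
    idx = int(rng.choice(len(branches), p=probs / probs.sum()))
    outcome = branches[idx][1]
    if outcome[0] == "cont":
        return lesion
    return outcome[1]
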