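"""Diagnostic tests as stochastic classifiers of the true health state.

Three tests are modeled: the point-of-care oral cytopathology tool (POCOCT)
dichotomized at one of four diagnostic splits, the visual-tactile exam, and
scalpel biopsy with histopathology.  Each is characterized purely by the
operating characteristics reported for it; test results are conditionally
independent across repeat visits given the true state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .parameters import ParameterSet
from .states import (
    ABSORBING_STATES,
    CANCER_STATES,
    HealthState,
)

S = HealthState


class SplitName(Enum):
    """The four diagnostic cut points on the benign -> carcinoma spectrum."""

    BENIGN_MILD = "benign|mild"
    MILD_MODERATE = "mild|moderate"
    LOW_HIGH = "low|high"
    MODERATE_SEVERE = "moderate|severe"


class TestKind(Enum):
    POCOCT = "pococt"
    VISUAL = "visual"
    BIOPSY = "biopsy"


_CANCERS = frozenset(CANCER_STATES)

#: True states counted as positive at each split (nested by construction).
POSITIVE_STATES: dict[SplitName, frozenset[HealthState]] = {
    SplitName.BENIGN_MILD: frozenset(
        {
            S.MILD_DYSPLASIA,
            S.MODERATE_DYSPLASIA_LOW,
            S.MODERATE_DYSPLASIA_HIGH,
            S.SEVERE_DYSPLASIA,
        }
    )
    | _CANCERS,
    SplitName.MILD_MODERATE: frozenset(
        {S.MODERATE_DYSPLASIA_LOW, S.MODERATE_DYSPLASIA_HIGH, S.SEVERE_DYSPLASIA}
    )
    | _CANCERS,
    SplitName.LOW_HIGH: frozenset({S.MODERATE_DYSPLASIA_HIGH, S.SEVERE_DYSPLASIA})
    | _CANCERS,
    SplitName.MODERATE_SEVERE: frozenset({S.SEVERE_DYSPLASIA}) | _CANCERS,
}

_SPLIT_PARAMS = {
    SplitName.BENIGN_MILD: ("sens_pococt_benign_mild", "spec_pococt_benign_mild"),
    SplitName.MILD_MODERATE: ("sens_pococt_mild_moderate", "spec_pococt_mild_moderate"),
    SplitName.LOW_HIGH: ("sens_pococt_low_high", "spec_pococt_low_high"),
    SplitName.MODERATE_SEVERE: (
        "sens_pococt_moderate_severe",
        "spec_pococt_moderate_severe",
    ),
}


@dataclass(frozen=True)
class DiagnosticSplit:
    name: SplitName
    positive_states: frozenset[HealthState]
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class TestResult:
    test: TestKind
    positive: bool
    histology_call: HealthState | None = None
    cycle: int = 0

    def __post_init__(self) -> None:
        if (self.histology_call is not None) != (self.test == TestKind.BIOPSY):
            raise ValueError("histology_call present iff the test is a biopsy")


def make_split(name: SplitName, params: ParameterSet) -> DiagnosticSplit:
    sens_f, spec_f = _SPLIT_PARAMS[name]
    return DiagnosticSplit(
        name=name,
        positive_states=POSITIVE_STATES[name],
        sensitivity=getattr(params, sens_f).value,
        specificity=getattr(params, spec_f).value,
    )


def _require_live_lesion(state: HealthState) -> None:
    if state in ABSORBING_STATES or state in (
        S.POST_TREATMENT_DYSPLASIA,
        S.POST_TREATMENT_CANCER_EARLY,
        S.POST_TREATMENT_CANCER_LATE,
    ):
        raise ValueError(f"cannot test a patient in state {state.name}")


def pococt_p_positive(state: HealthState, split: DiagnosticSplit) -> float:
    """P(positive POCOCT | true state) at a diagnostic split."""
    _require_live_lesion(state)
    if state in split.positive_states:
        return split.sensitivity
    return 1.0 - split.specificity


def run_pococt(
    state: HealthState, split: DiagnosticSplit, rng: np.random.Generator, cycle: int = 0
) -> TestResult:
    p = pococt_p_positive(state, split)
    return TestResult(TestKind.POCOCT, bool(rng.random() < p), cycle=cycle)


def visual_p_positive(state: HealthState, params: ParameterSet) -> float:
    """P(positive visual-tactile exam | true state).

    Carcinoma uses the cancer sensitivity (0.71), any dysplasia the
    mild/moderate dysplasia sensitivity (0.50, also applied to severe
    dysplasia, which has no separately reported value), and benign lesions
    the false-positive rate 1 - specificity.
    """
    _require_live_lesion(state)
    if state in CANCER_STATES:
        return params.sens_visual_cancer.value
    if state == S.BENIGN:
        return 1.0 - params.spec_visual.value
    if state == S.SEVERE_DYSPLASIA and params.visual_sens_severe is not None:
        return params.visual_sens_severe
    return params.sens_visual_dysplasia.value


def run_visual_exam(
    state: HealthState, params: ParameterSet, rng: np.random.Generator, cycle: int = 0
) -> TestResult:
    p = visual_p_positive(state, params)
    return TestResult(TestKind.VISUAL, bool(rng.random() < p), cycle=cycle)


def biopsy_call_branches(
    state: HealthState, params: ParameterSet
) -> list[tuple[float, HealthState]]:
    """Distribution of the histology call given the true state.

    With probability ``sens_biopsy`` a diseased lesion is graded exactly
    (cancer staged correctly); otherwise sampling error returns a benign
    call.  Benign lesions are called benign with probability ``spec_biopsy``
    (1.0 in the base case); any benign over-call goes to the mildest
    dysplasia grade.
    """
    _require_live_lesion(state)
    if state == S.BENIGN:
        spec = params.spec_biopsy.value
        branches = [(spec, S.BENIGN)]
        if spec < 1.0:
            branches.append((1.0 - spec, S.MILD_DYSPLASIA))
        return branches
    sens = params.sens_biopsy.value
    branches = [(sens, state)]
    if sens < 1.0:
        branches.append((1.0 - sens, S.BENIGN))
    return branches


def run_biopsy(
    state: HealthState, params: ParameterSet, rng: np.random.Generator, cycle: int = 0
) -> TestResult:
    branches = biopsy_call_branches(state, params)
    u = rng.random()
    acc = 0.0
    call = branches[-1][1]
    for p, c in branches:
        acc += p
        if u < acc:
            call = c
            break
    return TestResult(
        TestKind.BIOPSY, positive=call != S.BENIGN, histology_call=call, cycle=cycle
    )
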