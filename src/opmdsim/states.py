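"""Health-state space and patient-level transition context.

The model tracks the *true* biology of a simulated patient's oral lesion,
which is distinct from what any diagnostic test reports about it.  Moderate
dysplasia is carried as two substates (low/high risk) so that the WHO
dichotomous low|high classification is expressible; strategies that do not
distinguish them see identical behaviour apart from the malignant
transformation rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class HealthState(IntEnum):
    """True lesion/disease condition of a simulated patient.

    The integer ordering of the untreated lesion states (BENIGN through
    LATE_CANCER_UNDETECTED) doubles as the histologic severity ordering used
    for treatment thresholds.
    """

    BENIGN = 0
    MILD_DYSPLASIA = 1
    MODERATE_DYSPLASIA_LOW = 2
    MODERATE_DYSPLASIA_HIGH = 3
    SEVERE_DYSPLASIA = 4
    EARLY_CANCER_UNDETECTED = 5
    LATE_CANCER_UNDETECTED = 6
    POST_TREATMENT_DYSPLASIA = 7
    POST_TREATMENT_CANCER_EARLY = 8
    POST_TREATMENT_CANCER_LATE = 9
    METASTATIC = 10
    DEAD_CANCER = 11
    DEAD_OTHER = 12


#: Untreated, live, lesion-bearing states (order = histologic severity).
LESION_STATES: tuple[HealthState, ...] = (
    HealthState.BENIGN,
    HealthState.MILD_DYSPLASIA,
    HealthState.MODERATE_DYSPLASIA_LOW,
    HealthState.MODERATE_DYSPLASIA_HIGH,
    HealthState.SEVERE_DYSPLASIA,
    HealthState.EARLY_CANCER_UNDETECTED,
    HealthState.LATE_CANCER_UNDETECTED,
)

DYSPLASIA_STATES: frozenset[HealthState] = frozenset(
    {
        HealthState.MILD_DYSPLASIA,
        HealthState.MODERATE_DYSPLASIA_LOW,
        HealthState.MODERATE_DYSPLASIA_HIGH,
        HealthState.SEVERE_DYSPLASIA,
    }
)

#: Live states harbouring invasive carcinoma.
CANCER_STATES: frozenset[HealthState] = frozenset(
    {
        HealthState.EARLY_CANCER_UNDETECTED,
        HealthState.LATE_CANCER_UNDETECTED,
        HealthState.METASTATIC,
    }
)

ABSORBING_STATES: frozenset[HealthState] = frozenset(
    {HealthState.DEAD_CANCER, HealthState.DEAD_OTHER}
)

LIVE_STATES: tuple[HealthState, ...] = tuple(
    s for s in HealthState if s not in ABSORBING_STATES
)


def is_alive(state: HealthState) -> bool:
    return state not in ABSORBING_STATES


@dataclass(frozen=True)
class TransitionContext:
    """Patient-level modifiers of background (non-cancer) mortality.

    Parameters
    ----------
    age_years:
        Age at model entry; the base case is a 60-year-old cohort.
    sex:
        ``"male"`` or ``"female"``; selects the life-table fixture.
    charlson_multiplier:
        Multiplicative hazard ratio on non-cancer mortality representing
        comorbidity burden (Charlson score), default 1.0.
    non_cancer_mortality_hr:
        Additional hazard ratio on non-cancer mortality; set to 1.4 for the
        elevated-risk external-validation sub-model.
    """

    age_years: float = 60.0
    sex: str = "male"
    charlson_multiplier: float = 1.0
    non_cancer_mortality_hr: float = 1.0

    def __post_init__(self) -> None:
        if not 18.0 <= self.age_years <= 110.0:
            raise ValueError(f"age_years must be in [18, 110], got {self.age_years}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.charlson_multiplier <= 0 or self.non_cancer_mortality_hr <= 0:
            raise ValueError("hazard multipliers must be positive")

    @property
    def mortality_multiplier(self) -> float:
        """Combined hazard multiplier applied to background mortality."""
        return self.charlson_multiplier * self.non_cancer_mortality_hr
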