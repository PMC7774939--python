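"""Model parameters: base-case values with deterministic-sensitivity ranges.

Every substantive input of the model lives here as a ``Param`` (base value
plus low/high range).  The packaged ``base_case.yaml`` reproduces the source
parameter table exactly; structural modelling choices that the source leaves
open (moderate low/high split fraction, stage pooling weights, post-
surveillance progression, ...) are plain fields with documented defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, NamedTuple

import yaml


class Param(NamedTuple):
    """A model input with its deterministic-sensitivity range."""

    value: Any
    low: float
    high: float


def _p(value, low, high) -> Param:
    return Param(value, low, high)


#: Field names holding ``Param`` entries (mirrors the packaged YAML keys).
PARAM_FIELDS: tuple[str, ...] = (
    "prevalence_malignant",
    "prevalence_mild",
    "prevalence_moderate",
    "prevalence_severe",
    "p_early_given_cancer",
    "p_regress_mild_benign",
    "p_mild_to_moderate",
    "p_mt_moderate",
    "p_mt_low_risk",
    "p_mt_high_risk",
    "p_mt_severe",
    "p_early_to_late",
    "p_late_to_mets",
    "p_death_mets",
    "p_surgical_mortality",
    "p_visual_exam_no_screen_localized",
    "p_present_visual_no_screen_symptomatic",
    "adherence_surveillance",
    "adherence_biopsy",
    "p_rebiopsy_prior_benign",
    "sens_pococt_benign_mild",
    "spec_pococt_benign_mild",
    "sens_pococt_mild_moderate",
    "spec_pococt_mild_moderate",
    "sens_pococt_low_high",
    "spec_pococt_low_high",
    "sens_pococt_moderate_severe",
    "spec_pococt_moderate_severe",
    "sens_visual_cancer",
    "spec_visual",
    "sens_visual_dysplasia",
    "sens_biopsy",
    "spec_biopsy",
)


@dataclass(frozen=True)
class ParameterSet:
    # --- initial lesion-state mixture ---
    prevalence_malignant: Param = _p(0.05, 0.02, 0.075)
    prevalence_mild: Param = _p(0.1154, 0.05, 0.17)
    prevalence_moderate: Param = _p(0.0440, 0.03, 0.06)
    prevalence_severe: Param = _p(0.0288, 0.015, 0.05)
    p_early_given_cancer: Param = _p(0.2731, 0.13655, 0.5462)

    # --- natural history (annual probabilities) ---
    p_regress_mild_benign: Param = _p(0.04, 0.02, 0.08)
    p_mild_to_moderate: Param = _p(0.0003, 0.00015, 0.0006)
    p_mt_moderate: Param = _p(0.035, 0.0175, 0.07)
    p_mt_low_risk: Param = _p(0.029, 0.0145, 0.058)
    p_mt_high_risk: Param = _p(0.040, 0.02, 0.08)
    p_mt_severe: Param = _p(0.084, 0.042, 0.168)
    p_early_to_late: Param = _p(0.046, 0.023, 0.092)
    p_late_to_mets: Param = _p(0.391, 0.1955, 0.782)
    p_death_mets: Param = _p(0.127, 0.0635, 0.254)

    # --- care-seeking, adherence, procedures ---
    p_surgical_mortality: Param = _p(0.002, 0.001, 0.004)
    p_visual_exam_no_screen_localized: Param = _p(0.13, 0.065, 0.26)
    p_present_visual_no_screen_symptomatic: Param = _p(0.30, 0.15, 0.45)
    adherence_surveillance: Param = _p((0.92, 0.82, 0.72), 0.5, 1.0)
    adherence_biopsy: Param = _p(0.92, 0.5, 1.0)
    p_rebiopsy_prior_benign: Param = _p(0.20, 0.10, 0.40)

    # --- test operating characteristics ---
    sens_pococt_benign_mild: Param = _p(0.90, 0.86, 0.92)
    spec_pococt_benign_mild: Param = _p(0.57, 0.52, 0.62)
    sens_pococt_mild_moderate: Param = _p(0.90, 0.86, 0.92)
    spec_pococt_mild_moderate: Param = _p(0.66, 0.61, 0.71)
    sens_pococt_low_high: Param = _p(0.91, 0.87, 0.93)
    spec_pococt_low_high: Param = _p(0.62, 0.57, 0.67)
    sens_pococt_moderate_severe: Param = _p(0.92, 0.89, 0.94)
    spec_pococt_moderate_severe: Param = _p(0.65, 0.60, 0.70)
    sens_visual_cancer: Param = _p(0.71, 0.60, 0.85)
    spec_visual: Param = _p(0.97, 0.93, 0.98)
    sens_visual_dysplasia: Param = _p(0.50, 0.25, 0.75)
    sens_biopsy: Param = _p(0.98, 0.90, 1.0)
    spec_biopsy: Param = _p(1.0, 0.90, 1.0)

    # --- structural choices left open by the source (documented defaults) ---
    #: fraction of moderate dysplasia assigned to the low-risk substate; the
    #: 50/50 default makes the mixture's mean transformation rate match the
    #: pooled moderate rate ((0.029 + 0.040)/2 ~= 0.035).
    moderate_low_fraction: float = 0.5
    #: stage pooling weight of stage I within the treated early-cancer state
    #: (stage II gets the complement); pooled on the hazard scale.
    stage_weight_early: float = 0.5
    #: stage pooling weight of stage III within the treated late-cancer state.
    stage_weight_late: float = 0.5
    #: visual-exam sensitivity for severe dysplasia (not separately reported);
    #: None falls back to the mild/moderate dysplasia value.
    visual_sens_severe: float | None = None
    #: optional annual probability that a benign lesion develops mild
    #: dysplasia (no published rate; benign lesions are static by default).
    p_benign_to_mild: float = 0.0
    #: optional annual probability of a new benign lesion after surgical
    #: removal of dysplasia (no published rate; zero by default).
    p_new_lesion_after_treatment: float = 0.0
    #: interpretation of the published metastatic death probability 0.127.
    #: The base case treats it as *monthly*: the annual reading implies a
    #: median metastatic survival beyond five years, which contradicts both
    #: the survival-calibrated untreated pathway the source describes and
    #: observed survival with distant metastatic oral cancer.  Set True to
    #: use the literal annual reading.
    p_death_mets_is_annual: bool = False
    #: whether untreated lesions keep progressing after surveillance ends
    #: (month 60) in strategies that surveil.  The base case freezes them
    #: (lesions below the treatment threshold are assumed indolent once the
    #: five-year surveillance window closes); set True to let them progress.
    progression_after_surveillance: bool = False
    #: direct monthly override of the late-cancer -> metastasis probability
    #: (used by threshold analyses that sweep the monthly scale).
    monthly_late_to_mets_override: float | None = None

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in PARAM_FIELDS:
            p: Param = getattr(self, name)
            values = p.value if isinstance(p.value, (tuple, list)) else (p.value,)
            for v in values:
                if not 0.0 <= float(v) <= 1.0:
                    raise ValueError(f"{name}: probability {v} outside [0, 1]")
                if not (p.low <= float(v) <= p.high):
                    raise ValueError(
                        f"{name}: base value {v} outside range [{p.low}, {p.high}]"
                    )
        prev_sum = (
            self.prevalence_malignant.value
            + self.prevalence_mild.value
            + self.prevalence_moderate.value
            + self.prevalence_severe.value
        )
        if prev_sum > 1.0 + 1e-12:
            raise ValueError(f"initial prevalences sum to {prev_sum} > 1")
        if not 0.0 <= self.moderate_low_fraction <= 1.0:
            raise ValueError("moderate_low_fraction must be in [0, 1]")

    # ------------------------------------------------------------------
    @property
    def prevalence_benign(self) -> float:
        """Complement of the dysplasia/carcinoma prevalences."""
        return 1.0 - (
            self.prevalence_malignant.value
            + self.prevalence_mild.value
            + self.prevalence_moderate.value
            + self.prevalence_severe.value
        )

    def adherence_for_visit(self, visit_index: int) -> float:
        """Attendance probability for surveillance visit ``visit_index``.

        The three published values map to visits 1, 2, and 3+ (visit-ordered
        decay); a scalar override applies to every visit.
        """
        a = self.adherence_surveillance.value
        if isinstance(a, (tuple, list)):
            return float(a[min(visit_index, len(a) - 1)])
        return float(a)

    # ------------------------------------------------------------------
    def with_overrides(self, **overrides: Any) -> "ParameterSet":
        """Return a copy with base-case values (not ranges) replaced.

        Accepts any ``Param`` field name (new base value, range kept), any
        structural field, plus two composite keys used by sensitivity
        analyses: ``joint_adherence`` (sets every surveillance-visit adherence
        and the biopsy adherence to one value) and ``p_late_to_mets_monthly``
        (monthly-scale override of the metastasis probability).
        """
        changes: dict[str, Any] = {}
        for name, value in overrides.items():
            if name == "joint_adherence":
                changes["adherence_surveillance"] = self.adherence_surveillance._replace(
                    value=(float(value),) * 3
                )
                changes["adherence_biopsy"] = self.adherence_biopsy._replace(
                    value=float(value)
                )
            elif name == "p_late_to_mets_monthly":
                changes["monthly_late_to_mets_override"] = float(value)
            elif name in PARAM_FIELDS:
                p: Param = getattr(self, name)
                if name == "adherence_surveillance" and not isinstance(
                    value, (tuple, list)
                ):
                    value = (float(value),) * 3
                values = value if isinstance(value, (tuple, list)) else (value,)
                lo = min([p.low, *map(float, values)])
                hi = max([p.high, *map(float, values)])
                changes[name] = Param(value, lo, hi)
            elif name in {f.name for f in fields(self)}:
                changes[name] = value
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return dataclasses.replace(self, **changes)

    def dsa_ranges(self) -> dict[str, tuple[float, float]]:
        """Default one-way sensitivity range for every tabulated parameter."""
        return {name: (getattr(self, name).low, getattr(self, name).high) for name in PARAM_FIELDS}

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in PARAM_FIELDS:
            p: Param = getattr(self, name)
            value = list(p.value) if isinstance(p.value, tuple) else p.value
            out[name] = {"value": value, "low": p.low, "high": p.high}
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any], **structural: Any) -> "ParameterSet":
        kwargs: dict[str, Any] = {}
        for name, entry in data.items():
            if name not in PARAM_FIELDS:
                raise KeyError(f"unknown parameter {name!r} in config")
            value = entry["value"]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = Param(value, float(entry["low"]), float(entry["high"]))
        kwargs.update(structural)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **structural: Any) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), **structural)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def base_case(cls) -> "ParameterSet":
        """Load the packaged base-case parameter table."""
        ref = resources.files("opmdsim.data").joinpath("base_case.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))
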