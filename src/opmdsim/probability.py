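"""Probability/hazard plumbing shared by every module.

A 1-month cycle applied to annual transition probabilities requires a
rate-conversion convention; this package uses constant-hazard compounding
throughout.  Simultaneous monthly risks are combined by summing hazards and
allocating the total event probability proportionally to the individual
hazards, which is order-independent and exact in the small-probability limit.
"""

from __future__ import annotations

import math
from typing import Hashable, Sequence


def annual_to_monthly(p_annual: float) -> float:
    """Convert an annual probability to its 1-month equivalent.

    Uses constant-hazard compounding: ``1 - (1 - p)**(1/12)``.  Monotone
    increasing in ``p_annual``; 0 and 1 are fixed points.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p_annual}")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def monthly_to_annual(p_monthly: float) -> float:
    """Inverse of :func:`annual_to_monthly`."""
    if not 0.0 <= p_monthly <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p_monthly}")
    return 1.0 - (1.0 - p_monthly) ** 12


def prob_to_hazard(p: float) -> float:
    """Per-cycle probability -> cumulative hazard over the cycle."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if p == 1.0:
        return math.inf
    return -math.log1p(-p)


def hazard_to_prob(h: float) -> float:
    if h < 0:
        raise ValueError(f"hazard must be non-negative, got {h}")
    return -math.expm1(-h)


def scale_probability(p: float, hazard_ratio: float) -> float:
    """Apply a hazard ratio to a per-cycle probability: ``1-(1-p)**hr``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if hazard_ratio < 0:
        raise ValueError("hazard ratio must be non-negative")
    if p == 1.0:
        return 1.0
    return 1.0 - (1.0 - p) ** hazard_ratio


def apply_competing_risks(
    event_probabilities: Sequence[tuple[Hashable, float]],
    stay: Hashable = "stay",
) -> dict[Hashable, float]:
    """Combine simultaneous monthly risks into one proper distribution.

    Each ``(target, p)`` pair is converted to a hazard; hazards are summed;
    the total event probability ``1 - prod(1 - p_i)`` is allocated to targets
    proportionally to their hazards, with the residual mass on ``stay``.

    Certain events (``p == 1``) receive the whole event mass, split equally
    among themselves, since their hazards dominate every finite hazard.
    """
    probs = [float(p) for _, p in event_probabilities]
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {p}")

    out: dict[Hashable, float] = {}
    certain = [t for (t, p) in event_probabilities if p == 1.0]
    if certain:
        share = 1.0 / len(certain)
        for t, p in event_probabilities:
            if p == 1.0:
                out[t] = out.get(t, 0.0) + share
        out[stay] = 0.0
        return out

    total_surv = 1.0
    hazards = []
    for p in probs:
        total_surv *= 1.0 - p
        hazards.append(prob_to_hazard(p))
    total_event = 1.0 - total_surv
    hsum = sum(hazards)
    if hsum == 0.0:
        return {stay: 1.0}
    for (t, _), h in zip(event_probabilities, hazards):
        out[t] = out.get(t, 0.0) + total_event * h / hsum
    out[stay] = total_surv
    return out
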