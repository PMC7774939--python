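"""Background all-cause mortality: parametric life-table fixture and oracles.

The model needs U.S.-style period life tables for non-cancer mortality.  To
keep the package self-contained and download-free, the packaged fixture is a
Gompertz-Makeham hazard ``h(x) = c + a*exp(b*x)`` whose three constants were
fitted once, offline, to published U.S. period-life-table anchors (SSA 2019,
annual death probabilities at ages 50-90 and remaining life expectancy at
60).  The fitted male table gives e(60) = 21.32 years, within half a year of
the published 21.47; the female table gives e(60) = 24.30.

Any user-supplied two-column (age, q) CSV table can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .probability import annual_to_monthly, scale_probability
from .states import HealthState, TransitionContext
from .transitions import initial_state_distribution

#: Gompertz-Makeham constants (makeham_c [1/yr], gompertz_a [1/yr],
#: gompertz_b [1/yr]) fitted to published U.S. male/female period tables.
GM_MALE = (3.50981e-3, 1.25967e-5, 0.1053195)
GM_FEMALE = (2.20457e-3, 4.87101e-6, 0.1130517)

#: Closing age of every packaged table (q = 1 at this age).
CLOSING_AGE = 110


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual probabilities of death before the next birthday."""

    ages: np.ndarray
    q: np.ndarray
    sex: str = "male"
    source_tag: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.shape != q.shape or ages.ndim != 1 or len(ages) == 0:
            raise ValueError("ages and q must be equal-length 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous integers")
        if np.any(q <= 0) or np.any(q > 1):
            raise ValueError("q values must lie in (0, 1]")
        if q[-1] != 1.0:
            raise ValueError("terminal q must equal 1 at the closing age")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def end_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age_years: float) -> float:
        """Annual death probability at the attained integer age.

        Ages beyond the closing age return 1 (certain death)."""
        age = int(math.floor(age_years))
        if age < self.start_age:
            raise ValueError(f"age {age_years} below table start {self.start_age}")
        if age >= self.end_age:
            return 1.0
        return float(self.q[age - self.start_age])

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.ages, self.q])
        np.savetxt(path, arr, fmt=["%d", "%.10g"], delimiter=",", header="age,q", comments="")

    @classmethod
    def from_csv(cls, path: str | Path, sex: str = "male", source_tag: str = "csv") -> "LifeTable":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(ages=arr[:, 0].astype(int), q=arr[:, 1], sex=sex, source_tag=source_tag)


def make_gompertz_makeham_life_table(
    makeham_c: float,
    gompertz_a: float,
    gompertz_b: float,
    start_age: int = 0,
    end_age: int = CLOSING_AGE,
    sex: str = "male",
    source_tag: str = "gompertz-makeham",
) -> LifeTable:
    """Build a period life table from a Gompertz-Makeham hazard.

    ``q(x) = 1 - exp(-integral_x^{x+1} (c + a e^{bt}) dt)``; the terminal
    entry at ``end_age`` is set to 1.
    """
    if makeham_c <= 0 or gompertz_a <= 0 or gompertz_b <= 0:
        raise ValueError("Gompertz-Makeham parameters must be positive")
    if end_age < start_age:
        raise ValueError("end_age must be >= start_age")
    ages = np.arange(start_age, end_age + 1)
    cum = makeham_c + (gompertz_a / gompertz_b) * (
        np.exp(gompertz_b * (ages + 1.0)) - np.exp(gompertz_b * ages)
    )
    q = 1.0 - np.exp(-cum)
    q[-1] = 1.0
    return LifeTable(ages=ages, q=q, sex=sex, source_tag=source_tag)


def default_life_table(sex: str = "male") -> LifeTable:
    """The packaged fixture table for the requested sex."""
    c, a, b = GM_MALE if sex == "male" else GM_FEMALE
    return make_gompertz_makeham_life_table(c, a, b, sex=sex, source_tag=f"fitted-{sex}")


def monthly_background_mortality(
    table: LifeTable, age_years: float, ctx: TransitionContext | None = None
) -> float:
    """Monthly non-cancer death probability at an attained age.

    Converts the annual q at the attained integer age to a 1-month
    probability, then applies the context's Charlson and non-cancer hazard
    multipliers on the hazard scale.
    """
    qm = annual_to_monthly(table.q_at(age_years))
    if ctx is None:
        return qm
    return scale_probability(qm, ctx.mortality_multiplier)


def remaining_life_expectancy(
    table: LifeTable, age_years: float, ctx: TransitionContext | None = None
) -> float:
    """Deterministic actuarial remaining life expectancy in years.

    Monthly survival product with half-cycle correction (deaths are credited
    half a month in their cycle of death); the closed-form oracle for the
    simulation engines in the disease-free limit.
    """
    months = int(round((table.end_age - age_years) * 12))
    surv = 1.0
    le_months = 0.0
    for m in range(months + 1):
        qm = monthly_background_mortality(table, age_years + m / 12.0, ctx)
        nxt = surv * (1.0 - qm)
        le_months += 0.5 * (surv + nxt)
        surv = nxt
        if surv < 1e-16:
            break
    return le_months / 12.0


def generate_cohort(
    n: int,
    params,
    seed: int,
    age_years: float = 60.0,
    sex: str = "male",
) -> np.ndarray:
    """Draw ``n`` initial true health states i.i.d. from the lesion mixture.

    Returns an integer array of :class:`~opmdsim.states.HealthState` codes;
    reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    dist = initial_state_distribution(params)
    states = np.array([int(s) for s in dist], dtype=np.int64)
    probs = np.array([dist[HealthState(s)] for s in states], dtype=float)
    rng = np.random.default_rng(seed)
    return rng.choice(states, size=n, p=probs)
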