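"""Simulation engines: deterministic cohort expectation and microsimulation.

Both engines consume the same per-month *branch* decomposition of the model:
for every composite state (true lesion state x surveillance phase x
prior-benign flag, plus metastatic/post-treatment/dead states) the branch
builder enumerates the mutually exclusive outcomes of one cycle with their
probabilities and event tags.  The cohort engine propagates expected
occupancy through the branches (noise-free life expectancy); the
microsimulation samples them patient by patient (event tallies with Monte
Carlo error).  Sharing the builder guarantees the two agree in expectation.

Event order within a cycle is fixed: (1) background and disease death,
(2) scheduled management actions and tests, (3) treatment, (4) natural-
history progression.  Life expectancy is half-cycle corrected: deaths are
credited half a month in their cycle of death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibratedMortality, default_calibration
from .life_tables import LifeTable, default_life_table, monthly_background_mortality
from .parameters import ParameterSet
from .probability import annual_to_monthly, apply_competing_risks
from .states import HealthState, TransitionContext
from .strategies import (
    PHASE_DONE,
    InitialAction,
    Strategy,
    make_strategy,
    management_branches,
)
from .transitions import (
    disease_death_prob,
    initial_state_distribution,
    progression_branches,
)

S = HealthState

# ----------------------------------------------------------------------
# composite-state encoding

_LESION_ORDER = (
    S.BENIGN,
    S.MILD_DYSPLASIA,
    S.MODERATE_DYSPLASIA_LOW,
    S.MODERATE_DYSPLASIA_HIGH,
    S.SEVERE_DYSPLASIA,
    S.EARLY_CANCER_UNDETECTED,
    S.LATE_CANCER_UNDETECTED,
)
_LESION_INDEX = {s: i for i, s in enumerate(_LESION_ORDER)}
_N_PHASE = 7  # phases 0..5 awaiting that visit, 6 = done
_N_LESION_COMP = len(_LESION_ORDER) * _N_PHASE * 2

C_METS = _N_LESION_COMP  # 98
C_POST_DYS = C_METS + 1
C_POST_EARLY = C_METS + 2
C_POST_LATE = C_METS + 3
C_DEAD_CANCER = C_METS + 4
C_DEAD_OTHER = C_METS + 5
N_COMP = C_DEAD_OTHER + 1

_SIMPLE_COMP = {
    S.METASTATIC: C_METS,
    S.POST_TREATMENT_DYSPLASIA: C_POST_DYS,
    S.POST_TREATMENT_CANCER_EARLY: C_POST_EARLY,
    S.POST_TREATMENT_CANCER_LATE: C_POST_LATE,
    S.DEAD_CANCER: C_DEAD_CANCER,
    S.DEAD_OTHER: C_DEAD_OTHER,
}
_SIMPLE_STATE = {v: k for k, v in _SIMPLE_COMP.items()}


def lesion_comp(lesion: HealthState, phase: int, prior_benign: bool) -> int:
    return _LESION_INDEX[lesion] * (_N_PHASE * 2) + phase * 2 + int(prior_benign)


def decode_comp(comp: int) -> tuple[HealthState, int, bool]:
    """Composite index -> (state, phase, prior_benign)."""
    if comp >= _N_LESION_COMP:
        return _SIMPLE_STATE[comp], PHASE_DONE, False
    lesion, rest = divmod(comp, _N_PHASE * 2)
    phase, pb = divmod(rest, 2)
    return _LESION_ORDER[lesion], phase, bool(pb)


# events tracked by both engines
EVENTS: tuple[str, ...] = (
    "test",
    "presentation",
    "biopsy",
    "biopsy_benign",
    "surgery",
    "death_surgical",
    "treated_benign",
    "treated_dysplasia",
    "treated_early",
    "treated_late",
    "mt",
    "early_to_late",
    "new_mets",
    "death_cancer",
    "death_other",
)
_EV_INDEX = {name: i for i, name in enumerate(EVENTS)}


@dataclass
class RunResult:
    """Per-strategy outcome summary from either engine."""

    strategy_id: int
    label: str
    engine: str
    n: int | None
    life_years_mean: float
    life_years_se: float | None
    events_per_patient: dict[str, float]
    events_by_month: np.ndarray | None = None
    life_years: np.ndarray | None = field(default=None, repr=False)
    truncated: bool = False


# ----------------------------------------------------------------------
# branch construction


class _BranchBuilder:
    """Builds and caches one-cycle branch lists per composite state."""

    def __init__(
        self,
        strategy: Strategy,
        params: ParameterSet,
        calibration: CalibratedMortality,
        ctx: TransitionContext,
        include_background: bool,
    ):
        self.strategy = strategy
        self.params = params
        self.calibration = calibration
        self.ctx = ctx
        self.include_background = include_background
        self._cache: dict = {}

    def _mgmt_key(self, comp: int, month: int) -> str:
        if comp >= _N_LESION_COMP:
            return "n"
        if self.strategy.initial_action == InitialAction.DEFER:
            return "d"
        if month == 0:
            return "i"
        _, phase, _ = decode_comp(comp)
        sched = self.strategy.schedule
        if (
            sched is not None
            and phase < len(sched.visit_months)
            and month == sched.visit_months[phase]
        ):
            return "v"
        return "n"

    def _freeze(self, month: int) -> bool:
        return (
            not self.params.progression_after_surveillance
            and self.strategy.schedule is not None
            and month >= self.strategy.schedule.visit_months[-1]
        )

    def branches(self, comp: int, month: int, q_monthly: float):
        """Branch list ``[(prob, next_comp, event_index_tuple), ...]``.

        ``q_monthly`` is the ctx-scaled monthly background mortality (ignored
        when the builder excludes background death, as the microsimulation
        does via pre-drawn non-cancer death times).
        """
        if not self.include_background:
            q_monthly = 0.0
        key = (comp, self._mgmt_key(comp, month), self._freeze(month), q_monthly)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        out = self._build(comp, month, q_monthly)
        self._cache[key] = out
        return out

    def _build(self, comp: int, month: int, q_monthly: float):
        params, strategy, calib = self.params, self.strategy, self.calibration
        if comp in (C_DEAD_CANCER, C_DEAD_OTHER):
            return [(1.0, comp, ())]

        state, phase, pb = decode_comp(comp)
        p_other = q_monthly
        p_cancer = disease_death_prob(state, params, calib)
        deaths = apply_competing_risks(
            [(C_DEAD_OTHER, p_other), (C_DEAD_CANCER, p_cancer)], stay="alive"
        )
        alive = deaths.pop("alive")
        out: list[tuple[float, int, tuple[int, ...]]] = []
        if deaths.get(C_DEAD_OTHER, 0.0) > 0:
            out.append((deaths[C_DEAD_OTHER], C_DEAD_OTHER, (_EV_INDEX["death_other"],)))
        if deaths.get(C_DEAD_CANCER, 0.0) > 0:
            out.append((deaths[C_DEAD_CANCER], C_DEAD_CANCER, (_EV_INDEX["death_cancer"],)))
        if alive <= 0.0:
            return out

        if comp >= _N_LESION_COMP:
            # metastatic / post-treatment: optional new-lesion arc, else static
            nxt = comp
            if comp == C_POST_DYS and params.p_new_lesion_after_treatment > 0:
                p_new = annual_to_monthly(params.p_new_lesion_after_treatment)
                out.append(
                    (alive * p_new, lesion_comp(S.BENIGN, PHASE_DONE, False), ())
                )
                out.append((alive * (1.0 - p_new), nxt, ()))
                return out
            out.append((alive, nxt, ()))
            return out

        mgmt = management_branches(state, phase, pb, strategy, month, params)
        if mgmt is None:
            mgmt = [(1.0, ("cont", phase, pb, ()))]

        freeze = self._freeze(month)
        prog = (
            [(1.0, state, ())] if freeze else progression_branches(state, params)
        )
        for p_m, outcome in mgmt:
            if p_m <= 0.0:
                continue
            if outcome[0] == "moved":
                _, new_state, evs = outcome
                ev_idx = tuple(_EV_INDEX[e] for e in evs)
                out.append((alive * p_m, _SIMPLE_COMP[new_state], ev_idx))
                continue
            _, new_phase, new_pb, evs = outcome
            ev_base = tuple(_EV_INDEX[e] for e in evs)
            for p_g, new_lesion, g_evs in prog:
                if p_g <= 0.0:
                    continue
                ev_idx = ev_base + tuple(_EV_INDEX[e] for e in g_evs)
                if new_lesion in _LESION_INDEX:
                    nxt = lesion_comp(new_lesion, new_phase, new_pb)
                else:  # progressed to metastatic disease
                    nxt = _SIMPLE_COMP[new_lesion]
                out.append((alive * p_m * p_g, nxt, ev_idx))
        return out


def _initial_comp_distribution(params: ParameterSet):
    dist = initial_state_distribution(params)
    comps, probs = [], []
    for state, p in dist.items():
        if p > 0:
            comps.append(lesion_comp(state, 0, False))
            probs.append(p)
    return np.array(comps, dtype=np.int64), np.array(probs, dtype=float)


def _months_total(table: LifeTable, ctx: TransitionContext, max_months: int | None) -> int:
    # +1 so the closing-age cycle (q = 1) runs and absorbs all survivors
    months = int(round((table.end_age - ctx.age_years) * 12)) + 1
    if max_months is not None:
        months = min(months, max_months)
    return months


# ----------------------------------------------------------------------
# cohort-expectation engine


def run_cohort_expectation(
    params: ParameterSet,
    strategy: Strategy,
    table: LifeTable | None = None,
    ctx: TransitionContext | None = None,
    calibration: CalibratedMortality | None = None,
    max_months: int | None = None,
    initial_mass: np.ndarray | None = None,
) -> RunResult:
    """Exact expected-occupancy iteration over the composite state space.

    Returns noise-free per-patient life expectancy and expected event counts;
    the deterministic twin of :func:`run_microsimulation`.
    """
    ctx = ctx or TransitionContext()
    table = table or default_life_table(ctx.sex)
    calibration = calibration or default_calibration(params)
    builder = _BranchBuilder(strategy, params, calibration, ctx, include_background=True)

    mass = np.zeros(N_COMP)
    if initial_mass is not None:
        if initial_mass.shape != (N_COMP,) or abs(initial_mass.sum() - 1.0) > 1e-9:
            raise ValueError("initial_mass must be a distribution over composite states")
        mass[:] = initial_mass
    else:
        comps, probs = _initial_comp_distribution(params)
        mass[comps] = probs

    months = _months_total(table, ctx, max_months)
    n_ev = len(EVENTS)
    events_by_month = np.zeros((months, n_ev))
    le_months = 0.0

    for m in range(months):
        alive_before = 1.0 - mass[C_DEAD_CANCER] - mass[C_DEAD_OTHER]
        if alive_before < 1e-16:
            events_by_month = events_by_month[:m]
            break
        q = monthly_background_mortality(table, ctx.age_years + m / 12.0, ctx)
        new_mass = np.zeros(N_COMP)
        ev = events_by_month[m]
        for comp in np.flatnonzero(mass > 0.0):
            w = mass[comp]
            for p, nxt, evs in builder.branches(int(comp), m, q):
                wp = w * p
                new_mass[nxt] += wp
                for e in evs:
                    ev[e] += wp
        alive_after = 1.0 - new_mass[C_DEAD_CANCER] - new_mass[C_DEAD_OTHER]
        le_months += 0.5 * (alive_before + alive_after)
        mass = new_mass

    alive_end = 1.0 - mass[C_DEAD_CANCER] - mass[C_DEAD_OTHER]
    return RunResult(
        strategy_id=strategy.id,
        label=strategy.label,
        engine="cohort",
        n=None,
        life_years_mean=le_months / 12.0,
        life_years_se=None,
        events_per_patient={
            name: float(events_by_month[:, i].sum()) for i, name in enumerate(EVENTS)
        },
        events_by_month=events_by_month,
        truncated=alive_end > 1e-12,
    )


# ----------------------------------------------------------------------
# microsimulation


def _background_death_months(
    table: LifeTable, ctx: TransitionContext, months: int, u: np.ndarray
) -> np.ndarray:
    """Invert the monthly background-survival curve at uniforms ``u``."""
    q = np.array(
        [
            monthly_background_mortality(table, ctx.age_years + m / 12.0, ctx)
            for m in range(months)
        ]
    )
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:-1]
    pmf = surv_before * q
    cdf = np.cumsum(pmf)
    cdf[-1] = max(cdf[-1], 1.0)  # closing-age q = 1 guarantees totality
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def run_microsimulation(
    params: ParameterSet,
    strategy: Strategy,
    table: LifeTable | None = None,
    n: int = 100_000,
    seed: int = 0,
    ctx: TransitionContext | None = None,
    calibration: CalibratedMortality | None = None,
    max_months: int | None = None,
) -> RunResult:
    """Seeded individual-level simulation of ``n`` patients until death.

    Common random numbers across strategies: the initial true states and the
    background (non-cancer) death month are drawn from streams keyed by the
    seed alone, so they are identical for every strategy at the same seed;
    disease, test and adherence draws use a per-strategy stream.  Results are
    bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ctx = ctx or TransitionContext()
    table = table or default_life_table(ctx.sex)
    calibration = calibration or default_calibration(params)
    builder = _BranchBuilder(strategy, params, calibration, ctx, include_background=False)

    rng_init = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    rng_bg = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    rng_ev = np.random.default_rng(np.random.SeedSequence([int(seed), 33, strategy.id]))

    comps0, probs0 = _initial_comp_distribution(params)
    comp = rng_init.choice(comps0, size=n, p=probs0).astype(np.int64)
    months = _months_total(table, ctx, max_months)
    m_bg = _background_death_months(table, ctx, months, rng_bg.random(n))

    alive = np.ones(n, dtype=bool)
    life_months = np.full(n, np.nan)
    tallies = np.zeros(len(EVENTS))
    i_death_other = _EV_INDEX["death_other"]

    for m in range(months):
        if not alive.any():
            break
        # (1) pre-drawn background deaths pre-empt everything this month
        dying = alive & (m_bg == m)
        k = int(dying.sum())
        if k:
            comp[dying] = C_DEAD_OTHER
            life_months[dying] = m + 0.5
            tallies[i_death_other] += k
            alive[dying] = False

        idx_alive = np.flatnonzero(alive)
        if idx_alive.size == 0:
            continue
        comps_alive = comp[idx_alive]
        order = np.argsort(comps_alive, kind="stable")
        sorted_idx = idx_alive[order]
        sorted_comps = comps_alive[order]
        bounds = np.flatnonzero(np.diff(sorted_comps)) + 1
        groups = np.split(sorted_idx, bounds)
        group_comps = [int(sorted_comps[0])] + [int(sorted_comps[b]) for b in bounds]

        for c, members in zip(group_comps, groups):
            branches = builder.branches(c, m, 0.0)
            if len(branches) == 1 and branches[0][1] == c and not branches[0][2]:
                continue  # identity: nothing can happen this month
            probs = np.array([b[0] for b in branches])
            cdf = np.cumsum(probs)
            cdf[-1] = 1.0
            draws = np.searchsorted(cdf, rng_ev.random(members.size), side="right")
            for b_i, (p, nxt, evs) in enumerate(branches):
                sel = members[draws == b_i]
                if sel.size == 0:
                    continue
                comp[sel] = nxt
                for e in evs:
                    tallies[e] += sel.size
                if nxt in (C_DEAD_CANCER, C_DEAD_OTHER):
                    life_months[sel] = m + 0.5
                    alive[sel] = False

    if alive.any():  # truncated horizon: survivors credited full horizon
        life_months[alive] = months
    life_years = life_months / 12.0
    return RunResult(
        strategy_id=strategy.id,
        label=strategy.label,
        engine="micro",
        n=n,
        life_years_mean=float(life_years.mean()),
        life_years_se=float(life_years.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        events_per_patient={name: float(tallies[i] / n) for i, name in enumerate(EVENTS)},
        life_years=life_years,
        truncated=bool(alive.any()),
    )


# ----------------------------------------------------------------------
# convenience drivers and validation sub-model


def run_all_strategies(
    params: ParameterSet,
    table: LifeTable | None = None,
    ctx: TransitionContext | None = None,
    engine: str = "cohort",
    n: int = 100_000,
    seed: int = 0,
    calibration: CalibratedMortality | None = None,
    strategy_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
) -> list[RunResult]:
    """Evaluate several strategies on identical parameters and seed scheme."""
    ctx = ctx or TransitionContext()
    table = table or default_life_table(ctx.sex)
    calibration = calibration or default_calibration(params)
    out = []
    for sid in strategy_ids:
        strat = make_strategy(sid)
        if engine == "cohort":
            out.append(run_cohort_expectation(params, strat, table, ctx, calibration))
        elif engine == "micro":
            out.append(
                run_microsimulation(params, strat, table, n, seed, ctx, calibration)
            )
        else:
            raise ValueError(f"unknown engine {engine!r}")
    return out


def huang_validation_submodel(
    table: LifeTable | None = None,
    age_years: float = 53.0,
    non_cancer_hr: float = 1.4,
    stage_survival: float | None = None,
) -> float:
    """Life expectancy of men treated for stage I oral cancer at age 53.

    External-validation sub-model: stage I cancer-specific mortality is
    calibrated to its 5-year survival target and applied to a cohort whose
    non-cancer mortality carries a hazard ratio of 1.4 (elevated-risk,
    tobacco-history population).  Deterministic via the cohort engine.
    """
    from .calibration import STAGE_SURVIVAL_5Y, calibrate_stage_mortality

    ctx = TransitionContext(age_years=age_years, non_cancer_mortality_hr=non_cancer_hr)
    table = table or default_life_table(ctx.sex)
    target = STAGE_SURVIVAL_5Y["I"] if stage_survival is None else stage_survival
    p_stage = calibrate_stage_mortality(target) if target < 1.0 else 0.0
    calib = CalibratedMortality(early=p_stage, late=p_stage)
    init = np.zeros(N_COMP)
    init[C_POST_EARLY] = 1.0
    res = run_cohort_expectation(
        ParameterSet(),
        make_strategy(1),
        table,
        ctx,
        calibration=calib,
        initial_mass=init,
    )
    return res.life_years_mean
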