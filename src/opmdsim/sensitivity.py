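"""Deterministic sensitivity analysis: one-way, two-way, and thresholds.

All sweeps use the noise-free cohort engine so that repeated runs are
identical to machine precision.  Composite parameter names accepted
everywhere: ``joint_adherence`` (surveillance and confirmatory-biopsy
adherence moved together on the diagonal) and ``p_late_to_mets_monthly``
(metastasis probability swept on the monthly scale).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import default_calibration
from .engine import run_cohort_expectation
from .life_tables import LifeTable, default_life_table
from .parameters import ParameterSet
from .states import TransitionContext
from .strategies import make_strategy

#: Strategies whose initial action is specialist referral for biopsy.
BIOPSY_FIRST_IDS = (2, 3, 4)


def _le(
    params: ParameterSet,
    strategy_id: int,
    table: LifeTable,
    ctx: TransitionContext,
) -> float:
    return run_cohort_expectation(
        params, make_strategy(strategy_id), table, ctx, default_calibration(params)
    ).life_years_mean


def _resolve_range(params: ParameterSet, name: str) -> tuple[float, float]:
    if name == "joint_adherence":
        return (0.5, 1.0)
    if name == "p_late_to_mets_monthly":
        return (0.001, 0.05)
    ranges = params.dsa_ranges()
    if name not in ranges:
        raise KeyError(f"unknown parameter {name!r}")
    return ranges[name]


def one_way_dsa(
    param_name: str,
    params: ParameterSet | None = None,
    value_range: tuple[float, float] | None = None,
    k_points: int = 11,
    strategy_ids: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8),
    table: LifeTable | None = None,
    ctx: TransitionContext | None = None,
) -> pd.DataFrame:
    """Cohort-engine life expectancy per strategy over a parameter sweep.

    Long-format output: (parameter, value, strategy_id, life_years).
    """
    params = params or ParameterSet.base_case()
    ctx = ctx or TransitionContext()
    table = table or default_life_table(ctx.sex)
    lo, hi = value_range if value_range is not None else _resolve_range(params, param_name)
    rows = []
    for value in np.linspace(lo, hi, k_points):
        p = params.with_overrides(**{param_name: float(value)})
        for sid in strategy_ids:
            rows.append(
                {
                    "parameter": param_name,
                    "value": float(value),
                    "strategy_id": sid,
                    "life_years": _le(p, sid, table, ctx),
                }
            )
    return pd.DataFrame(rows)


def tornado_summary(sweeps: list[pd.DataFrame]) -> pd.DataFrame:
    """Life-expectancy span of the top-ranked strategy for each parameter."""
    rows = []
    for df in sweeps:
        best = df.groupby("value")["life_years"].max()
        rows.append(
            {
                "parameter": df["parameter"].iloc[0],
                "le_min": best.min(),
                "le_max": best.max(),
                "span": best.max() - best.min(),
            }
        )
    return pd.DataFrame(rows).sort_values("span", ascending=False).reset_index(drop=True)


def two_way_dsa(
    param_a: str,
    param_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    params: ParameterSet | None = None,
    strategy_ids: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8),
    table: LifeTable | None = None,
    ctx: TransitionContext | None = None,
) -> pd.DataFrame:
    """Top-ranked strategy id over a two-parameter grid (ties to lower id)."""
    params = params or ParameterSet.base_case()
    ctx = ctx or TransitionContext()
    table = table or default_life_table(ctx.sex)
    matrix = np.zeros((len(grid_a), len(grid_b)), dtype=int)
    for i, va in enumerate(grid_a):
        for j, vb in enumerate(grid_b):
            p = params.with_overrides(**{param_a: float(va), param_b: float(vb)})
            les = {sid: _le(p, sid, table, ctx) for sid in strategy_ids}
            matrix[i, j] = min(les, key=lambda s: (-les[s], s))
    return pd.DataFrame(matrix, index=list(grid_a), columns=list(grid_b))


def find_threshold(
    param_name: str,
    strategies_a: Sequence[int],
    strategies_b: Sequence[int],
    bracket: tuple[float, float],
    params: ParameterSet | None = None,
    table: LifeTable | None = None,
    ctx: TransitionContext | None = None,
    tol: float = 1e-3,
    scan_points: int | None = None,
) -> float | None:
    """Parameter value where the preferred group flips, by bisection.

    The objective is ``max(LE of group a) - max(LE of group b)``; bisection
    on the cohort engine to absolute tolerance ``tol`` on the parameter.
    Returns None when the objective does not change sign in the bracket.

    When the objective may cross more than once (e.g. a strategy preferred
    only on an interior interval), pass ``scan_points``: the bracket is first
    scanned on that many grid points and bisection runs inside the
    sign-change interval closest to the upper bracket edge.
    """
    params = params or ParameterSet.base_case()
    ctx = ctx or TransitionContext()
    table = table or default_life_table(ctx.sex)

    def gap(x: float) -> float:
        p = params.with_overrides(**{param_name: float(x)})
        le_a = max(_le(p, sid, table, ctx) for sid in strategies_a)
        le_b = max(_le(p, sid, table, ctx) for sid in strategies_b)
        return le_a - le_b

    lo, hi = bracket
    if scan_points is not None:
        xs = np.linspace(lo, hi, scan_points)
        gs = [gap(x) for x in xs]
        interval = None
        for i in range(len(xs) - 1):
            if np.sign(gs[i]) != np.sign(gs[i + 1]):
                interval = i  # keep the last (closest to hi)
        if interval is None:
            return None
        lo, hi = float(xs[interval]), float(xs[interval + 1])
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo == 0.0 and g_hi == 0.0:
        return None  # no preference anywhere (e.g. identical groups)
    if g_lo == 0.0:
        return float(lo)
    if g_hi == 0.0:
        return float(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid == 0.0:
            return float(mid)
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
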