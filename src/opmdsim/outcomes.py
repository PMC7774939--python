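"""Result tables: strategy ranking, event tallies, and biopsy intensity."""

from __future__ import annotations

import pandas as pd

from .engine import RunResult


def _check(results: list[RunResult]) -> None:
    ids = [r.strategy_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strategy in results")
    if not results:
        raise ValueError("no results supplied")


def rank_strategies(results: list[RunResult], expect_ids=None) -> pd.DataFrame:
    """Strategies sorted by life expectancy (descending; ties by id).

    Columns: rank, strategy_id, label, life_years (full precision),
    life_years_rounded (0.01 yr), delta_vs_previous.
    """
    _check(results)
    if expect_ids is not None:
        missing = set(expect_ids) - {r.strategy_id for r in results}
        if missing:
            raise ValueError(f"missing strategies: {sorted(missing)}")
    rows = sorted(results, key=lambda r: (-r.life_years_mean, r.strategy_id))
    df = pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "strategy_id": [r.strategy_id for r in rows],
            "label": [r.label for r in rows],
            "life_years": [r.life_years_mean for r in rows],
        }
    )
    df["life_years_rounded"] = df["life_years"].round(2)
    df["delta_vs_previous"] = df["life_years"].diff().fillna(0.0).round(4)
    return df


def tally_events(results: list[RunResult], per: float = 1_000_000) -> pd.DataFrame:
    """Treated-cancer and progression tallies scaled to ``per`` patients.

    Early/late treated counts follow AJCC 1-2 vs 3-4 at the time of
    treatment; "dysplasia_to_cancer" counts malignant transformations during
    simulation (not prevalent baseline cancers); "new_metastases" counts
    transitions into the metastatic state after model entry.
    """
    _check(results)
    rows = []
    for r in results:
        ev = r.events_per_patient
        rows.append(
            {
                "strategy_id": r.strategy_id,
                "label": r.label,
                "early_stage_treated": ev["treated_early"] * per,
                "late_stage_treated": ev["treated_late"] * per,
                "dysplasia_to_cancer": ev["mt"] * per,
                "new_metastases": ev["new_mets"] * per,
            }
        )
    return pd.DataFrame(rows)


def biopsies_per_1000(results: list[RunResult]) -> pd.DataFrame:
    """Lifetime biopsies per 1000 patients, total and with benign histology."""
    _check(results)
    rows = []
    for r in results:
        ev = r.events_per_patient
        rows.append(
            {
                "strategy_id": r.strategy_id,
                "label": r.label,
                "biopsies_per_1000": ev["biopsy"] * 1000,
                "benign_biopsies_per_1000": ev["biopsy_benign"] * 1000,
            }
        )
    return pd.DataFrame(rows)


def biopsy_reduction(
    results: list[RunResult], reference_id: int, comparison_id: int
) -> dict[str, float]:
    """Relative biopsy reduction of one strategy versus a reference."""
    by_id = {r.strategy_id: r for r in results}
    ref = by_id[reference_id].events_per_patient
    cmp_ = by_id[comparison_id].events_per_patient
    return {
        "total_reduction_pct": 100.0 * (1.0 - cmp_["biopsy"] / ref["biopsy"]),
        "benign_reduction_pct": 100.0
        * (1.0 - cmp_["biopsy_benign"] / ref["biopsy_benign"]),
        "reference_per_1000": ref["biopsy"] * 1000,
        "comparison_per_1000": cmp_["biopsy"] * 1000,
    }
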