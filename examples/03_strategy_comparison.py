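"""Base-case life-expectancy comparison of the eight management strategies.

Runs the deterministic cohort-expectation engine (noise-free life
expectancy) for every strategy and prints the ranking table.
"""

import opmdsim as om

params = om.ParameterSet.base_case()
table = om.default_life_table("male")

results = om.run_all_strategies(params, table, engine="cohort")
ranking = om.rank_strategies(results, expect_ids=range(1, 9))

print("Life expectancy of 60-year-old men with OPMDs, by strategy:")
for _, row in ranking.iterrows():
    print(f"  {row['rank']}. [{row['strategy_id']}] {row['label'][:72]:<72} "
          f"{row['life_years']:.2f} yr")

les = {r.strategy_id: r.life_years_mean for r in results}
top = max(les.values())
print(f"\nTop strategy LE: {top:.2f} years; deferral: {les[1]:.2f} years "
      f"(gap {top - les[1]:.2f}).")
print(f"POCOCT mild|moderate (strategy 6) trails the top strategy by only "
      f"{top - les[6]:.3f} years (~{(top - les[6]) * 365:.0f} days),")
print("while avoiding routine referral of every visible lesion for biopsy.")
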