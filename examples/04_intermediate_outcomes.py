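"""Biopsy intensity and cancer-event tallies from the microsimulation.

Simulates individual patients (seeded) under routine biopsy referral
(strategy 3) and the POCOCT mild|moderate pathway (strategy 6), then
tabulates biopsies per 1000 patients and treated cancers per million.
"""

import opmdsim as om

N = 100_000
SEED = 1

params = om.ParameterSet.base_case()
table = om.default_life_table("male")
calib = om.default_calibration(params)

results = [
    om.run_microsimulation(params, om.make_strategy(sid), table, n=N, seed=SEED,
                           calibration=calib)
    for sid in (1, 3, 6)
]

print(f"Microsimulation, n = {N:,} patients per strategy, seed {SEED}.\n")
print(om.biopsies_per_1000(results).round(1).to_string(index=False))
red = om.biopsy_reduction(results, reference_id=3, comparison_id=6)
print(f"\nPOCOCT triage performs {red['total_reduction_pct']:.0f}% fewer lifetime "
      f"biopsies than routine referral ({red['reference_per_1000']:.0f} -> "
      f"{red['comparison_per_1000']:.0f} per 1000), and "
      f"{red['benign_reduction_pct']:.0f}% fewer biopsies of benign lesions.\n")

print(om.tally_events(results, per=1_000_000).round(0).to_string(index=False))
print("\nDeferring evaluation leaves most carcinomas untreated: dysplasia keeps")
print("transforming and metastatic disease is an order of magnitude more common")
print("than under any active strategy.")
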