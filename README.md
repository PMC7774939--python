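# opmdsim

A state-transition (Markov) microsimulation of **test-and-treat strategies for
oral potentially malignant disorders (OPMDs)** in primary dental care.

Visible oral lesions found at a routine dental exam may be benign, dysplastic,
or already cancerous, and the three are often indistinguishable by appearance.
Current guidance is to refer every such lesion to a specialist for scalpel
biopsy; in practice many are deferred instead. A point-of-care brush-cytology
test (POCOCT) that grades lesions chairside opens a third option: treat or
refer only test-positive lesions and surveil the rest. `opmdsim` is for health
services / decision-science researchers who want to compare these policies on
life expectancy and resource use, and to probe which assumptions the
comparison hinges on.

## The model

A cohort of 60-year-old men with asymptomatic OPMDs is simulated in 1-month
cycles until death (age cap 110). True health states are

```
benign -> mild dysplasia -> moderate dysplasia (low/high risk) -> severe
dysplasia -> early (undetected) OSCC -> late OSCC -> metastatic -> death
```

with regression of mild dysplasia, surgical treatment arcs into
post-treatment states, and background (non-cancer) mortality from a
Gompertz–Makeham life-table fixture fitted to U.S. male period-table values
(hazard *h(x) = c + a·e^{bx}*; remaining life expectancy at 60 = 21.32 y).
Annual probabilities *p* become monthly via constant-hazard compounding
`1 − (1 − p)^{1/12}`; simultaneous risks combine by hazard-proportional
allocation. Treated-cancer mortality is not an input: it is **calibrated** by
root finding so that constant monthly cancer-specific death probabilities
reproduce SEER 5-year cancer-specific survival by AJCC stage
(93.4 / 85.5 / 78.7 / 66.2 %), pooled 50/50 on the hazard scale into
early (I–II) and late (III–IV) treated states.

Eight management strategies are compared: (1) deferral, (2–4) biopsy-first
referral with varying surgery thresholds and surveillance, (5–8) POCOCT
triage at each of its four diagnostic splits (benign|mild, mild|moderate,
low|high-risk, moderate|severe) with POCOCT-based surveillance at months
6, 12, 24, 36, 48, 60 and imperfect adherence (0.92/0.82/0.72 per visit,
0.92 for confirmatory biopsy, 0.20 re-biopsy recommendation for lesions
previously categorized benign).

Two engines share one transition-branch builder, so they agree in
expectation: a deterministic **cohort-expectation engine** (noise-free life
expectancy, used for ranking and sensitivity analysis) and a seeded,
vectorized **microsimulation** (event tallies with common random numbers
across strategies).

## Worked example

```python
import opmdsim as om

params = om.ParameterSet.base_case()          # packaged parameter table
table = om.default_life_table("male")         # fitted life-table fixture
results = om.run_all_strategies(params, table, engine="cohort")
print(om.rank_strategies(results, expect_ids=range(1, 9)))
```

which (see `examples/03_strategy_comparison.py`) prints

```
Top strategy LE: 20.85 years; deferral: 20.52 years (gap 0.34).
POCOCT mild|moderate (strategy 6) trails the top strategy by only 0.018 years (~6 days),
while avoiding routine referral of every visible lesion for biopsy.
```

Biopsy-first referral maximizes life expectancy, deferring evaluation costs
about a third of a year, and the non-invasive POCOCT pathway gives up only
days of life expectancy. The microsimulation
(`examples/04_intermediate_outcomes.py`, n = 100,000, seed 1) quantifies the
trade: POCOCT triage performs 27 % fewer lifetime biopsies than routine
referral (961 → 697 per 1000 patients) at similar early-stage cancer
treatment rates (13,240 vs 13,560 per million).

The other examples cover calibration (`02`), the external validation
sub-model — a 53-year-old treated stage-I cohort with a 1.4 non-cancer
hazard ratio giving 19.80 years (`05`) — and deterministic sensitivity
analysis, including the monthly metastasis probability (~0.013) below which
POCOCT triage becomes the top-ranked strategy (`06`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch — stage-mortality
calibration, the eight-strategy cohort comparison, the seeded
strategy-6 microsimulation (biopsies per 1000, early-stage treated cancers
per million), the validation sub-model, and the sensitivity thresholds — and
writes them as JSON (runs in well under a minute).

## Layout

- `src/opmdsim/` — parameters, states, transitions, life tables, diagnostics,
  strategies, engines, calibration, outcomes, sensitivity
- `src/opmdsim/data/base_case.yaml` — the base-case parameter table with
  sensitivity ranges
- `examples/` — one narrative script per capability
- `docs/methods.md` — model description, assumptions, numerical choices, and
  known limitations
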