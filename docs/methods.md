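# Methods

## Model structure

`opmdsim` is an individual-level state-transition model of oral potentially
malignant disorder (OPMD) management with a 1-month cycle. A patient's *true*
state is one of: benign lesion; mild dysplasia; moderate dysplasia (split
into low- and high-risk substates so the WHO dichotomous classification is
expressible); severe dysplasia; undetected early (AJCC I–II) or late
(III–IV) oral squamous cell carcinoma; post-treatment dysplasia (lesion
removed); post-treatment early/late cancer; metastatic disease; death from
cancer; death from other causes. What a test *reports* about the lesion is
modeled separately (see Diagnostics), and the management layer tracks, per
patient, the surveillance clock and whether the lesion was previously
categorized benign.

Within each cycle events occur in a fixed order: (1) background and
disease-specific death, (2) scheduled management actions and tests,
(3) treatment, (4) natural-history progression. The source material for this
model class leaves the ordering unstated; the order above is this package's
contract and is covered by regression tests.

Both engines — the deterministic cohort-expectation engine and the seeded
microsimulation — consume the same enumeration of per-cycle outcome
*branches* (probability, next composite state, event tags), which guarantees
agreement in expectation and is verified to 3 Monte-Carlo standard errors at
n = 100,000. Life expectancy is half-cycle corrected: deaths are credited
half a month in their cycle of death.

## Parameters

All tabulated inputs live in `src/opmdsim/data/base_case.yaml` as
(value, low, high) triples; the low/high columns drive the deterministic
sensitivity analyses (rows published as 0.5×–2× the base-case estimate are
expanded at authoring time and clipped to 1). Key values: initial mixture
76.18 % benign, 11.54 % mild, 4.40 % moderate, 2.88 % severe, 5 % carcinoma
(27.31 % of it early stage); annual malignant-transformation probabilities
0.035 (moderate; 0.029/0.040 for the low/high substates), 0.084 (severe);
early→late progression 0.046/yr; late→metastasis 0.391/yr; surgical
mortality 0.002 per procedure; surveillance adherence 0.92/0.82/0.72 by
visit; confirmatory-biopsy adherence 0.92; re-biopsy recommendation for
previously-benign lesions 0.20.

Annual probabilities convert to monthly by constant-hazard compounding
`1 − (1 − p)^{1/12}`; simultaneous monthly risks are combined by summing
hazards and allocating the total event probability proportionally to the
individual hazards (order-independent, exact for small probabilities).

Structural choices the source leaves open, all exposed as configuration:

- **Moderate low/high split fraction** defaults to 50/50, making the
  mixture's mean transformation rate (0.029 + 0.040)/2 ≈ 0.035 match the
  pooled moderate rate.
- **Benign lesions are static** (no published benign→mild rate) and no new
  lesions arise after surgical removal; both rates exist as config fields
  defaulting to 0.
- **Metastatic death probability 0.127 is interpreted as monthly** (toggle
  `p_death_mets_is_annual`). The annual reading implies a median metastatic
  survival above five years, which is inconsistent with the
  survival-calibrated untreated pathway the model family describes and with
  observed survival in distant metastatic oral cancer (months, not years);
  under the annual reading the deferral strategy loses only ~0.11 years of
  life expectancy and the published comparative pattern is unreachable.
- **Post-surveillance indolence**: in strategies with surveillance,
  untreated lesions stop progressing after the last visit at month 60
  (toggle `progression_after_surveillance`). This follows the stated
  assumption that lesions below the treatment threshold remain indolent
  once the five-year surveillance window closes; the toggle's effect is
  about +0.06 years for the highest-threshold strategy
  (`examples/06_sensitivity.py`).
- **Charlson comorbidity** enters as a multiplicative hazard ratio on
  non-cancer mortality (default 1.0), alongside the validation sub-model's
  1.4 non-cancer hazard ratio.

## Background mortality (synthetic life table)

Background mortality comes from a Gompertz–Makeham hazard
`h(x) = c + a·e^{bx}` whose constants were fitted once, offline, to
published U.S. period-life-table anchors (male and female annual death
probabilities at ages 50–90 and remaining life expectancy at 60) and then
hard-coded. The male fixture gives e(60) = 21.3241 years (published ≈ 21.5,
well within the ±0.5-year band the fixture is required to meet), the female
fixture 24.3002. The fixture emulates the *level and age-gradient* of U.S.
all-cause mortality; it does not reproduce year-specific or cohort tables,
so absolute life expectancies carry a fraction-of-a-year fixture error that
cancels almost entirely from between-strategy differences. Any two-column
(age, q) CSV can be substituted.

## Diagnostics

POCOCT is modeled as a binary classifier at one of four diagnostic splits
with the published sensitivity/specificity per split; the positive sets are
nested (moderate|severe ⊂ low|high ⊂ mild|moderate ⊂ benign|mild). The
visual-tactile exam uses cancer sensitivity 0.71, dysplasia sensitivity 0.50
(also applied to severe dysplasia, which has no separately published value;
configurable), specificity 0.97. Scalpel biopsy grades the lesion exactly
with probability 0.98 and otherwise returns a benign call (sampling error);
benign lesions are never over-called at base case. Repeat tests are
conditionally independent given the true state.

## Management strategies

Eight policies: deferral; biopsy-first referral with surgery for any
dysplasia (without or with visual surveillance of benign results) or for
moderate-or-worse; and POCOCT triage at each split, with surgery thresholds
mirroring the split and POCOCT surveillance of below-threshold results.
Surveillance visits fall at months 6, 12, 24, 36, 48, 60; attendance is an
independent per-visit draw (0.92, 0.82, then 0.72; missing a visit does not
cancel later ones). A positive surveillance test leads to confirmatory
biopsy with probability 0.92, additionally multiplied by the 0.20
re-biopsy-recommendation probability when the lesion was previously
categorized benign — including by a negative initial POCOCT result. That
reading is load-bearing: without it, POCOCT surveillance generates more than
double the published biopsy volume, and with it the per-1000 biopsy counts
fall within about 2 % of the published values. The initial referral for
biopsy in the biopsy-first strategies is gated by the same 0.92 adherence
(the published treated-cancer counts match only under that choice);
non-adherent patients enter surveillance where the strategy has it,
otherwise they receive no further care. In the deferral strategy, undetected
early cancer presents symptomatically at annual probability 0.13 and late
cancer at 0.30, each followed by visual exam, biopsy, and treatment;
active strategies have no symptomatic-presentation pathway (the published
missed-cancer outcomes imply none). Metastatic disease is never a surgical
candidate and keeps the metastatic death rate regardless of detection.

## Calibration

Treated-cancer mortality is recovered, not assumed: a constant monthly
cancer-specific death probability per AJCC stage is found by bracketed Brent
root finding so that re-simulated 5-year cancer-specific survival (background
deaths censored, matching SEER cause-specific semantics — hence analytically
`(1 − p)^{60}`) hits 93.4/85.5/78.7/66.2 %. Stage pairs pool into the two
treated states by an arithmetic mean of monthly hazards with 50/50 weights
(no within-pool distribution is published; weights configurable). The
calibrated mortality applies for the remainder of life — no cure point —
which is the standard reading of lifetime states calibrated to 5-year
survival. `verify_printed_calibrations` audits the published calibrated
rates without changing them; it reports, in particular, that the published
0.04/yr mild-dysplasia regression implies 24.9 % regression over seven years
rather than the stated 30 % anchor (exact match would need 0.0497/yr).

## Numerical choices

Root finding: Brent on [0, 0.5], parameter tolerance 1e-12. Threshold
(preference-flip) analysis: bisection on the cohort-engine life-expectancy
difference to 1e-3 (2e-4 for the metastasis threshold) on the parameter,
with an optional pre-scan to bracket the sign change when the objective
crosses more than once; ties in strategy ranking break toward the lower
strategy id. Transition rows are proper to 1e-12. The microsimulation
pre-draws each patient's initial state and background death month from
streams keyed by the seed alone (common random numbers across strategies)
and samples disease/test/adherence branches from a per-strategy stream;
within-month simultaneous background and disease death is attributed to
background in the microsimulation and split hazard-proportionally in the
cohort engine (life expectancy is unaffected; cause attribution differs at
second order in monthly probabilities). The horizon includes the closing-age
cycle (q = 1 at age 110), so no live mass survives the run.

## What the synthetic world does and does not establish

The generator emulates the stated world: the published lesion mixture, test
characteristics, adherence pattern, and a U.S.-style male life table. It
does not emulate secular trends in mortality, competing oral-cavity risk
factors (tobacco/alcohol heterogeneity beyond the single hazard-ratio knob),
lesion multiplicity, or correlated repeat-test errors. A green test
therefore establishes internal correctness (engines agree, oracles match,
operating characteristics are honored) and reproduction of the published
comparative pattern under these assumptions — not calibration to any real
cohort.

## Known limitations

- The joint surveillance/biopsy adherence flip published at ≥ 0.88 does not
  reproduce: in this implementation the best biopsy-first strategy retains a
  small (≤ 0.02-year) life-expectancy edge over POCOCT triage everywhere in
  the swept range, under every defensible reading of which gates the
  adherence parameters control. The threshold machinery reports the absence
  of a crossing rather than a value; the corresponding acceptance test is an
  expected failure.
- Between-strategy life-expectancy differences are of order days; they are
  meaningful under the deterministic cohort engine but should not be read as
  clinically precise.
- Treated dysplasia cannot recur and treated cancer cannot metastasize as a
  distinct event (its calibrated mortality absorbs metastatic deaths); the
  state diagram has no recurrence arcs.
- The model is male, age-60 by default; the female life table is provided
  but no female-specific disease parameters exist.
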