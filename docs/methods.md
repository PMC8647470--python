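# Methods

## Model structure

The model is a discrete-time Markov cohort over six mutually exclusive
states: `CONTROLLED`, three escalating exacerbation states (`EXAC_OCS`,
`EXAC_ED`, `EXAC_HOSP`), and two absorbing death states (`DEATH_ASTHMA`,
`DEATH_OTHER`). The cycle length is 2 weeks, with exactly 26 cycles per
52-week year so that the 52-week adherence switch falls on a whole cycle.
Exacerbation states are single-cycle tunnels: an occupant either escalates
one severity level, dies, or returns to `CONTROLLED` in the next cycle. This
matches a natural-history reading in which an exacerbation episode spans
roughly one 2-week cycle per severity level.

Competing risks within a cycle are composed mortality-first: the per-cycle
background death probability `q` (from the life table, converted from the
annual probability by `1 − (1−q)^(1/26)`) is applied to every alive state,
and all disease transitions are scaled by `(1 − q)`. Rows therefore sum to 1
for any admissible inputs; the engine verifies this at build time (1e-12) and
on the cohort trace (1e-10).

Asthma mortality (0.0002 per cycle) applies from all three exacerbation
states. Only hospitalization-level deaths would be a defensible alternative;
the all-exacerbation reading is the simpler one and the probability is small
enough that the choice is immaterial to the base case.

## Treatment arms and adherence

Both arms share the disease dynamics; triple therapy multiplies the
controlled→OCS-burst probability by RR = 0.85 (range 0.78–0.92) while the
patient is on treatment, and adds the LAMA acquisition cost. At cycle 26 the
cohort splits: a fraction equal to the 52-week persistence (0.63 triple, 0.56
dual) keeps the treatment effect and drug cost; the rest revert to RR = 1 and
the dual-therapy drug cost. No "untreated" natural history is modelled, so
discontinuation on the dual arm is economically neutral by construction. The
split is implemented as two sub-cohorts carried from cycle 0 whose matrices
and costs diverge at cycle 26 — algebraically identical to splitting the
alive mass at the switch, but simpler to account. Persistence ranges are
stored on the 52-week proportion itself (not converted to a per-cycle
discontinuation hazard), which is how the published ranges are printed.

## Rewards, discounting, half-cycle correction

* QALYs: occupancy × state utility × (2/52) years. State utilities are the
  controlled utility 0.74 minus the decrement of the occupied exacerbation
  state (0.10 OCS, 0.15 ED, 0.20 hospital), applied for the full cycle.
* Costs: drug acquisition per cycle alive (4-week pack price × 2/4), plus
  per-episode event costs charged once on entry to an exacerbation state —
  which, with single-cycle tunnels, equals occupancy. The ED visit costs
  US$26; hospitalization is priced per day (US$80) times a configurable
  length of stay (`hosp_los_days`, default 5 days — the stay length is not
  part of the published set and the default is deliberately exposed in the
  DSA-ready config). The OCS-burst episode cost is likewise unpublished and
  defaults to 0; zero-valued costs are excluded from DSA/PSA rather than
  invented.
* The triple arm's LAMA price is a market-share-weighted mix of tiotropium
  (US$60/4 wk), umeclidinium and glycopyrronium (US$32/4 wk each); shares are
  unpublished, so the default is equal thirds (`triple_drug_mix`).
* Discounting: 5%/year (range 0–6%), applied per cycle as `(1+r)^(−t/26)`.
* Half-cycle correction (default on): trapezoid weights 0.5 on the first and
  final rows of both cost and QALY streams. With the correction off, rewards
  accrue on cycle-start occupancy (rows 0..N−1), so a quiescent 1-year run at
  unit utility accrues exactly 1.0 QALY — the convention the unit tests pin
  down with a closed-form geometric-series oracle.
* Horizon: "lifetime" means age 100 or an alive mass below 1e-9, whichever
  comes first; the cohort starts at age 18 (configurable; no starting age is
  published) fully controlled.

The 1-year exacerbation-free probability is computed exactly by making the
exacerbation states absorbing for 26 cycles; it is the probability of no
exacerbation entry during the first model year (death without exacerbation
counts as exacerbation-free — the published definition of "surviving free of
exacerbation" is not precise enough to distinguish the variants, and the
quantity is only used for ordering the arms).

## Background mortality

No national life-table values are distributed with the package. The packaged
default is a synthetic Gompertz–Makeham table,
`q(x) = 1 − exp(−(a + b·e^(c·x)))` with a = 5e-4, b = 3e-5, c = 0.09, chosen
once to give adult mortality of realistic order for a middle-income
population (q(40) ≈ 1.6e-3, q(80) ≈ 0.04, ~6% of the cohort alive at 100). A
real life table supplied as CSV (optionally sex-stratified; sexes are
averaged) takes precedence everywhere, including the acceptance script.

## Sensitivity analysis

Ranges are the published low/high where printed and otherwise base ± 25%
clipped to the role's bounds. One printed row (controlled→OCS) has its high
equal to its base; the printed value is kept by default and a `strict_25pct`
flag recomputes it as base × 1.25. The relative-risk row prints its ends in
reverse order and is normalized to (0.78, 0.92).

The one-way DSA sets each of the 18 ranged parameters in turn to its low and
high (all others at base), recomputes the ICER, and reports tornado rows
sorted by spread plus a flag for any ICER above the US$19,000/QALY
willingness to pay.

The PSA reads each range as a central 95% interval (sd = width/3.92 — the
same reading under which the RR row's range is its published 95% CI) and
moment-matches: beta for RR, utilities, decrements and the two adherence
proportions (proportions are beta-distributed even though the published
distribution list omits them); gamma for costs; Dirichlet for transition
probabilities, with the effective sample size solved from the beta-marginal
variance identity `p(1−p)/(N+1) = s²` and the residual (stay/return) branch
taking the remaining concentration. Degenerate ranges collapse to fixed
values. Parameters are sampled independently, with utilities, event costs and
transition probabilities shared across arms within a replicate; 1000
replicates by default. Invalid draws (a composed row leaving the simplex, or
a sampled decrement exceeding the sampled controlled utility) are rejected
and redrawn, aborting above 5% rejections; at the default ranges no draws
are rejected.

Decision summaries: quadrant shares of the (ΔE, ΔC) cloud with boundary
zeros assigned to quadrant 1 and ties in net monetary benefit counted as not
cost-effective (both conservative toward the intervention); the CEAC on a
$0–2,000 grid in $50 steps plus the WTP point; and the probabilistic ICER as
the ratio of mean increments (per-replicate ICERs are unstable and are not
averaged).

## Validation oracle

`asthmacea.microsim.simulate_patients` walks individual patients through the
exact per-cycle matrices of the cohort engine with identical reward,
half-cycle and persistence conventions, so its sample means estimate the same
expectations. The test suite checks agreement within 3 Monte Carlo standard
errors at n = 50,000 on the default parameter set (and on truncated horizons
for speed elsewhere), plus pointwise agreement of the survival curve within
binomial error. `random_parameter_table` fuzzes the whole pipeline with
random-but-valid bundles (probabilities in (0, 0.9), utilities in (0.3, 1),
costs in (1, 500), RR in (0.5, 1)) for the conservation and absorption
property tests.

## Problem sizes

Default analyses run the full horizon (2,132 cycles). The test suite uses
1000 PSA replicates for the probabilistic checks, n = 50,000 patients for the
full-horizon oracle comparison, truncated horizons (ages 18–30/40) for the
remaining microsimulation tests, and 100 fuzzed bundles on 12-year horizons
for the property sweep. The acceptance script runs the deterministic base
case plus the 1000-replicate PSA.

## What the synthetic data does and does not show

The synthetic life table reproduces the shape, not the values, of a national
table; absolute life expectancy, and hence lifetime totals, shift with the
real table supplied. The generator has no patient heterogeneity (no
covariates, frailty or severity mixture), no seasonality in exacerbation
risk, and treats adherence as a single 52-week cliff rather than a gradual
hazard. Passing tests therefore demonstrate internal correctness of the
estimators and their agreement with an independent simulator — not external
validity of the parameter set.

## Known limitations

* Drug acquisition cost dominates the incremental cost at the packaged
  prices; conclusions are highly sensitive to the LAMA price and to the RR.
* Event costs are charged once per episode entry; multi-week hospitalizations
  longer than one cycle are priced through `hosp_los_days` rather than
  extended occupancy.
* No indirect/societal cost components, no EVPI, no correlation structure
  between sampled parameters, and no age- or sex-specific utilities or event
  costs.
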