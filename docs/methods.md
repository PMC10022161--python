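# Methods

## Decision problem and model structure

The package evaluates elective open mesh repair of primary inguinal hernia
for adult Ghanaian men against a no-treatment comparator, from a
healthcare-system perspective, and projects the affordability of a national
scale-up. The cohort model has six mutually exclusive health states — new
hernia, repaired hernia, recurrent hernia (each subdivided into four pain
severities: none, mild, moderate, severe) and absorbing death — advanced in
one-year cycles. Everyone starts in *new hernia* at age 50 with pain
severities drawn from the untreated-state distribution; the base-case
horizon is 10 cycles and the cohort numbers 707,121 men.

Within a cycle, events are ordered: death risks first, then transitions
among survivors. Background mortality q(age) applies to every living state;
the unrepaired states (new, recurrent) additionally face the
hernia-attributable premature-death risk r, composed as independent
competing risks, p_death = 1 − (1 − q)(1 − r), so a row probability never
exceeds one. Deaths are attributed background-first: q to background,
(1 − q)·r to the hernia. Survivors of the new (and, by default, recurrent)
state are repaired at the repair rate (100% in the base case; the treated
arm only), repaired patients return to *new* via the contralateral risk or
to *recurrent* via the recurrence risk. Pain severity is assigned on state
entry from the destination state's distribution and kept until the state
changes — pain transitions within a state are not modelled. The cohort is
propagated as expected fractional occupancy (no sampling); totals are
conserved to machine precision, which the tests assert at 1e-6 persons.

Whether recurrent hernias may be re-repaired within the horizon is not
determined by the source description; the default allows it at the same
repair rate (a recurrent hernia is an untreated hernia), and the
`repair_recurrent` flag turns it off. The premature-death risk likewise
applies to the recurrent state by default.

## Parameters

All money is 2020 USD; all risks are annual probabilities.

| parameter | default | note |
|---|---|---|
| starting age | 50 years | varied to 60 in scenario analysis |
| time horizon | 10 one-year cycles | |
| cohort size | 707,121 persons | consumed as an input, not derived |
| repair rate | 1.0 / cycle | treated arm |
| recurrence risk | 0.00376 / person-year | |
| contralateral risk | 0.00380 / person-year | |
| complication risk | 0.0056 / patient-year | upper published bound, chosen because the cohort is relatively old |
| complication case fatality | 0.20 | conservative assumption |
| premature-death risk | 0.00112 | derived: 0.0056 × 0.20, overridable |
| discount rate | 3% / year | costs and DALYs alike |
| half-cycle correction | on | |
| cost per procedure | 123.40 (MD) / 132.71 (surgeon) | component sums are 123.38 / 132.69; the printed totals are kept as defaults |
| disability weights | 0 / 0.011 / 0.114 / 0.324 | GBD-2017 weights for the four severities; IPQ scores 1 / 2–3 / 4–5 / 6–7 |

Costs are consumed as already converted to 2020 USD; the package contains
no currency or inflation machinery.

## Outcome accrual

DALY = YLD + YLL, without age or time weighting.

The single-shot reading of the burden formulas (disability weight × full
remaining life expectancy at surgery) double-counts when embedded in a
cycle model, so the engine accrues **YLD as disability weight ×
person-time per cycle within the horizon**, the standard Markov practice
and the only reading under which treated-arm YLD falls after repair.
`closed_form_daly_per_person` reproduces the literal single-shot formula
for comparison; a test asserts it strictly exceeds the cycle-accrued
per-person burden. **YLL counts hernia-attributable deaths only** —
background mortality is identical across arms and would cancel in the
increment while inflating both totals — valuing each death at the remaining
life expectancy ex(age) from the life table, discounted at the death cycle.

Half-cycle correction averages beginning- and end-of-cycle occupancy for
person-time and shifts health-outcome discounting to mid-cycle,
(1 + r)^−(t−0.5) for cycle t ≥ 1. Procedures are booked at the start of the
cycle in which they are performed and discounted at (1 + r)^−t; with a 100%
repair rate nearly all spending falls in cycle 0 and is undiscounted, and
the half-cycle toggle deliberately affects outcome accrual only.

## Incremental analysis

ICER = (C_i − C_c) / (E_c − E_i) in USD per DALY averted, reported only
when informative (both increments positive, or both negative); corner cases
map to dominance verdicts (cheaper-and-no-worse dominates; equal cost and
effect ties). Verdicts against a willingness-to-pay band (371–491 USD/DALY
for Ghana): below the band — cost-effective, above — not, inside or
undefined — uncertain. Per-patient averages are totals divided by cohort
size.

## Sensitivity analysis

The one-way analysis re-runs the full pipeline with exactly one input at
±20% (procedure costs, the three non-zero disability weights, recurrence,
contralateral and premature-death risks) and adds three structural rows run
as labelled scenarios: starting age 50→60, discount 3%→3.5%, half-cycle
on→off. Rows are tornado-sorted by absolute ICER spread; rows whose spread
is below one cent are flagged `negligible` so they can be dropped from the
figure (the premature-death risk was dropped this way in the source
analysis; under the shipped stand-ins its spread is small but visible).

The probabilistic analysis draws five inputs from their published normal
distributions (disability weights mild/moderate/severe, recurrence and
contralateral risks); inputs without a published distribution stay at base
case. Draws are truncated to [0, 1] by resampling, and the rare draw that
breaks the severity ordering of the weights is redrawn, keeping every
sampled parameter set valid. Each iteration re-runs both arms; 1,000
iterations by default. Randomness is a single user seed expanded into
per-iteration substreams (`numpy` `SeedSequence.spawn`), so runs are
bit-reproducible and individual iterations are independent. Acceptability
curves use net monetary benefit: at willingness-to-pay λ an iteration
counts as cost-effective when λ·ΔE − ΔC > 0; the curve is the fraction of
iterations passing, by construction non-decreasing in λ whenever all
iterations avert DALYs.

## Budget-impact simulator

Years 2020–2030. The untreated backlog starts at 1,000,000, grows by
annual incident cases and shrinks by repairs. Incidence is not published;
it is set so the 2020 backlog of about one million grows to the roughly 1.4
million cases treated through 2030 absent intervention: (1.4e6 − 1.0e6)/10
= 40,000/year, overridable in config. The existing workforce repairs 1.57%
of the prevalent backlog per year (≈15,700 repairs).

Each year, repairs are the largest whole-person volume simultaneously
within (i) the plan — either "as much of the backlog as possible" or a
per-year schedule whose undelivered volume carries forward — (ii) workforce
capacity, providers × productivity, including this year's trainee intake
(intake is allowed only during the initial ramp years, up to an annual
cap), and (iii) the budget cap, found by integer bisection since annual
cost is monotone in volume. Annual cost = repairs × unit cost + new
trainees × USD 2,000 + newly activated facilities × USD 18,000, with
providers housed two per facility. Health gains price each repair at the
cohort model's per-patient incremental DALYs averted (≈1.09 at base case),
keeping both halves of the analysis on one set of assumptions.

Scenario 1 (conservative): USD 10M annual cap, productivity 50
repairs/provider/year, 250 trainees/year over a 5-year ramp. Scenario 2
(aggressive): no cap, productivity 200, 400 trainees/year over 3 years,
with a repair schedule interpolating the backlog linearly down to 30%
remaining by 2025 and zero by 2030. Under these defaults scenario 2 clears
the backlog exactly in 2030 at a total cost near USD 188M for ~1.57M DALYs
averted while training ~900 providers; a schedule that front-loads more
volume would need closer to 1,200, which is why the trained-provider count
is the output most sensitive to the (configurable) schedule shape. The
budget-impact one-way analysis varies training and renovation costs ±20%
and increments providers-per-facility and productivity, reporting the
final-year backlog for capped scenarios and cumulative cost for
elimination scenarios.

## Synthetic stand-ins

Two inputs of the original evaluation are unpublished and are emulated:

- **Life table.** A Gompertz–Makeham hazard μ(x) = a + b·e^{cx}
  (a = 0.004, c = 0.085/year) integrated to annual death probabilities,
  with the scale b solved by bisection so remaining life expectancy at age
  50 equals 25 years — a plausible value for Ghanaian men in 2016 — giving
  e0 ≈ 63.7 years. ex comes from the standard life-table recursion and is
  cross-checked in tests against a direct survival summation.
- **Pain distributions.** Categorical distributions over IPQ scores 1–7
  per health state, aggregated to the four severities (1 → none, 2–3 →
  mild, 4–5 → moderate, 6–7 → severe). The shipped values were produced by
  `calibrate_to_paper` — a Nelder–Mead search over the severity logits of
  the untreated and repaired states (recurrent mirrors untreated)
  minimising squared relative error against the published aggregate DALY
  totals (870,469.63 untreated / 101,718.64 treated) — then frozen. The
  calibrated stand-ins imply a mean untreated disability weight of 0.127
  and post-operative 0.006.

What this does and does not show: with the stand-ins, the pipeline
reproduces the published aggregate DALY totals (by construction), lands
within ~2% of the published ICERs, and respects every structural property
(conservation, absorption, ledger identities). It does **not** establish
that the stand-in pain prevalences match the unpublished cohort data — only
that a plausible configuration exists under which the published aggregates
arise. The discounted repair volume is ~2% below the volume implied by the
published incremental cost; no free parameter exists on the cost side, so
that residual is reported, not tuned away. Calibration is optional tooling,
separate from the deterministic base pipeline, and its tests use only
model-generated targets (parameter-recovery), never the published numbers.

## Numerical choices and problem sizes

- Probabilities must sum to 1 within 1e-9 (distributions) and rows of the
  transition matrix within 1e-12; cohort conservation is asserted at 1e-6
  persons.
- Degenerate inputs fail fast with the offending field named: negative
  rates, partial pain distributions, ages outside the life table, horizons
  beyond coverage, hazards reaching q ≥ 1 before the table's end.
- A zero-repair year under an infeasibly low budget cap is allowed and
  flagged rather than an error.
- Default analysis sizes: 1,000 probabilistic iterations (10,000 for the
  moment-recovery bias test), 11 budget-impact years, 106-row life table.
  The full test suite and the reproduction script each run in seconds.

## Known limitations

- Deterministic cohort (expected values): no individual-level variance, so
  probabilistic results reflect parameter uncertainty only.
- The budget-impact trainee schedule is a simple ramp-with-cap; real
  workforce growth is lumpier and constrained by factors not modelled
  (the published discussion lists several).
- Costs enter as fixed 2020-USD unit costs; no economies of scale,
  inflation or exchange-rate dynamics.
- The comparator is strict no-treatment; partial self-resolution or
  emergency repair of untreated hernias is not modelled beyond the
  premature-death risk.
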