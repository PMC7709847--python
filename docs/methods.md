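# Methods

## The model

`teleroi` evaluates the economics of an outpatient specialist clinic under
three care-delivery models, from the separate perspectives of each hospital
site involved:

* **telehealth** — the patient stays at the rural site and consults a
  specialist at a metropolitan partner over videoconference; the rural site
  pays its own clinic staff plus part of the partner's administration time,
  and each side claims its own activity-based-funding stream (consultant
  provider side vs patient recipient side);
* **patient travel** — the patient travels to a regional hospital for
  in-person care; the regional hospital staffs the clinic and claims the
  in-person funding, while the rural site earns nothing and subsidises
  travel for the fraction of patients who claim the subsidy scheme;
* **virtual health practitioner** — the rural site directly employs the
  specialist, who works off site over videoconference; the rural site bears
  all staffing costs and claims the consultant-side funding itself.

For a site *s* under model *m* the yearly cost and income cells are

```
cost(s, y)   = clinic_cost(s) x clinics(y) x d(y)  [+ subsidy(y) if s bears it]
clinic_cost  = sum over staff lines of  wage x (1 + on-cost) x hours
subsidy(y)   = base population(y) x uptake x average claim cost x d(y)
income(s, y) = attended(y) x sum of claimed per-appointment rates(y)
```

with `attended(y) = bookings(y) - FTA(y)` (failure-to-attend appointments
earn nothing) and `d(y)` a divisive price-discount factor (below).  Over the
evaluation horizon,

```
net benefit = total income - total cost
ROI (%)     = 100 x net benefit / total cost          (undefined at cost 0)
breakeven   = smallest integer b with b x rate >= clinic cost
```

A site with positive clinic cost and no funding claim can never break even
and is reported as `unreachable`.

## Parameters and defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| on-cost fraction | 0.23 medical officers, 0.29 others | – | employer overheads per the workplace agreements behind the bundled wage table; other values are accepted with a warning |
| discount rate | 2.5 %/year, divisive | – | wage/travel price escalation: earlier years are base-year prices divided by 1.025 per year back |
| travel-subsidy uptake | 0.17 | fraction | observed uptake in the source region's annual reporting |
| average subsidy claim | A$1447 | A$/claimant | the same annual reporting (A$14.48M over 8623 supported patients is ≈A$1679; the rounder A$1447 figure is used as published) |
| subsidy base population | `all_bookings` | – | see calibration notes below; `attended_only` is configurable |
| FTA sensitivity bounds | 10 % / 35 % | rate | customary low/high reporting bounds |
| uptake sensitivity grid | 17 % / 25 % | fraction | observed and hypothetical uptake |
| breakeven reference year | last activity year | – | the base-price year, whose calibrated rates reproduce all three derivable published breakeven counts |

Money is held as exact decimals; rounding happens only at reporting points
(half-up to cents per clinic line, half-up to whole dollars per annual
cell).  Multi-year totals are sums of the rounded yearly cells, and ROI is
computed from those totals, matching how the published summary table is
assembled.

## Calibration of the bundled scenario

The bundled fracture-clinic scenario transcribes published activity, wage
and funding tables.  Three quantities the source never states directly are
calibrated from it and shipped as auditable configuration:

* **Funding rates.**  The source prints annual income per site but not A$
  per appointment.  Each rate ships as an `{income, attended}` pair resolved
  to `income / attended` at load time; feeding it back through the income
  engine reproduces every printed income cell to within A$1.  Three streams
  are needed: consultant-side telehealth provider, patient-side telehealth
  recipient, and an in-person provider stream for the travel model, whose
  printed incomes are *not* attended x the telehealth provider rate (they
  calibrate to their own rate series, and give the travel provider's
  published 93% ROI; the telehealth-provider rates would give 89%).
* **Discount schedules.**  The published cells are only reproduced by
  *divisive* factors (base-year cost / 1.025^k), and the earliest year uses
  k = 3 for staffing components but k = 2 for the travel model (regional
  staffing and the subsidy).  The source states only "2.5% per year"; both
  calibrated schedules ship in the scenario document rather than being
  silently unified.
* **Subsidy base population.**  The source describes the subsidy as
  covering 17% of the *non-FTA* population, but its printed subsidy cells
  equal `total bookings x 0.17 x 1447` exactly.  The bundled policy
  therefore uses `all_bookings`; `attended_only` remains available.

### Reported-cost pins and source rounding

Six per-clinic wage lines print figures that differ from
`rate x (1 + on-cost) x hours` by A$0.01–0.02 (e.g. 261.13 printed vs
261.15 computed).  Those lines carry the printed figure as a
`reported_cost` pin, validated to lie within A$0.03 of the formula, so that
the printed site totals (351.12 / 1754.52 / 1341.42 / 1925.66 A$ per
clinic) are reproduced exactly.

Two yearly cost cells of the published summary are internally inconsistent
at the A$1 level: the rural telehealth costs for the last two years print
140,361 and 143,870 where the arithmetic gives 140,361.6 and 143,870.64.
No rounding rule reproduces them together with the rest of the table
(truncation would fix them but breaks 154,053, computed 154,052.8, and
279,445, computed 279,444.64).  The engines keep uniform half-up rounding;
those cells and their three-year sum are documented as matching within A$1
per cell (A$2 for the sum).  A few published income figures carry the same
±A$1 noise (292,785 / 496,281 / 118,439 / 418,839 differ by A$1 from sums
or differences of their own printed components).

### Published figures that do not follow from the published inputs

Three published claims cannot be derived from any shipped configuration and
are deliberately excluded from the golden set (a regression test asserts
what the method actually yields):

* the narrative claim that the rural site breaks even at **3** attended
  patients under the virtual-practitioner model — the provider-rate
  calculation gives 9 (both streams together would give 6);
* the 25%-uptake subsidy cells for the two later years (425,234 and
  391,146) — exact linearity in uptake gives 435,865 and 410,948; only the
  earliest year's printed cell matches the 25/17 scaling;
* the FTA sensitivity bounds printed for the travel provider and for the
  earliest telehealth-recipient year, which reuse a different rate than the
  same row's base income implies; sweeps recompute bounds from each site's
  own calibrated stream.

## Synthetic activity generator

The generator emulates the statistical shape of an aggregate activity
report: yearly clinics ~ Poisson(mean) with zero-clinic years rejected,
bookings ~ Poisson(clinics x bookings-per-clinic mean), and independent
binomial splits for FTA, new-vs-review and adult-vs-pediatric mixes.  One
integer seed drives a single `numpy` Generator stream, so output is
bit-reproducible.  Defaults are the bundled scenario's aggregate scale
(65 clinics/year, 13.8 bookings/clinic, FTA 0.26, 55% new, 27% pediatric).

It does **not** emulate patient-level structure: no arrival times, case-mix
severity, year-on-year volume trends (the real clinic quadrupled between
its first and second year), or correlation between FTA and patient mix.
Passing tests therefore demonstrate the pipeline's accounting is correct on
realistically sized aggregates, not that real clinics behave like Poisson
draws.

## Numerical choices and degenerate inputs

* Exact `Decimal` arithmetic (28 significant digits) end to end; property
  tests allow 1-ulp slack where multiplication order differs.
* Half-up rounding everywhere a figure is reported (cents, then whole
  dollars); never banker's rounding, which published finance tables do not
  use.
* FTA-rate overrides keep attendance fractional before multiplying by the
  rate, making income exactly linear in (1 − FTA rate); recorded FTA counts
  win over rates when both are supplied, and a rate converts to a count by
  half-up rounding.
* Breakeven at an exact multiple needs no extra appointment
  (`500 / 100 -> 5`); zero clinic cost breaks even at 0; zero rate with
  positive cost is `unreachable` (a distinct sentinel, never 0).
* Zero total cost makes ROI undefined (`None`, rendered `N/A`), never 0 or
  −100.
* Financial-year labels are opaque ordered strings; ordering comes from the
  activity list, never from parsing the label.

## Problem sizes

Everything is desk scale: three activity years, at most seven staffing
lines per model, three funding streams.  The full test suite (including the
10⁴-pair breakeven ceiling sweep and 200-year generator convergence runs)
completes in a few seconds on one CPU.

## Known limitations

* Income streams are not discounted to present value (only wages and travel
  are, following the source's convention).
* No capital, equipment or videoconferencing-infrastructure costs, no
  overheads, and no currency-year conversion.
* Rates are exogenous: the funding bodies' rate-setting is not modelled.
* Substitution between telehealth and in-person care is out of scope; FTA
  rates are assumed identical across the three models.
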