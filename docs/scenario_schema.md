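# Scenario document schema (version 1)

A scenario is one YAML (or JSON) document with four sections under a
required `schema_version: 1`.  The bundled example
(`src/teleroi/data/fracture_clinic.yaml`, exportable via `teleroi fixture`)
exercises every feature.

## `discount_schedules`

A mapping of schedule name → schedule.  Two forms:

```yaml
discount_schedules:
  staffing:                       # divisive form: factor = 1/(1+rate)^k
    base_year: "2016-2017"
    annual_rate: 0.025
    years_back: {"2014-2015": 3, "2015-2016": 1, "2016-2017": 0}
  explicit:                       # literal factors
    base_year: "2016-2017"
    factors: {"2015-2016": 0.9756097561, "2016-2017": 1}
```

The base year's factor must be exactly 1; all factors must be positive.

## `activity`

One entry per financial year, in evaluation order (labels are opaque):

```yaml
activity:
  - {year_label: "2016-2017", total_bookings: 1136, clinics_held: 82,
     new_bookings: 612, review_bookings: 524,
     adult_bookings: 915, pediatric_bookings: 221, fta_count: 318}
```

Invariants: `new + review = total`, `adult + pediatric = total`,
`0 <= fta_count <= total`.  `fta_rate` may be given instead of `fta_count`
(converted by half-up rounding of `rate x total_bookings`); a count wins
when both appear.

## `funding_streams`

A$ per attended appointment, per year.  A rate is a number or an
`{income, attended}` calibration pair (resolved to `income / attended`
exactly at load time):

```yaml
funding_streams:
  - stream_id: telehealth_provider
    label: "Telehealth consultant provider (NWAU 20.29 class)"
    rates:
      "2016-2017": {income: 184082, attended: 818}
      "2015-2016": 256.24
```

Every year referenced by the activity table must have a (possibly zero)
rate in every claimed stream.

## `care_models`

```yaml
care_models:
  - model_id: telehealth
    sites:
      - {site_id: rural, role: referral}
      - {site_id: metro, role: provider}
    staff_discount_schedule: staffing      # name from discount_schedules
    staff_lines:
      - {site_id: metro, role_name: "Radiographer",
         hourly_rate: 50.61, on_cost_fraction: 0.29, hours_per_clinic: 4,
         reported_cost: 261.13}            # optional printed-figure pin
    income_claims:
      metro: [telehealth_provider]         # a site absent here earns zero
      rural: [telehealth_recipient]
    travel_policy:                         # optional subsidy burden
      site_id: rural
      uptake_fraction: 0.17
      average_cost_per_claimant: 1447
      base_population: all_bookings        # or attended_only
      discount_schedule: travel_model      # defaults to the staff schedule
```

Validation: every `site_id` used by staff lines, income claims or the
travel policy must be declared under `sites`; `reported_cost` must lie
within A$0.03 of `hourly_rate x (1 + on_cost_fraction) x hours_per_clinic`;
on-cost fractions outside {0.23, 0.29} load with a warning.

Violations raise `ScenarioValidationError` with a path into the document;
the CLI exits 4 (3 for an unreadable file).
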