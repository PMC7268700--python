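# Methods

This note documents the model implemented by `hospexp`, its assumptions, the
synthetic parameter generator, and the numerical/design choices that were
genuinely open.

## Model structure

The simulator couples two subsystems over discrete two-week cycles
(26 per simulated year by default):

1. **Disease and care-seeking.** Per cycle and per disease class *d*, the case
   count is Binomial(*N*, *q_d*) with *N* the (static) population size and
   *q_d* the two-week prevalence. Each case receives independent categorical
   draws for gender, age band, occupation, marital status, education and
   income band (marginals only — no joint distribution is modelled), an
   insurance scheme by population share, and a district by population share
   with a uniform location in the district's bounding rectangle. Preference
   over the four institution types is a deterministic lookup on
   (severity class, age band, income band), with two hard gates: severe cases
   have zero community-centre weight, and the specialized-hospital weight is
   active only for diseases flagged specialized-eligible. The community
   first-visit promotion multiplies the community weight by the promotion
   degree (baseline 1.0) for minor/common cases only. The type is drawn
   categorically from the renormalized weights and the patient attends the
   nearest institution of that type (haversine distance on a 6371-km sphere;
   ties broken by lowest institution id).
2. **Expense generation.** A doctor is drawn uniformly from the attended
   institution's pool. The doctor over-prescribes with probability
   `p_regime · (1 − R)`, where the regime is selected by comparing the
   workload-implied expected income `E(h) = −12685.5 + 678.13·h` with actual
   income (10% in one regime, 50% in the other) and `R` is the institution's
   public-welfare responsibility index. Care events are independent Bernoulli
   draws for outpatient visit, hospitalization, and physical examination, with
   surgery conditional on hospitalization; a patient who draws neither
   outpatient nor inpatient care falls back to an outpatient visit (a
   generated patient seeks care by construction). Episode expenses are the
   disease's schedule components for the institution's type — outpatient
   components for outpatient care; inpatient components plus
   treatment/material (and surgery if drawn) for admissions; exam components
   only when the examination event fires — each compounded as
   `base·(1+g)^year`. If the doctor over-prescribed, an extra of
   `degree · (medicine + exam components) · adherence` is allocated pro-rata
   across the episode's medicine/exam components, where the degree is uniform
   on the configured range (default 0.1–0.5) and adherence is the insurance
   reimbursement proportion `1 − copay(level)`. Adherence scales only the
   over-prescribed extra, not the base prescription: the base schedule
   represents clinically indicated care, and the adherence mechanism models
   patients declining marginal prescriptions.

Between years, doctor incomes and weekly hours grow by their configured
rates (hours capped at 60), and subsidy proportions grow by per-type rates;
the responsibility index is recomputed at each year start as

```
R = clamp((subsidy/baseline − r0) / (rmax − r0), 0, 1)
```

with `rmax` = 1.75 for community centres (subsidies at 175% of baseline give
perfect commitment) and a higher default (3.0) for the hospital types, whose
saturation point is empirically not reached; `r0` defaults to 0, making the
index proportional up to saturation. Insurance affects the model only
through reimbursement proportions, and the population is static: no
transmission, mobility, births or deaths.

## Randomness and common random numbers

All stochasticity flows from one root seed through a `SeedSequence` tree
keyed on (module, year, cycle): separate streams for doctor-pool creation,
patient generation, type choice, event/degree draws, and over-prescription
decisions. Every episode consumes a *fixed* number of draws from each stream
regardless of outcomes (e.g. the surgery uniform is drawn even when the
patient is not hospitalized, and the over-prescription degree is drawn even
when the decision is negative). Consequence: two scenario runs at the same
seed are coupled draw-for-draw, so scenario contrasts are exact pathwise
comparisons — raising the promotion degree can only move individual patients
toward community care, and lowering the over-prescription probability can
only switch individual decisions off. The direction-of-effect and dominance
tests rely on this coupling, which makes them sharp at small population
sizes.

## The income-expectation comparison

The over-prescription rule is two-sided: one regime probability (default
0.10) when `E(h) ≥ actual income` and the other (default 0.50) otherwise.
That literal orientation is the package default (`condition_swapped=False`).
It is, however, economically inverted: under it, *raising* doctor incomes
pushes doctors into the 50% regime and *increases* over-prescription, the
opposite of the intervention logic the scenarios encode (income raises and
workload cuts are supposed to weaken over-prescription incentives, which is
the documented behaviour of supplier-induced demand). The rule therefore
carries a `condition_swapped` flag; with it set, unmet income expectations
(`E(h) ≥ actual`) select the 50% regime. All direction-of-effect analyses,
the scenario-comparison example and the acceptance computation use the
swapped orientation; unit tests cover both. This is a deliberate dual
surface: the default preserves the stated rule verbatim, the flag provides
the orientation under which the intervention results are reproducible.

## Synthetic parameter generator

The calibrated input table for the real system (Shanghai) is not publicly
available. `generate_fixture(seed, population_size)` emulates its structure:

- **Diseases (30):** 10 minor / 12 common / 8 severe named profiles.
  Two-week prevalences are uniform in severity-specific bands
  (minor 0.005–0.05, common 0.001–0.02, severe 0.0005–0.005), spanning the
  order of magnitude of national two-week morbidity statistics. Care-event
  probabilities follow severity (e.g. severe: hospitalization 0.5–0.9,
  surgery 0.3–0.7 given admission).
- **Expense schedules:** community-level components drawn in CNY bands of
  yearbook magnitude (e.g. outpatient medicine 30–90, inpatient medicine
  600–2500, scaled 0.7×/1×/1.8× by severity), then tier multipliers
  district = community × U(1.5, 2.0), specialized = district × U(1.3, 1.6),
  tertiary = specialized × U(1.05, 1.3) — the ordering
  tertiary > district > community holds componentwise by construction, which
  is what gives the patient-diversion scenarios their expense-reducing sign.
  Annual growth rates are U(0.03, 0.08), bracketing the observed 4–8% range.
- **Geography:** 16 districts as a 4×4 rectangle grid over the municipal
  lat/lon extent, shares Dirichlet-distributed; 16 community centres (one per
  district), 10 district hospitals, 8 tertiary comprehensive and
  4 specialized hospitals (the latter two clustered centrally).
- **Insurance:** urban-worker 50%, urban–rural-resident 40%, uninsured 10%;
  copays 0.30/0.40/0.50 (worker) and 0.30/0.45/0.55 (resident) across
  primary/secondary/tertiary; the uninsured pay in full at every level (their
  copay is unstated in the source system; full out-of-pocket is the natural
  reading and makes their adherence to over-prescribed extras zero).
- **Doctors:** four titles with weekly hours 40–52 and incomes
  15–30 kCNY placed deliberately *on the scale of the expected-income line*
  (≈14.4 kCNY at 40 h to ≈28.0 kCNY at 60 h) so that both regimes of the
  comparison are populated and income/workload interventions can flip
  doctors across the boundary. These are stand-in values: with realistic
  annual clinician salaries the comparison would be vacuously one-sided and
  the doctor-side scenarios inert, because the source regression's units and
  period are unstated. Incomes get ±10% jitter per doctor.
- **Preferences:** severity-specific base weights with small deterministic
  age/income modifiers, tuned so that district + tertiary comprehensive
  hospitals jointly receive the majority of first choices (the observed
  pattern), community centres a substantial minority, specialized hospitals
  a few percent.

Identical seeds give field-for-field (and byte-for-byte on disk) identical
configurations. What passing tests on this fixture *do* show: the arithmetic,
the mechanisms, invariances (conservation, determinism, monotonicity) and the
signs and ordering of intervention effects. What they *cannot* show: absolute
CNY levels, calibrated ratios, or quantitative effect sizes for the real
system — those require the unavailable calibrated inputs.

## Scenarios

Scenario transforms are pure functions applied to the baseline configuration
once (not compounded year-over-year): promotion degree ×0.5 / ×1.5 / ×2.0
(patient tests 1–3, with "rationalized preferences" in tests 2–3 implemented
as zero tertiary-comprehensive weight for minor cases on top of the always-on
severe gating — the source gives no formal definition, so rationalization is
operationalized as the minimal severity-consistent steering rule); doctor
income ×0.5/×2/×3 with matching growth and hours changes (test 1 sets all
weekly hours to the 60-h cap); subsidy growth ×0.5, ×2 (×1.75 community), ×3
(×2 community) for government tests 1–3; and the combined scenario stacking
patient test 2 + doctor test 2 + government test 2 (the marginal-value
intensities). Scenario growth-rate changes take effect from the first
simulated year; since year 1 uses baseline subsidy proportions, government
scenarios differentiate from year 2 onward.

## Validation and analytics

`validate` computes per-metric percent differences
`100·(simulated − actual)/actual` rounded to 0.1, passing when all lie within
±10 (the credibility band of the validation protocol). `growth_rate` is the
adjacent-year percent change to 0.1. `hospexp.reference` stores the published
yearbook/validation/baseline tables as *inputs* to these functions; three
printed cells there are internally inconsistent (the 2013/2014 outpatient
growth figures, which appear transposed, and the year-1 inpatient medicine
ratio/difference pair) — the module docstring flags them, and tests assert
the recomputed values.

## Numerical choices and problem sizes

- Expenses are reported to 0.1 CNY and ratios/shares to 0.1 percentage point
  (the reporting precision of the mirrored tables); internal arithmetic is
  full float64.
- Per-capita outpatient/inpatient denominators are event-specific (visits vs
  admissions), following the yearbook convention.
- Categorical draws use inverse-CDF on a fixed type order with the community
  interval last (this is what makes promotion monotonicity exact under
  common random numbers).
- Nearest-facility ties break to the lowest institution id; equidistance is
  exact only in symmetric constructions but the rule is deterministic.
- Aggregation with zero admissions in a year reports zero inpatient
  per-capita values and ratios rather than NaN.
- Default test/demo problem sizes (population 1000–5000, 5–8 cycles/year,
  3 years, ≈5–50 k episodes per run) were chosen so that every Monte-Carlo
  assertion has ≥3-standard-error headroom while the whole suite and the
  acceptance script run comfortably on a single CPU; the acceptance rate
  estimate uses 20,000 decisions (binomial SE ≈ 0.35 points).

## Known limitations

- One disease per patient per episode; no comorbidity, recurrence linkage,
  queueing, or capacity constraints.
- Doctor pools are representative per institution (uniform draw per episode);
  there is no within-institution doctor–patient matching.
- Insurance-fund accounting, price regulation and case-mix adjustment are out
  of scope; insurance acts only through reimbursement proportions.
- The expected-income regression's units/period are unstated in its source;
  only the sign of the comparison is used, and the fixture income scale is
  chosen to make that comparison informative.
- Subsidy proportions evolve by their own growth rates independent of
  institutional revenue dynamics, so declining-proportion trajectories
  (subsidies growing slower than revenue) are not representable without a
  negative growth rate.
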