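# hospexp

A multi-agent simulator of how medical expenses are generated in a tiered
public-hospital system, built for health-policy analysis of the
*unreasonable growth* of expenses in Chinese urban public hospitals
(Shanghai-style system: community health service centres, district hospitals,
and tertiary comprehensive/specialized hospitals).

The package is aimed at health-services researchers and policy modellers who
want a scriptable, fully reproducible counterpart to GUI agent-based models:
every mechanism is an importable, unit-tested function, and every run is
determined by a configuration object plus a seed.

## The model

Five agent classes interact over two-week cycles within a simulated year:

- **Patients** are generated per cycle from two-week prevalences of 30
  disease classes, with demographics, an insurance scheme, and a home
  location drawn from district population shares. Each patient gets a
  preference over institution types from a lookup on
  (severity, age band, income band) — severe cases never choose primary care —
  then government promotion of the *community first-visit system* scales the
  community weight by the promotion degree *g* for minor/common cases. After a
  categorical draw of the type, the patient attends the nearest facility of
  that type (great-circle distance, 6371-km sphere).
- **Doctors** compare the income their workload should command,
  *E(h) = −12685.5 + 678.13 h* (CNY at *h* weekly hours), with their actual
  income. The comparison selects one of two over-prescription regimes
  (10% vs 50% of doctors over-prescribe); the realized probability is damped
  by the institution's public-welfare responsibility index *R*:
  *p = p_regime · (1 − R)*.
- **Institutions** carry a government subsidy proportion; the responsibility
  index is piecewise linear in the subsidy ratio relative to baseline and
  saturates at a per-type ratio (1.75 for community centres: subsidies at
  175% of baseline mean responsibilities are undertaken perfectly).
- **Insurance** enters through level-dependent copays (30% out of pocket at
  primary care, 50% at tertiary by default); the reimbursement proportion
  *1 − copay* doubles as prescription **adherence**, scaling the
  over-prescribed extra a patient actually accepts.
- **Expenses** per episode are the disease's base schedule for the chosen
  institution type (nine components), compounded by per-component annual
  growth rates; over-prescription adds
  *degree · (medicine + exam components) · adherence*.

Annual summaries mirror the statistical-yearbook shape: per-capita outpatient
(per visit) and inpatient (per admission) expenses, medicine/exam ratios,
subsidy proportions, patient shares per institution type, and the
over-prescription rate. A validation helper applies the ±10%
simulated-vs-observed credibility rule, and ten policy scenarios (three
patient-side, three doctor-side, three government-side, one combined) are
pure transforms of a baseline configuration.

The true calibrated parameter table for Shanghai is not publicly available,
so `generate_fixture(seed, population_size)` produces a complete synthetic
stand-in configuration with the documented structural guarantees
(fee schedules ordered tertiary > district > community, the copay schedule
above, 16 districts, 30 diseases). Absolute CNY outputs are therefore not
comparable to the published calibrated run; arithmetic identities, validation
logic and direction-of-effect results are.

## Worked example

```python
from hospexp import generate_fixture, run, summaries_to_frame

cfg = generate_fixture(seed=1, population_size=5000)
print(summaries_to_frame(run(cfg, "baseline", seed=1)).to_string())
```

prints (abridged):

```
                                                     year_1   year_2   year_3
Outpatient total medical expenses (CNY)               176.1    186.4    196.7
Outpatient medicine expenses (CNY)                    109.6    115.9    122.2
Ratio of outpatient medicine to total medical ...      62.2     62.2     62.1
Inpatient total medical expenses (CNY)              17711.5  18399.7  20058.6
Patient share: tertiary comprehensive hospital (%)     31.0     31.4     30.9
Patient share: district hospital (%)                   39.1     38.9     38.9
Probability of over-prescription (%)                   15.5     15.9     16.9
```

Per-capita expenses compound with the schedules' growth rates; district and
tertiary comprehensive hospitals together absorb ~70% of first choices; and
the over-prescription rate is the damped mixture of the 10%/50% regimes.
The scripts in `examples/` walk through configuration generation, the
baseline run, scenario comparisons, and validation/growth analytics, each
printing and explaining its numbers.

A thin CLI wraps the same library calls:

```bash
hospexp fixture --seed 1 --population 10000 --out cfg.yaml
hospexp simulate --config cfg.yaml --scenario doctor_test2 --seed 1 --out scen.csv
hospexp validate --summary base.csv --actual actual.csv
hospexp compare base.csv scen.csv
```

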