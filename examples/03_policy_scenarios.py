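"""Compare policy-intervention scenarios against the baseline.

Three intervention families are simulated at a shared seed (common random
numbers): the patient-side community first-visit promotion, the doctor-side
income/workload adjustment, the government-side subsidy growth increase, and
their combination.  The comparison metric is the total expense generated over
the three-year horizon.

The doctor-side intervention only bites when unmet income expectations drive
over-prescription, so this example uses the economically standard orientation
of the income-expectation comparison (condition_swapped=True).
"""

from hospexp import generate_fixture, run

cfg = generate_fixture(seed=1, population_size=2000, cycles_per_year=8)
cfg = cfg.model_copy(deep=True)
cfg.overrx_rule.condition_swapped = True


def total_expense(summaries):
    return sum(s.outpatient_total * s.n_outpatient + s.inpatient_total * s.n_inpatient
               for s in summaries)


base = total_expense(run(cfg, "baseline", seed=1))
print(f"baseline 3-year total expense: {base / 1e6:.2f} MCNY\n")
print(f"{'scenario':18s} {'total (MCNY)':>12s} {'reduction':>10s}")
for name in ("patient_test2", "doctor_test2", "government_test2", "combined"):
    total = total_expense(run(cfg, name, seed=1))
    print(f"{name:18s} {total / 1e6:12.3f} {100 * (base - total) / base:9.2f}%")

print("\nEach single-agent intervention lowers total expenses, and the combined")
print("intervention (all three at their marginal-value intensities) cuts at")
print("least as much as the best single one — interventions on demanders,")
print("suppliers and the government reinforce each other.  The government")
print("lever is the weakest here: it acts only by damping the over-prescribed")
print("extras, and under these synthetic parameters its subsidy-growth change")
print("moves the responsibility index by a few points at most.")
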