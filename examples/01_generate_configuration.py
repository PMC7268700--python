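"""Generate a synthetic parameter configuration and inspect its structure.

The configuration plays the role of the model's flat input table: 30 disease
profiles, 16 districts, an institution roster over the four public types,
insurance copay schedules, subsidy policy and doctor parameters.  All numbers
are seeded synthetic stand-ins; the structure (tier ordering, copays, severity
classes) is guaranteed by construction.
"""

from collections import Counter

from hospexp import generate_fixture

cfg = generate_fixture(seed=1, population_size=10_000)

print(f"diseases: {len(cfg.diseases)}  districts: {len(cfg.districts)}  "
      f"institutions: {len(cfg.institutions)}")
print("severity mix:", dict(Counter(d.severity_class for d in cfg.diseases)))
print("institution types:", dict(Counter(i.type for i in cfg.institutions)))

d = cfg.diseases[0]
print(f"\nexample disease: {d.name!r} (severity {d.severity_class})")
print(f"  two-week prevalence      {d.two_week_prevalence:.4f}")
print(f"  P(outpatient visit)      {d.p_outpatient:.2f}")
print(f"  P(hospitalization)       {d.p_hospitalization:.2f}")
print("  outpatient medicine base expense by tier (CNY):")
for itype in ("community_center", "district_hospital", "tertiary_comprehensive"):
    print(f"    {itype:24s} {d.base_expenses[itype].components['outpatient_medicine']:8.1f}")

worker = next(s for s in cfg.insurance if s.name == "urban_worker")
print("\nurban-worker copay by level:", worker.copay_by_level)
print("-> patients pay 30% out of pocket at primary care but 50% at tertiary")
print("   hospitals; the complement is the reimbursement proportion, which the")
print("   model uses as prescription adherence.")
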