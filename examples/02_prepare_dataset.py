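"""From raw cohort to analysis dataset: eGFR, exclusions, derived factors.

Mirrors a baseline-eligibility workflow: compute MDRD eGFR from serum
creatinine, drop prevalent kidney disease, derive MET-min/week volumes
and the lifestyle binaries, and attach the composite CKD outcome from an
event-record table.
"""

import lifescore as ls

# The MDRD equation itself
egfr = ls.egfr_mdrd(creatinine_umol_l=88.4, age_years=50, sex="male")
print(f"eGFR at Scr 88.4 umol/L (1.0 mg/dL), age 50, male: {egfr:.1f} ml/min/1.73m^2")
print(f"same but female: {ls.egfr_mdrd(88.4, 50, 'female'):.1f}  (x0.742 exactly)")

# MET-min/week from activity raw fields (IPAQ weights 3.3 / 4.0 / 8.0)
met = ls.met_minutes(walking_min_per_day=60, walking_days_per_week=7)
print(f"walking 60 min/day x 7 d/wk = {met['walking']:.0f} MET-min/week")

# Full prep chain on a simulated raw cohort
codebook = ls.default_codebook()
cohort = ls.generate_cohort(ls.SimulationConfig(n_participants=20_000, seed=2), codebook)

retained, log = ls.apply_exclusions(cohort, ls.OutcomeDefinition(), codebook)
print("\nexclusion log (first-matching-rule attribution):")
for rule, count in log.items():
    print(f"  {rule:22s} {count}")

analysis = ls.derive_factors(retained, codebook)
print("\nderived factor prevalences:")
for name in ["current_smoking", "current_alcohol", "adequate_sleep", "psychological_health"]:
    print(f"  {name:22s} {analysis[name].astype('Float64').mean():.3f}")

# Outcome definition from a long event-record table (round-trips the
# simulator's own event labels)
records = ls.event_records(cohort, seed=2)
print(f"\n{len(records)} event records; kinds: {records['kind'].value_counts().to_dict()}")
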