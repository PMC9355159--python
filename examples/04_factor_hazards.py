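"""Per-factor direction of effect: Cox HRs, Fine-Gray sensitivity, and
cumulative hazard curves.

One age/sex-adjusted Cox model per factor gives the hazard ratio whose
95% CI signs the factor (healthy if CI < 1, unhealthy if CI > 1,
indeterminate otherwise). The Fine-Gray subdistribution fit treats death
as a competing risk.
"""

import warnings

import lifescore as ls
from lifescore.hazards import estimates_frame

warnings.filterwarnings("ignore")

codebook = ls.default_codebook()
cohort = ls.generate_cohort(ls.SimulationConfig(n_participants=30_000, seed=4), codebook)
retained, _ = ls.apply_exclusions(cohort, ls.OutcomeDefinition(), codebook)
analysis = ls.derive_factors(retained, codebook)

for factor in ["wholegrain_bread", "white_bread", "current_smoking", "processed_meat"]:
    for est in ls.fit_factor_cox(analysis, factor, codebook):
        print(f"{factor:18s} [{est.exposure_level:10s}] "
              f"HR {est.hr:5.2f} ({est.ci_low:.2f}-{est.ci_high:.2f}) -> {est.direction}")

# Fine-Gray sensitivity analysis: subdistribution HR with death competing
fg = ls.fit_finegray(analysis, "white_bread", codebook)[0]
print(f"\nwhite_bread subdistribution HR (death competing): "
      f"{fg.hr:.2f} ({fg.ci_low:.2f}-{fg.ci_high:.2f})")

# Nelson-Aalen cumulative hazard by smoking status
analysis["smoker"] = analysis["current_smoking"].map({1: "current", 0: "non-current"})
curves = ls.cumulative_hazard(analysis.dropna(subset=["smoker"]), "smoker")
for grp, curve in curves.items():
    print(f"cumulative hazard at end of follow-up, {grp:12s}: "
          f"{curve['cumulative_hazard'].iloc[-1]:.4f} "
          f"(se {curve['se'].iloc[-1]:.4f})")
print("(a higher curve for current smokers reflects the planted HR of 1.28)")
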