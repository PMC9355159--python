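# lifescore

Machine-learning-plus-Cox lifestyle scorecards for incident chronic kidney
disease (CKD), with a synthetic UK-Biobank-like cohort simulator that makes
the whole derivation pipeline testable end to end.

## The problem

Which everyday lifestyle behaviours — bread choice, walking, tea, sleep,
smoking — matter most for preserving kidney function, and how can they be
combined into a single interpretable score? `lifescore` implements a
two-stage derivation used for large prospective cohorts:

1. **Importance.** A gradient-boosted tree classifier (LightGBM) is trained
   on the 37 lifestyle factor columns against incident-CKD status; each
   factor's total split gain — its mean decrease impurity, MDI — ranks the
   factors.
2. **Direction.** One age- and sex-adjusted Cox proportional-hazards model
   per factor estimates the hazard ratio of the exposed state. A factor is
   *healthy* when the 95% CI of its HR lies entirely below 1, *unhealthy*
   when entirely above 1, and unscored otherwise. A Fine–Gray
   subdistribution fit with death as the competing risk is available as a
   sensitivity analysis.
3. **Scorecard.** Each scored factor receives the integer number of points
   `round(MDI / 1000)`; a participant's total is

   `total = Σ points(healthy factors satisfied) − Σ points(unhealthy factors satisfied)`

   with graded categories total `< 0, 0–20, 20–40, 40–60, ≥ 60` → grades
   0–4.
4. **Validation.** Restricted-cubic-spline Cox regression tests the shape of
   the score–risk relation (likelihood-ratio test of the nonlinear spline
   terms), Cox models per grade report the percent lower risk versus grade
   0, and discrimination is summarised by the ROC AUC at the administrative
   horizon plus Harrell's C-statistic of the age-adjusted score.

Because the cohorts such scores are derived from are access-restricted, the
package ships a first-class simulator: 37 factors with UK-Biobank-style
codings, planted per-factor log hazards, a Weibull proportional-hazards CKD
process calibrated to ~2.9% cumulative incidence over a median 11-year
follow-up, competing death, and MDRD-eGFR/exclusion machinery
(eGFR = 175·Scr^−1.154·age^−0.203·0.742^[female]·1.212^[Black]). Every
statistical claim in the test suite is checked against planted truth or an
independent oracle.

## Worked example

```python
import lifescore as ls

codebook = ls.default_codebook()                      # the 37 factors
cohort   = ls.generate_cohort(ls.SimulationConfig(n_participants=30_000, seed=5), codebook)
retained, log = ls.apply_exclusions(cohort, ls.OutcomeDefinition(), codebook)
analysis = ls.derive_factors(retained, codebook)

importance = ls.fit_importance(analysis, codebook, seed=5)   # MDI ranking
estimates  = ls.fit_all_factors(analysis, codebook)          # Cox HRs
card       = ls.build_scorecard(importance, estimates, codebook)
scores     = ls.score_cohort(analysis, card)
report     = ls.validation_report(scores, analysis, outcomes=("ckd",), seed=5)
```

Running `python examples/05_build_and_validate_scorecard.py` (which is
exactly this) prints the scorecard —

```
Healthy factors
-------------------------------------------------------
   +51  usual_walking_pace in {brisk}
    +6  dried_fruit >= 1
    +4  light_diy == 1
    ...
Unhealthy factors
-------------------------------------------------------
    -4  processed_meat in {2_4_wk, 5_6_wk, daily_plus}
    -3  beef in {2_4_wk, 5_6_wk, daily_plus}
    -2  white_bread >= 2
```

— and its validation:

```
RCS linearity p (H0: linear dose-response): 1.000
linear slope (log-HR per point): -0.0189
grade 1: HR 0.40 (0.33-0.50) -> 60% lower risk   [n=15944]
grade 3: HR 0.16 (0.12-0.21) -> 84% lower risk   [n=6431]
grade 4: HR 0.07 (0.04-0.10) -> 93% lower risk   [n=4718]
age-adjusted score: C = 0.719 (0.671-0.768), AUC at 11.9 y = 0.722
```

Read: each point value is MDI/1,000 for that factor, signed by its Cox
direction; the per-factor HRs on this synthetic cohort recover the planted
effects (brisk walking pace was planted protective, processed meat
harmful); higher totals carry monotonically lower CKD hazard; and the
age-adjusted score discriminates future cases at C ≈ 0.72. Exact numbers
vary with the seed and cohort size.

The other scripts in `examples/` each demonstrate one capability:
simulation and incidence calibration, eGFR/exclusion/MET preparation,
importance ranking on a planted-truth cohort, and per-factor hazards with
the Fine–Gray sensitivity analysis.

A thin CLI wraps the same pipeline for shell use:

```bash
lifescore run --n 20000 --seed 7 --out run_dir     # full chain
lifescore score --importance imp.csv --hazards hz.csv --out card.csv
```

## Layout

```
src/lifescore/
  codebook.py    # FactorSpec / FactorCodebook, the 37 default factors
  simulate.py    # SimulationConfig, cohort generator, incidence calibration, I/O
  prep.py        # MDRD eGFR, exclusions, MET-min/week, derived codings, outcomes
  importance.py  # LightGBM MDI ranking
  hazards.py     # per-factor Cox, Fine-Gray, Nelson-Aalen, direction rule
  scorecard.py   # MDI/1,000 scorecard, participant scoring, grades
  validate.py    # RCS dose-response, grade HRs, AUC / Harrell's C
  pipeline.py    # end-to-end orchestration with manifest
  cli.py         # `lifescore` subcommands
docs/methods.md  # model, assumptions, parameter choices, limitations
```
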