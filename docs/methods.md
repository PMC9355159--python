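# Methods

This note records the models behind `lifescore`, the assumptions they
make, the defaults and why they were chosen, and what the synthetic-data
experiments can and cannot show.

## The scoring model

The scorecard is derived in two independent stages and combined by a
fixed rule.

**Importance stage.** A LightGBM binary classifier is trained on the 37
model-ready lifestyle columns against incident-CKD status (demographics
excluded by design — the score should rank behaviours, not age). The
importance of factor *j* is its mean decrease impurity (MDI): the total
split gain attributed to *j* across all trees. Ranks are assigned by
non-increasing MDI with lexicographic tie-break, so the table is
deterministic given the seed.

Booster defaults (all overridable): 500 trees, learning rate 0.05,
**depth-1 trees** (`num_leaves=2`), minimum 50 samples per leaf,
`is_unbalance` class weighting, single-threaded deterministic mode. The
depth-1 choice is deliberate and load-bearing. The eventual score is
additive in the factors, and a depth-1 ensemble is exactly the matching
additive model. With deeper trees, split gain systematically accrues to
the factors with the most distinct values (the three MET volumes, stair
climbing): each extra split candidate is another chance to fit noise,
a multiple-comparisons effect that at realistic effect sizes (|HR|
1.2–1.5, ~3% events) can rank a zero-effect high-cardinality factor
above a genuinely associated coarse one. Restricting to depth 1 removes
the interaction channel for that bias; it is this package's reading of
"conditioning" the importance measure against scale and collinearity
artefacts. Class imbalance is handled by weighting rather than
resampling because resampling would change the gain scale that feeds the
scorecard. An optional permutation-importance cross-check
(`importance.permutation_check`) flags rank instability.

The MDI scale is raw split gain; the divisor that turns it into points
(default 1,000) is configurable because gain magnitude grows with cohort
size and event count — the *ranking*, not the scale, is the
transportable object.

**Direction stage.** One Cox proportional-hazards model per factor,
adjusted for age and sex only (not mutually adjusted across factors),
estimates the hazard ratio of the exposed state: exposure indicator for
count factors (codebook thresholds, e.g. walking MET > 2,000 min/week,
tea > 4 cups/day), level indicators against the first level for
polytomous factors, the 0/1 value for binaries. Fits use the partial
likelihood with Efron tie handling (lifelines). The direction rule is

- healthy iff the 95% Wald CI of the HR lies entirely below 1,
- unhealthy iff entirely above 1,
- indeterminate otherwise — such factors are listed as unscored rather
  than silently dropped (a `keep_indeterminate` option signs them by the
  point estimate instead).

For polytomous factors the direction is taken from the highest declared
exposure level versus reference. Monotone likelihood (separation on a
sparse level) produces a flagged, indeterminate estimate. A mutually
adjusted mode exists for sensitivity analysis but never feeds the
scorecard.

**Combination.** Points are `round(MDI / 1000)` with round-half-to-even
(printed scores are integers; the exact rounding rule is a convention and
is documented as such). Zero-point factors stay on the card flagged
non-contributing. Totals map to grades by left-closed intervals:
(−∞,0) → 0, [0,20) → 1, [20,40) → 2, [40,60) → 3, [60,∞) → 4. The
published interval labels overlap at their endpoints, so a boundary
dialect has to be chosen; left-closed is the default (an exact total of 0
is grade 1, matching the "0–20" label), and a right-closed option is
exposed. The interval list as sometimes printed leaves exactly 60
unassigned; here 60 belongs to grade 4.

## Competing risks

The Fine–Gray subdistribution-hazard model (death competing with CKD) is
implemented directly as an IPCW-weighted Breslow partial likelihood: a
participant who dies at time *s* remains in risk sets at *t* > *s* with
weight G(t−)/G(s−), where G is the Kaplan–Meier estimate of the censoring
distribution; the weighted likelihood is maximised with BFGS using the
analytic gradient, and the covariance is the inverse weighted information.
No installed Python survival package provides this estimator, hence the
in-house implementation; the tests cross-check it against R's
`cmprsk::crr` on a small cohort (coefficients agree to ~5e-3, the residual
being left-limit conventions in G) and verify the exact reduction to the
cause-specific Cox fit when no competing events exist. It is a
sensitivity analysis only; the scorecard uses cause-specific Cox
directions.

## Validation machinery

**Restricted cubic splines.** The Harrell truncated-power basis: k knots
at conventional quantiles (5/35/65/95% for the default k=4; k
configurable 3–5) give k−2 nonlinear terms, each linear beyond the
boundary knots and C² everywhere, normalised by (t_k−t_1)². The
linearity test is the likelihood-ratio statistic of the nonlinear terms
(χ², k−2 df) against the plain linear Cox fit.

**Graded risk.** Cox regression on grade indicators versus grade 0,
reported as hazard ratios and as 100·(1−HR) percent lower risk.

**Discrimination.** Two conventions are computed, because both are in
common use: (a) ROC AUC of the risk score against case status at a fixed
administrative horizon (default: 95th percentile of follow-up), with
participants censored before the horizon excluded and a seeded bootstrap
CI; (b) Harrell's C over all usable pairs under censoring (earlier time
must be an event; prediction ties count ½), with a closed-form
U-statistic variance from per-subject concordance residuals
(Var ≈ 4·Σφᵢ²/D², φᵢ = cᵢ − C·dᵢ). The exact O(n²) computation is used up
to 4,000 rows; above that C comes from the O(n log n) routine and the
variance from a seeded subsample. "Age-adjusted score" means the linear
predictor of a Cox fit on score + age; when no adjustment covariate is
requested the raw score itself is the risk prediction — re-estimating its
sign in-sample would bias null discrimination away from 0.5.

## The synthetic cohort

The simulator emulates the study conditions of a UK-Biobank-scale
derivation: male fraction 53.91%; age drawn from a normal with SD 8 years
truncated to the 40–69 recruitment window, with the location solved so the
*truncated* mean is exactly 57 (the truncated SD is necessarily below 8);
ethnicity ~94.5% White with Black ≈ 1.6%; serum creatinine lognormal with
sex-specific medians (80/65 µmol/L) giving a baseline eGFR distribution
around 85 and ~1% of participants excluded at eGFR ≤ 60.

Event model: the CKD cause has Weibull cumulative baseline hazard
H₀(t) = (t/σ)^k with shape k = 1.5 (risk accelerating with age/time) and
scale σ pre-calibrated by bisection so cumulative incidence is ≈ 2.9%
(13,555/470,778) at the 11-year administrative horizon; σ defaults to
46.5 under the default codebook. Event times are drawn by inverse
transform conditional on the linear predictor
lp = Σⱼ βⱼ·exposedⱼ + 0.07·(age−57) − 0.12·male, so the proportional-
hazards assumption the Cox stage relies on holds exactly. Death is an
independent exponential competing cause (0.004/yr; a `death_loghr_scale`
knob can couple it to lifestyle), CVD a parallel secondary process coupled
at half the lifestyle effect. Follow-up ends at the event, death, or an
administrative boundary of 11 ± 1 years (uniform staggered entry), giving
a median observed follow-up of ~11 years. Note that with a time-scale
Weibull parameterisation, *increasing* σ delays events and lowers
incidence; the calibrator's bisection accounts for this direction.

Default per-factor effects are the hazard-ratio magnitudes the scoring
system is designed around (whole-grain bread 0.77, white bread 1.36,
processed meat 1.40, brisk pace 0.33, current smoking 1.28, adequate
sleep 0.81, alcohol 0.66, …). Marginal distributions of the diet and
activity variables are plausible frequencies chosen once; they are free
parameters of the simulator, not calibrated claims. The exact 37-item
list is itself a reconstruction: 12 diet counts, 11 polytomous diet
items, 10 activity variables, and 4 derived binaries (current smoking,
current alcohol, adequate sleep = 7–9 h/day, psychological health = no
illness/injury/bereavement/stress in 2 years). Seven factors are
*derived*: the simulator emits raw fields (minutes/day × days/week,
status categories, sleep hours, adversity flags) and the prep stage
computes the model-ready columns (MET weights 3.3/4.0/8.0), so the
derivation code is exercised, and the planted truth is computed through
the same derivation.

**Recovery experiment design.** The rank/sign recovery experiments use a
dedicated codebook (`recovery_codebook`): four target factors with
hazard-ratio magnitudes 1.50/1.43/1.38/1.32 ordered
bread > walking > moderate PA > vigorous PA, all other factors exactly
null. The design is powered: set recovery at ~1,400 events requires each
target's Wald z to clear the expected maximum (~3) of 33 null
association statistics, i.e. z = |log HR|·√(D·p(1−p)) ≳ 5, which holds
when each exposure prevalence p is near 0.4 — hence the three MET
exposure thresholds sit near their exposure medians in this codebook
(700/400/300 MET-min/week) rather than at the default clinical strata.
At the default walking threshold (2,000 MET-min/week, ~11% exposed) a
planted HR of 1.4 yields z ≈ 3 and is statistically indistinguishable
from the null maximum, so no importance measure could recover it — an
identifiability floor of the experiment, not an estimator property.

Factors are independent by default; a Gaussian copula
(`copula_rho`) with exchangeable latent correlation is available to probe
importance behaviour under collinearity. Missingness is MCAR at 2% per
lifestyle field, plus a 0.1% sliver of near-empty lifestyle records to
exercise the <5%-data exclusion rule. A small fraction of participants
carries prevalent-CKD codes or prior renal replacement therapy for the
baseline filters.

What the simulator does **not** emulate: realistic joint dietary
patterns, assessment-centre or geographic effects, time-varying
behaviour, informative censoring, measurement error in creatinine or
questionnaires, and the real (unpublished) per-factor prevalences. A
passing recovery test therefore shows the *pipeline* is sound — ranking,
signing, scoring and validation recover planted truth under the model's
own assumptions — not that the specific published point values would be
reproduced on the real cohort.

## Preparation rules

- MDRD eGFR, IDMS-traceable 175 variant, creatinine µmol/L ÷ 88.4 →
  mg/dL. Both the baseline exclusion and the incident event use
  eGFR ≤ 60 ml/min/1.73 m² (an `inclusive_threshold=False` switch gives
  the strict-< dialect, since both wordings circulate).
- Exclusion order, with first-matching-rule attribution: baseline eGFR,
  prevalent renal-failure codes (ICD-10 N18 / ICD-9 5859 / self-report
  1192), prior renal replacement therapy, then <5% lifestyle data; counts
  partition the input exactly.
- Composite CKD event: first of qualifying follow-up eGFR, renal-failure
  diagnosis (hospitalisation, death record, or self-report), or RRT code
  (Z99.2, Z94.0, Z49). Follow-up never reaches zero or below; records at
  or before baseline are data errors.
- Missing lifestyle values are kept as explicit missing for the tree
  learner (which routes them natively), dropped factor-wise for the
  per-factor Cox fits, and contribute zero points when scoring — each
  choice preserves the maximal usable n for its stage.
- Tea exposure is scored at >4 cups/day (the scored system's threshold)
  even though a >5 cups/day stratum also appears in this literature; the
  codebook makes the threshold editable.

## Experiment sizes and numerical choices

Simulation-based checks use sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes: null CI coverage uses 200 replicates
of n = 3,000 (~300 events each); rank recovery uses 20 seeds of
n = 50,000 at the calibrated ~2.9% incidence (recovery baseline scale
102.7, with only the four target factors non-null); sign recovery uses
n = 50,000 under the full 37-factor codebook; the spline power check uses
n = 20,000 for the quadratic alternative and 100 null replicates of
n = 2,000; null-AUC checks average ten replicates of n = 10,000 because a
single ~450-case replicate has an AUC standard error of ~0.014.
Optimisation tolerances: Fine–Gray BFGS gradient tolerance 1e-8; Cox fits
use lifelines defaults; incidence calibration stops within 10% relative
of target. Determinism: every stochastic routine takes an explicit seed,
LightGBM runs single-threaded in deterministic mode, and a pipeline rerun
with the same config hash produces byte-identical artifacts.

## Known limitations

- MDI from a depth-1 ensemble understates factors whose effect is purely
  interactive; that is the accepted cost of the bias correction above.
- The Fine–Gray variance is model-based (inverse information), not the
  robust sandwich form; its CIs are mildly optimistic under heavy
  weighting.
- Wald CIs for sparse polytomous levels can be degenerate; such levels
  are flagged rather than fixed (no Firth correction).
- The grade-0 reference group can be small on synthetic cohorts whose
  score distribution is lumpy (a few large point values dominate), which
  widens grade-HR CIs.
- The AUC convention excludes participants censored before the horizon
  rather than reweighting them (no IPCW time-dependent AUC).
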