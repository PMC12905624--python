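# Methods

This note documents the models, the synthetic world, the numerical choices
and their rationale. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## CGM signal conditioning

Wearable glucose sensors exhibit slow non-physiological drift (calibration
dynamics, sensor–tissue interaction), step-like offsets between consecutive
sensors, measurement noise that is approximately Gaussian with short-range
autocorrelation, and missing data. The chain addresses each in turn:

1. **Segmentation.** Records split where the inter-sample interval exceeds
   `max_gap` (20 min, strict) or the sensor changes — a sensor change is a
   new calibration regime even without a time gap. Concatenating segments
   reproduces the input exactly.
2. **Short-gap interpolation.** Missing grid points inside a segment are
   filled linearly between flanking observations; nothing is extrapolated
   past segment ends. Gaps > 20 min are never bridged.
3. **Drift correction.** Within each segment a slowly varying baseline is
   the 0.10 quantile in sliding 4-h windows advanced by 1 h, joined at
   window centres by a monotone cubic (PCHIP) and subtracted. A low
   quantile tracks the fasting envelope without chasing meal peaks; PCHIP
   avoids the overshoot a natural spline would add. Segments shorter than
   2 h carry too little support and pass through flagged. The window,
   step and quantile are exposed in `PreprocessConfig` because no standard
   values exist for this class of baseline estimator.
4. **Stable-baseline re-referencing.** Drift removal leaves each segment
   centred near zero, so all segments are shifted by a participant-specific
   fasting reference: per night, a 1-h window slides in 5-min steps over
   the raw 00:00–08:00 values; the night's candidate is the mean of its
   lowest-SD full window; the reference is the minimum candidate across
   nights. Variability is sample SD and the night summary is the window
   mean — simple choices where only "lowest variability" is canonical.
   With no complete overnight window the 5th percentile of all raw values
   substitutes, flagged. Note the reference deliberately comes from *raw*
   values: it restores absolute scale and gives both sensors a common
   anchor, at the cost of inheriting any calibration offset present during
   the quietest night.
5. **Smoothing.** 5-tap Gaussian kernel (σ = 1 grid step, truncated at ±2
   steps), renormalised at segment edges so constants are preserved;
   smoothing never crosses segment boundaries and is applied exactly once.
6. **Gridding.** Left-closed 5-min bins labelled by left edge; multiple
   samples per bin averaged; empty bins stay empty. Timestamps are
   timezone-naive device-clock values throughout (CGM and EMA share the
   device clock; DST is ignored).
7. **Assessment alignment.** For an assessment at time *t* the matched
   glucose is the mean of grid samples in [*t*+5, *t*+10] min — the
   physiological delay of glucose transport from blood to interstitium —
   with both 5-min grid points eligible and averaged when present. An
   empty window leaves the observation without concurrent glucose;
   participants need ≥ 20 concurrent runs for inclusion.

## Observation-level models

All continuous predictors are z-standardised across *all* observations
(grand moments, not within person), after QC inclusion, so fixed effects
are comparable across scales; glucose is ln-transformed first (right
skew). Mixed models have a participant random intercept plus random slopes
for each focal predictor, estimated by restricted likelihood via
statsmodels' MixedLM. The random-effects correlation is estimated by
default; on convergence failure the fit falls back to uncorrelated random
effects, then to intercept-only, each rung flagged and never changing the
fixed-effect specification. Inference uses t statistics with residual
participant-level degrees of freedom (n participants − n fixed effects) —
a deliberate approximation in lieu of Satterthwaite, which the backend
does not provide; the acceptance suite verifies its calibration (type-I
error and CI coverage bands) by simulation.

**Interoceptive accuracy** is −(fixed slope + conditional mode) from the
glucose→metabolic-state model: a shrunken per-person slope, not a separate
per-person regression, so low-information participants are pulled toward
the population value rather than dominated by noise. The inversion makes
"ratings track glucose closely" score high. The reversed direction
(predicting glucose from ratings) is available behind a flag; it targets a
more heavily shrunken estimand and is not the default.

**Participant-level models** are ordinary least squares: mood mean and
mood SD each on accuracy × (BMI + age + sex), and accuracy on
BMI × residual-HOMA-IR × sex + age.

## Metabolic indices

HOMA-IR = fasting glucose (mg/dL) × fasting insulin (mU/L) / 405, median
over up to three draws, ≥ 2.5 flagged elevated, ln-transformed for
parametric use and residualised (OLS) on BMI, sex and age; the residual is
z-standardised for modelling. TyG is computed in two variants — classic
ln(TG·G/2) and a halved variant ln(TG·G/2)/2 — because descriptive tables
in healthy cohorts appear on both scales; neither is asserted as canonical
and the variant is a config choice.

Sensitivity refits exclude participants with BMI ≥ 30 or HOMA-IR ≥ 2.5
(thresholds configurable; ≥ matches how such counts are usually tabulated)
and rerun the model battery and mediation on the subset, reporting deltas.

## Mediation

The decomposition follows the product-of-coefficients structure for linear
mixed models without a treatment–mediator interaction (the interaction is
examined separately in the M4 model and not carried into the mediation).
Uncertainty propagation is quasi-Bayesian over fixed effects only: draws
from N(β̂, Cov(β̂)) for each model, with random-effect uncertainty entering
through that covariance. Per draw ACME + ADE = total holds exactly. The
proportion mediated uses only draws with |total| above a machine-scaled
epsilon (excluded draws are counted) and carries an instability flag
whenever the total's interval covers zero — in that regime the ratio's
interval is expectedly wide and its sign unstable, which is reported, not
patched. Point estimates are medians of draws (robust under the ratio's
skew). The total effect is the combined-model total (a·b + c′); a separate
total-effect model is not fitted.

## The synthetic world

The generator emulates a four-week observational study of ~90 healthy
adults (46 female / 44 male when configured): 5-min CGM with bi-exponential
meal excursions (rise τ ≈ 20 min, decay τ ≈ 60 min; three meals/day with
jitter), a nonnegative circadian elevation (amplitude 5 mg/dL peaking at
16:00, zero trough overnight so "basal" *is* the overnight fasting floor
the stable-baseline stage estimates), per-sensor smooth cubic drift
(amplitude 10 mg/dL, nonnegative — calibration bias is treated as
unidirectional so the raw overnight minimum still reaches basal), a sensor
swap after 14 days with a calibration step (sd 5 mg/dL), AR(1) noise
(sd 3 mg/dL, φ = 0.6), and short (<20 min) and long (>20 min) gaps at ~1
and ~0.15 events/day. Glucose is clamped to [40, 250] mg/dL.

EMA: two assessments/day in 08:00–23:00 at least 2 h apart, ~85%
completion (mean ≈ 48 of 56 scheduled). Ratings derive from latents on the
grand-standardised ln-glucose scale z:

    m  = a_i·z + ε_m,          a_i ~ N(−0.5, 0.2²),  sd(ε_m) = 0.6
    y  = c′·z + b·m + ε_y,     b = −3,  c′ = 0
    hunger  = clip(50 + h_i + 20·m),   satiety = clip(100 − hunger + ε_s)
    happy   = clip(60 + (y + y_i)/2),  sad = clip(40 − (y + y_i)/2)

with between-person intercepts h_i (sd 8 VAS) and y_i (sd 12 VAS), satiety
inconsistency noise sd 4 VAS, and per-person mood noise
sd = 8 + 6·(1 − |a_i|) — weaker interoceptors fluctuate more. The latent
noise sd 0.6 gives an average within-person glucose–hunger correlation
near 0.6, consistent with the strong population coupling such studies
report and sufficient per-person slope reliability at ~48 observations for
the accuracy construct to be meaningful. Cohort generation is two-pass
(traces first, then ratings from cohort-level ln-glucose moments) so the
generative slopes are the estimands of the fitted models. Everything is
driven by per-participant `SeedSequence` substreams: identical seeds give
bit-identical cohorts.

Demographics and labs: age ~ N(24.3, 3.6²), BMI ~ N(24.7, 4.1²), basal
glucose ~ N(85, 7²) mg/dL; fasting insulin log-normal with a mild BMI
dependence (so residualisation has signal to remove) and triglycerides
log-normal around 105 mg/dL, three draws each.

`simulate_observations` is a model-level fast path that draws standardised
glucose directly (between-person sd 0.4, within-person remainder) and maps
it through the same latent→VAS machinery; it exists for statistical
calibration studies where re-simulating and re-conditioning the sensor
layer adds runtime but no information.

**What a green test does not establish.** The generator's world is linear
with Gaussian noise; real cohorts have meal-timing structure, circadian
mood rhythms, autocorrelated affect, missingness that is not completely at
random, and rating-scale artefacts beyond clipping. The VAS mapping itself
attenuates recovered mediated effects by a few percent (clipping plus the
satiety inconsistency noise act as mediator measurement error) — recovery
tests therefore check interval coverage of the stated truth, not exact
equality. Drift is modelled as smooth and unidirectional; sharp sensor
failures are represented only as missingness.

## Known limitations

- No physiological glucose–insulin dynamics (no minimal-model ODEs); meals
  are additive bi-exponentials.
- The stable baseline inherits any calibration offset active during the
  quietest night; with signed between-sensor offsets the absolute level is
  only as good as the better-calibrated sensor.
- Degrees of freedom are a residual-df approximation; with very few
  participants, inference leans conservative/anticonservative within the
  simulated calibration bands rather than exactly nominal.
- Mediation assumes sequential ignorability; no sensitivity analysis for
  unmeasured confounding is included.
- The proportion mediated is undefined when the total effect is near zero;
  it is reported with the instability flag rather than suppressed.
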