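# Methods

This note documents the models, conventions and design choices behind
`swimresp`, in the spirit of a methods appendix: what each computation
assumes, which defaults matter, and what the synthetic validation does and
does not demonstrate.

## Respirometry

Closed-phase oxygen consumption assumes a well-mixed respirometer and a
constant metabolic rate over the phase, so PO2 (% air saturation) declines
linearly.  The slope is an ordinary least-squares fit restricted to
t ≥ 120 s (configurable `wait_period_s`), excluding the mixing transient;
r² is the squared Pearson correlation of the retained points.  At least 30
post-wait samples are required.  Fits with r² < 0.80 are flagged `low_r2`
but retained — low-r² resting fits are normal for low metabolic rates and
dropping them would bias RMR upward.

Conversion from % saturation to concentration uses the García–Gordon (1992)
combined fit of the Benson–Krause solubility data (ml l⁻¹ × 1.42905 mg ml⁻¹),
valid for 0–40 °C and 0–40 ppt; the formulation name is recorded in
`respirometry.SOLUBILITY_FORMULATION` and the function is pluggable at the
`compute_mo2(beta=...)` boundary.  Effective volume subtracts the fish's
volume at a body density of 1.0 kg l⁻¹ — standard respirometry practice.
A positive slope beyond 1 % sat h⁻¹ raises a leak error; smaller positive
slopes clip to MO2 = 0 (sensor noise around zero consumption).

Background (microbial) respiration, measured in the empty tunnel, is
expressed as a fraction of the fish's rate; below 1% it is recorded but not
subtracted, at or above 1% the fish's MO2 is adjusted by subtraction.

## Cardiac traits

Heart rate reproduces manual chart reading: systolic peaks are counted in two
non-overlapping 30-s windows (defaults: first and last 30 s of the closed
phase) and the mean count doubled to beats min⁻¹.  The detector uses an
adaptive threshold (midpoint of the 10th/90th amplitude percentiles in the
window), a prominence guard of half the 10th–90th range to reject sensor
noise riding on a systolic lobe, and a refractory period of 0.25 × the median
inter-peak interval from an initial pass.  All settings are module constants
logged with each detection.  Counting quantizes fH to about ±2 beats min⁻¹
for 30-s windows; stroke volume inherits that quantization through
VS = Q̇/fH.

Cardiac output is the time-averaged flow over the whole trace (windowed
averaging available), divided by body mass.  Tissue oxygen extraction is
MO2/(60·Q̇); the factor 60 reconciles per-hour MO2 with per-minute Q̇ and is
asserted in code because it is easy to lose silently.  The identities
Q̇ = fH·VS and MO2 = 60·Q̇·extraction hold exactly for every emitted sample
by construction.

## Swimming performance

Ucrit = V + tf·Vi/ti with V the highest fully completed speed.  The increment
Vi and step length ti default to the recorded schedule's own values.  A fish
that fatigues during the first swimming step is scored with V = 0 and flagged
`sub_protocol`.  The solid-blocking correction is applied multiplicatively to
the final Ucrit (not per step; a per-step correction would change nothing for
a constant girth but would complicate the schedule bookkeeping), using the
fish's own girth: ε = τλ(A0/AT)^1.5 with τ = 0.8, λ = 0.5, exponent 1.5,
A0 = 0.25G²/π and AT = πr² in cm².  Body lengths are fork lengths, the
measured length.

## Trait assembly

* RMR: the MO2 sample at the 0.08 bL s⁻¹ baseline (pre-test, not
  post-recovery).
* MMR: the maximum single-step MO2 across swim steps, including the partial
  exhaustion step when a closed phase fit inside it — the conventional
  incremental-test definition, not necessarily the final step.
* SMR: 10^intercept of the log10(MO2)-on-speed regression over sustained
  (pre-exhaustion) swim steps; base 10 by default, base-e selectable (only
  the intercept transform differs).  Fish that fatigued after fewer than
  three increments fall back to including the exhaustion-step sample and, as
  a last resort, the baseline point, each fallback flagged
  (`smr_fit_includes_exhaustion` / `_baseline`).  With real data the baseline
  fallback can bias SMR upward (postural costs); with the generator's
  log-linear model it is exact.
* Scopes are identities (AAS = MMR − SMR, etc.) and therefore hold exactly;
  physiological ordering violations (SMR > RMR etc.) are flagged, never
  repaired.
* Q10 is evaluated from group means — with unpaired temperature groups a
  per-fish Q10 does not exist.  The expression is orientation-invariant.
  The bundled printed Q10 table is reference-only: it is not reproducible
  from the bundled group means via the defining expression (e.g. resting fH
  gives 2.01 against a printed 2.06), so Q10 output is validated by the
  identities (Q10 = 1 at equal rates, 2 for a doubling over 10 °C,
  orientation invariance) rather than against that table.

## Statistics

Welch's t (Welch–Satterthwaite df) and the paired t delegate to scipy behind
the module interface; both are cross-checked in the tests against independent
hand-formula oracles.  Degenerate inputs follow explicit conventions: two
identical constant groups give p = 1, two separated constant groups p = 0.
Grubbs (two-sided, sample SD) and Rosner's generalized ESD are implemented
from their t-distribution closed forms; Rosner warns below n = 10 and flags
the largest i with R_i > λ_i together with all more-extreme candidates.
Shapiro–Wilk and Levene screens are exposed as a delegated pre-check — they
gate nothing downstream.  All tests are two-sided at α = 0.05 with no
multiplicity adjustment.  Group tables report mean ± 1 SEM with two-group
significance letters (a/b).

## Synthetic generator

The generator defines the study conditions used throughout validation:

* two temperature groups (22 and 30 °C, 34 ppt), n = 9 fish each, in a
  108.7-l tunnel of 120 mm radius;
* schedule: 0.08 bL s⁻¹ baseline, first swimming speed 0.35, increments of
  0.15 bL s⁻¹ every 15 min; 2-h recovery with cardiac samples every 15 min
  and MO2 every 30 min; temperature ramped at 1 °C h⁻¹ (metadata only);
* MO2–speed coupling is the same log-linear model the SMR extrapolation
  assumes, so extrapolation bias is zero by construction noise-free; a
  quadratic curvature option exists for robustness probing;
* group-level truths equal the published group means, with the log-linear
  slope set through (Ucrit, MMR) — which also lands the implied RMR at the
  baseline speed within ~1% of the published value;
* between-fish biological variability uses CV = 3·SEM/mean from the published
  group table (n = 9 ⇒ SD = 3·SEM), with redraws enforcing physiological
  ordering and Ucrit > 0.40 bL s⁻¹ so every fish yields an SMR fit;
* flow is a train of half-sine ejection pulses (systolic fraction 0.4 of the
  cardiac period), each integrating to one stroke volume — the waveform shape
  is a modelling choice, chosen for integrability and peak-detectability;
* recovery decays single-exponentially toward resting values; the time
  constants (30 min at 22 °C, 70 min at 30 °C) reproduce the published 2-h
  endpoints (full recovery at 22 °C, ~40% elevated MO2 at 30 °C);
* noise is additive Gaussian, independent across samples (AR(1) option in
  config): PO2 sd 0.05 % sat (giving resting-fit r² in the published 0.87–0.95
  range), flow sd 2 ml min⁻¹ (~4–5% of a resting pulse peak);
* sampling rates (PO2 1 Hz, flow 100 Hz), closed-phase length (480 s, shorter
  if the 85% air-saturation floor would be approached; minimum 150 s so the
  2-min wait leaves 30 samples) and the 65-s flow windows are configuration
  choices, not protocol facts;
* exhaustion is placed inside the step containing the true Ucrit so the
  prorating formula inverts it exactly; the exhaustion-step MO2 is the model
  value at Ucrit (the fish's maximum aerobic output) and is emitted only when
  the time to fatigue accommodates a minimal closed phase, so fish fatiguing
  within ~2.5 min of a step change contribute their last full step to MMR
  (a small, quantified downward bias well inside 2 SEM at the study design).

What passing these validations shows: the pipeline inverts its own data
model exactly and recovers group means under realistic noise at the study's
sample size.  What it does not show: robustness to features of real traces
the generator omits — sensor drift, flush artefacts, behavioural
non-stationarity (burst-and-coast swimming, refusals), waveform morphology
(dicrotic notches), probe failures, or deviations of true metabolism from
log-linearity in speed.

## Validation design

Parameter-recovery coverage compares each replicate's estimated group mean
against the mean of that replicate's own per-fish true values, within 2 SEM
of the estimates — standard confidence-interval coverage, which isolates
measurement/estimation error from sampling error of the biological draw.
The acceptance run uses 100 replicates (50 per temperature pairing) of the
full n = 9 design, sized to keep the whole run around half a minute on one
core while leaving the coverage estimate's Monte-Carlo error near 3
percentage points.
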