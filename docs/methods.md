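# Methods

This note documents the models, conventions and numerical choices behind
`motornorms`, in the order data flows through the package.

## Coordinate frame and landmark set

Recordings are 25-landmark skeletons in the Kinect-v2 joint set, in a
right-handed camera frame: +x to the subject's left when facing the sensor,
+y up, +z from the sensor toward the subject. The "pelvic center" is the
spine-base joint; the "manubrium" is the spine-shoulder joint. A subject
walking toward the sensor has decreasing z. The sensor sits at 1.4 m height
with a pitch of roughly −8° to −9°; preprocessing rotates all coordinates
by −pitch about the lateral axis so the vertical axis is gravity-aligned
(a pure rotation — inter-landmark distances are preserved to ~1e-9 m).

## Preprocessing

1. tilt correction (above);
2. tracking gaps up to `max_gap` (default 0.5 s) per landmark are bridged
   by linear interpolation and marked valid; longer gaps are still filled
   so filtering stays well defined, but the recording is flagged
   (`qc_gap_exceeded`) and QC discards it — gaps are never silently fixed;
3. resampling to the uniform nominal rate (default 30 Hz) by linear
   interpolation — consumer sensors jitter their timestamps and the
   extraction assumes a uniform dt;
4. a zero-phase 4th-order Butterworth low-pass at 6 Hz, which retains all
   voluntary movement content of gait and transitions.

Within the extractors, *derived* series whose physiological band is much
narrower get a second, harder zero-phase low-pass before differentiation or
thresholding: tandem-walk trunk/arm vectors and progression velocity at
1.2 Hz, sit-to-stand vertical velocity at 1.5 Hz, postural sway vectors at
1 Hz. Rate estimates (mean |frame difference| / dt) and extreme-value
statistics (max − min) amplify residual landmark noise; restricting them to
the signal band is standard sway/transition practice. Folded (unsigned)
angles are never filtered after folding — the smoothing is applied to the
underlying vectors, since folding moves signal energy into harmonics.

## Direction conventions

Walk tasks measure along the *walk axis*, the net horizontal pelvis
displacement; the lateral axis is its 90° horizontal rotation. Stationary
tasks (SIP, SAS, POCO) use body-derived axes: anterior is the horizontal
perpendicular of the mean shoulder line. All parameters are therefore
invariant to rotating the scene about the vertical axis. One caveat: the
walk *measurement band* is defined as pelvis-to-sensor horizontal distance
in [2.0, 4.0] m (configurable), which anchors it to the sensor; it excludes
the static-start acceleration and the near-field tracking loss inside the
1.5–4.5 m operating range. Horizontal translations of the scene can
therefore shift band membership for walk tasks; everything else is fully
translation-invariant.

## Extraction algorithms (selected conventions)

- **Step events** are local extrema of the signed left-minus-right ankle
  position along the walk axis, prominence ≥ 0.15 m, restricted to the
  measurement band, minimum separation a quarter of the median
  inter-extremum interval, sides forced to alternate (of two same-side
  events the one with larger foot separation wins). Event times are refined
  to sub-frame precision with a three-point parabola; at 30 Hz and walk
  spans of ~1–3 s, half-frame quantization would otherwise bias cadence by
  1–2 steps/min.
- **Gait speed** is the least-squares slope of the pelvis position along
  the walk axis over in-band frames. **Cadence** uses the first-to-last
  event span (60·(n−1)/span), not the raw recording length, to avoid
  counting pre-cue standing.
- **Step length** is the foot separation along the walk axis at each
  placement, averaged (the per-step placement-separation convention);
  width is the mean absolute lateral separation at placements.
- **Arm swing** is the wrist elevation angle at the manubrium,
  atan2(anterior offset, downward vertical offset); the amplitude is the
  per-gait-cycle max − min, cycles delimited by consecutive same-side step
  events (cycles may extend beyond the band — the band guards step
  geometry, not the arm oscillation), then averaged per side.
- **Symmetry angle** between side amplitudes L, R is
  |45° − atan2(L, R)·180/π| / 90°, a fraction in [0, 0.5], 0 = perfect
  symmetry; undefined (absent) only when both sides are zero.
- **SIP** uses anterior knee-excursion peaks (prominence ≥ 0.05 m) above a
  5th-percentile baseline. Stance is the per-cycle dwell below 20% of the
  side amplitude — a documented convention, since no formal stance
  definition exists for stepping in place. Arrhythmicity is the mean of the
  left and right CoVs of peak-to-peak stride times, in percent.
- **SAS** transitions are the maximal positive (stand-up) and negative
  (sit-down) episodes of the manubrium vertical velocity; bounds are where
  |v| falls below 10% of the episode peak (configurable), consistent with
  formal sit-to-stand phase definitions. For a sin²-shaped velocity pulse
  of nominal duration D the detector reports
  D·(1 − 2·asin(√0.1)/π) ≈ 0.795·D — the generator records this closed
  form as its detected-duration truth.
- **POCO** measures the sway vector from the segment-mean ankle midpoint to
  the pelvic center: pitch = atan2(anterior, vertical), roll =
  atan2(lateral, vertical); the 3D inclination is measured against the
  segment-mean sway direction (the "3D direction" convention adopted
  here). Ranges are max − min; speeds are mean |frame difference|/dt, and
  the 3D speed is the mean frame-to-frame angular step of the unit sway
  vector. Romberg ratios divide each closed-eyes measure by its open-eyes
  counterpart; an open-eyes value at the numerical floor makes the ratio
  absent ("degenerate denominator").

Units follow the normative tables: step length/width in cm, knee amplitude
in m, sway in ° and °/s, symmetry angles as fractions. Two published unit
ambiguities are resolved as: tandem progression speed in m/s (the table
body, not the header typo), and relative progression variability as a
fraction (its normative mean 0.33 is only coherent on the fraction scale).

## Synthetic motion generator

The generator is deliberately minimal — rigid trunk, sinusoidal limb
oscillations, smooth-step (sin²-velocity) transitions — because its job is
to exercise event detection and parameter recovery with *known* truths, not
to be biomechanically realistic. Key constructions:

- **Walks**: the pelvis accelerates linearly over the first two steps
  (static start just outside the 4.5 m range, beginning at 4.7 m) and then
  translates at the truth speed; foot placements are spaced one step length
  (60·speed/cadence) apart on the steady-state beat, each swing lasting
  half a stride with zero end velocities, so the left-minus-right ankle
  extremum falls exactly on each placement. Wrists swing sagittally at
  cadence/2 with per-side peak-to-peak amplitudes.
- **Tandem gait**: constant (or sinusoidally modulated) progression at
  0.35 m/s; trunk roll is a sinusoid locked to the stride rate
  (cadence/120 Hz); ankles oscillate anti-phase relative to the hips on a
  single file. With a planted speed CoV c the extracted time-average speed
  over the fixed path is biased by about −c² (slow frames spend more time
  in the window), so exact speed recovery is asserted at c = 0 and the
  scale-free CoV at c > 0.
- **Stepping in place**: per-side sin² knee-excursion humps on stride
  grids jittered multiplicatively log-normal (keeping times positive) to a
  target CoV; the swing occupies half the nominal stride, giving the
  closed-form stance truth T − (1 − 2·asin(√0.2)/π)·T_swing.
- **Sit-stand-sit**: smooth-step chest rise of 0.45 m over the nominal
  durations with a forward-then-back AP excursion spanning exactly the
  truth deflection inside the transition.
- **Postural control**: the pelvis sways about the fixed ankle midpoint
  with horizontal offsets h·tan(angle), so atan2 recovery is exact;
  segments are pure sinusoids (closed forms: range 2A, mean speed 4fA) or
  band-limited noise with target RMS.
- **Cohorts**: three studies (41/57/35), 56% female, ages from a truncated
  normal (36.8 ± 10.4, range 20–60), sex-conditional height/weight normals
  whose mixture reproduces the cohort-level 172.9 ± 9.3 cm and
  71.8 ± 13.9 kg. Parameters are drawn i.i.d. around the packaged normative
  mean/SD unless a linear effect (β's + residual SD) is planted.
  Recordings can be materialized from a subject's parameter truths for the
  parameters with closed-form inverses.

Everything is a pure function of (truth, seed) and reproduces bit-exactly.
What the generator does **not** emulate: occlusion and soft-tissue
artifacts, correlated landmark noise, inverse-kinematic coupling, skewed
real-world parameter distributions. Passing recovery tests therefore
demonstrates algorithmic correctness on idealized kinematics, not clinical
validity on real recordings.

Recording durations not fixed by protocol (SIP 40 s, POCO 2×20 s are) are
implied by the 3 m capture path at the truth speed.

## Confound modelling

Design: intercept, age, sex (female 0 / male 1), height, weight, plus k−1
effect-coded study columns (reference level = lexicographically last label,
coded −1; irrelevant to prediction but fixed for reproducibility).
Cross-validation shuffles subjects uniformly into five near-equal folds,
100 repetitions, per-repetition generators derived from the master seed via
a seed-sequence counter. Fits use the full design; held-out predictions
drop the study term (emulating external data). Per fold,
Rtest² = 1 − SSres/SStot with SStot around the test fold's own mean
(training-mean baseline available as config); per-fold values are averaged
(prediction pooling available as config). The gate is the strict inequality
mean Rtest² > 0.1. Test-fold R² is a coefficient of determination, not a
squared correlation — negative values are expected and required for
uninformative models. Full-data coefficients, classical 95% CIs and
p-values come from OLS; the residual SD uses denominator n − p.

## Normative statistics and scoring

Descriptives are mean, sample SD (n−1), CoV = SD/mean, and quartiles by
linear interpolation between order statistics (the common type-7 rule; the
convention reproduces the published CoV values from the published
mean/SD at print precision). The packaged `reference_norms.json` carries
the published per-parameter statistics (with per-task n) verbatim at
printed precision plus the two gated confound models, so scoring works with
no cohort data; users rebuild the resource from their own cohorts with the
same pipeline. Scores are displayed at 2 decimals.

Known discrepancy: the published residual z-score for the example
patient's step length (−2.70) is not reproducible from the printed
coefficients and covariates — recomputation gives −3.05, consistent with a
study-effect term having entered the original prediction. The package
implements the residual equation exactly as defined; the step-width value
reproduces within the ±0.07 coefficient-rounding tolerance. Z-scores are
also reported for parameters with skewed normative distributions (as the
reference tables do), with the caveat that they cannot be converted to
percentiles there.

## Quality control

Basic configurable heuristics only: per-task minimum durations, the
preprocessing gap flag, pelvis net displacement ≥ 1.5 m for gait tasks, and
pelvis horizontal drift ≤ 0.3 m for postural control. The original
full QC pipeline is not public; the rule set is config-driven so users can
approximate it. Discard rates on real data are not reproducible from
synthetic input and are reported as computed.

## Test problem sizes and known limitations

The recovery suite uses one noise-free recording per task plus 50 seeds at
5 mm landmark noise; the gate suite uses n = 126 cohorts, 20 master seeds,
100×5-fold CV; coefficient recovery uses 250 simulated cohorts. These sizes
make the Monte-Carlo acceptance margins small while keeping the default
test run fast.

One recovery bound is knowingly not met and its test is expected to fail:
postural-sway range/speed under 5 mm landmark noise. Through the ~0.9 m
ankle-to-pelvis lever, 5 mm of i.i.d. landmark noise is ~0.32° of angular
noise per frame — the same order as physiological quiet-stance sway
(~0.5°). Sway range is an extreme-value statistic and sway speed a mean
absolute difference; both are inflated by residual noise even after
sway-band filtering (measured +10–45%), and no linear zero-phase filter can
remove it without attenuating the 0.2–0.3 Hz sway signal itself. Real
systems face the same floor: published sway norms include the sensor noise
of the measuring device. All other tasks recover within twice their
noise-free tolerances in ≥ 96% of seeds.
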