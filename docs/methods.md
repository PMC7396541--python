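# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the tests do and do not demonstrate.

## Signal conventions

All trials are uniformly sampled (100 Hz default) with three IMU channels
from a thigh-mounted sensor: thigh angle θ_z in degrees (0° at quiet
standing, positive with the thigh forward of vertical), thigh angular
velocity ϖ_z in rad/s about the mediolateral axis, and forward axial
acceleration a_x. The acceleration channel is treated as unit-agnostic
("sensor units"): its thresholds and statistics are pure numbers, matching
how the reference values are printed. Optional heel/toe insole-pressure
channels (arbitrary nonnegative units) serve only as reference ground
truth. The angle convention assumes a vertical-standing zero; the
`integrate_angle` helper implements the accompanying angle-from-rate
accumulation θ[k] = θ[k−1] + ϖ[k]·(180/π)/fs.

All detection runs on **causally** low-pass filtered channels (2nd-order
Butterworth, 5 Hz cutoff, recursion initialized at the first sample's value
to suppress the startup transient): a streaming detector cannot see future
samples. The zero-phase two-pass variant exists for offline reference
reading only. The first and last parsed stride of every trial are excluded
from evaluation (boundary effects, startup transient).

## Heel-strike detection

A three-phase state machine per cycle:

1. **Peak tracking.** While the angle rises, the running maximum is the
   peak candidate. A turn is *confirmed* only when the angle has dropped
   `confirm_margin_deg` (default 1.0°) below the running maximum —
   one-sample turn rules fire on noise wiggles at the flat peak top. A
   confirmed candidate is *accepted* if its prominence above the preceding
   trough is ≥ `prominence_deg` (default 5°) and it lies at least
   `refractory_frac` (default 0.4) of the current stride period after the
   previously accepted peak. The refractory base period is the measured
   HS-to-HS interval once two heel strikes exist (clipped to [0.5, 1.5] ×
   the trial's nominal period so one missed cycle cannot poison the gate),
   else the nominal period from trial metadata.
2. **Threshold prediction.** θ̂_h = B + W·(a_p, θ_p, ϖ_p) from the channel
   values at the accepted peak, clamped to at most θ_p − 0.5° so an
   over-predicting model cannot self-trigger at the peak.
3. **Crossing.** During the descent, HS is emitted at the first sample with
   θ ≤ θ̂_h. If a new rise (hysteresis margin again) begins before the
   crossing, the cycle is counted as a missed-crossing diagnostic; there is
   no fallback trigger — misses surface in the frequency error.

### Training the threshold model

Ordinary least squares on one row per stride (no regularization: four
parameters, hundreds of strides). The training reads are **detector
matched**: the peak features are read from the causally filtered channels
at that channel's own thigh-angle maximum, and the regression target is the
causally filtered angle at the true heel-strike instant. This convention
makes the filter's group delay (~45 ms at these frequencies) cancel at the
threshold crossing: the model learns to predict the value the *causal*
channel attains when the true event happens. Training instead on lag-free
(zero-phase or raw) targets leaves a systematic detection delay of
1–2% of the gait cycle that varies with stride frequency, because the
angle equivalent of a fixed time lag scales with the descent slope. The
lag-free reading modes are retained for correlation analysis
(`collect_training_pairs(mode="zero_phase" | "raw")`).

Splits are always at the subject level (no subject in both sets),
randomized deterministically per seed; the default ratio is 7:3. Models
pooled across the three stride frequencies perform within half a percent
of the cycle of frequency-specific models (tested), so the pooled model is
the default.

## Toe-off detection

A pure threshold conjunction, evaluated only outside the blanking window:

- armed once t_L ≥ α·T after the last heel strike (t_L counted in integer
  samples to avoid float drift);
- fires at the first sample with ϖ ≥ ϖ* **and** θ < θ* **and** a_x > a*;
  comparison operators deliberately asymmetric (the angular-velocity bound
  is the limiting threshold and is inclusive);
- at most one toe off per cycle; the detector then idles until the next
  heel strike.

α may be configured above 0.58 (with a warning) precisely because the
failure mode is instructive: toe off occurs at ~58% of the cycle, so a
blanking window that long overruns the event and the detector misses
essentially every cycle (verified by simulation at α = 0.7).

## The synthetic gait generator

The generator is the package's substitute for the unavailable human
recordings; it is calibrated to the published event-moment statistics, not
to biomechanical fidelity.

**Event features.** Each stride draws a 6-tuple
(θ_p, ϖ_p, a_p, θ_h, ϖ_h, a_h) — the three channels at the thigh-angle
peak and at the following heel strike — from a joint Gaussian whose
peak→HS cross-correlation block is set to the reference table
(r(θ_p, θ_h) = 0.8604, …). Variance splits 55% between-subject / 45%
within-subject with the same correlation structure at both levels, which
keeps the pooled correlations exact regardless of the split and gives six
subjects a heel-strike angle spread of ≈19°. Free constants (means and
SDs not fixed by any published value): θ_p ~ 40 ± 10°, θ_h ~ 23 ± 10°,
ϖ_p ~ 0.05 ± 0.25 rad/s, a_p ~ −0.5 ± 1.0, ϖ_h ~ −0.45 ± 0.15,
a_h ~ 0.3 ± 0.3.  The ϖ_p and a_p standard deviations are set wide enough
that the fitted coefficients on those channels stay small, keeping the
predicted threshold insensitive to filtered channel noise in the feature
reads.  Draws implying a geometrically degenerate descent are rejected and
redrawn (peak-to-HS drop ≥ 3.5° per stride, ≥ 6° at the subject level;
both floors sit >2.5 SD below the mean drop of 17°, so under 1% of draws
are affected and the joint feature distribution — and with it the linear
peak→HS relation — is preserved on every kept stride). The within-peak correlations are chosen so that the
implied linear relation θ_h | (a_p, θ_p, ϖ_p) is nearly deterministic
(residual SD ≈ 0.19°): the adaptive-threshold premise is that the
heel-strike angle is linearly encoded in the peak features, and the
dispersion of real-world temporal errors is attributed to sensor noise and
reference labeling rather than to model misfit. Consequently the simulated
cohort's temporal errors (~0.5% MAE) sit *below* the published ~1.3%: the
generator carries no insole-labeling error, no sensor-mount wobble and no
robot interaction torques, so passing the ≤2% bound here shows the
detection machinery is sound, not that real-world accuracy would be this
good.

**Toe-off moments.** (θ, ϖ, a) at toe off are population-level draws
(healthy: −8.31 ± 5.17° / 0.32 ± 0.12 rad/s / 1.76 ± 1.32; hemiplegic:
−7.68 ± 4.36 / 0.26 ± 0.11 / 1.27 ± 1.08), clamped to physically
sign-definite ranges (θ ≤ −1°, ϖ ≥ 0.05, a ≥ 0.15) with the pre-clamp
center analytically shifted so the post-clamp means equal the targets.
There is no between-subject component in these draws, so a profile's
toe-off parameters are the group calibration values verbatim.

**Waveforms.** The thigh angle is a shape-preserving monotone (PCHIP)
interpolation through per-stride keyframes — HS (0%), trough (50%, ~−12 ±
3°), TO (58%), a post-TO point (65%, the rapid forward swing after
lift-off), peak (90%) — so the angle decreases monotonically from each
peak through the next heel strike to the trough by construction. The
angular-velocity channel is the analytic derivative of that interpolant
plus a smooth (PCHIP) correction pinned so the channel passes exactly
through each stride's sampled event values, with an extra pre-TO pin
(ϖ ≈ 0.03 rad/s at 55% of the cycle) concentrating the angular-velocity
rise just before toe off, as in real swing initiation, and pre-peak pins
(~83% of the cycle) that flatten ϖ and a_x across the peak so the
peak-feature reads are insensitive to the causal filter's lag. The acceleration
channel interpolates its event keyframes directly. Heel pressure is a
smoothed pulse rising exactly at HS; toe pressure holds until TO and
falls from it, so trend-based labeling of rise onset / fall onset recovers
the true events. Stride periods are jittered (CV 2%, the cadence tolerance
of a robot-paced protocol); channel noise (0.5° / 0.05 rad/s / 0.2 /
5% of pulse height, scalable) is added *before* filtering so the causal
filter is genuinely exercised.

**What the generator does not emulate:** turning, stairs or non-steady
gait; bilateral coordination (single leg only); integration drift of the
angle channel; pressure-sensor failure modes (e.g. uneven loading in
strephenopodia); robot assistance torques. Results on this data bound the
algorithmic error only.

## Reference labeling and metrics

Insole-pressure labeling is trend-based and scale-invariant: HS is the
first sample of a sustained heel-pressure rise (smoothed derivative above
κ·range/s for ≥ d samples, starting near baseline and reaching stance
level; κ = 0.05, d = 3), TO is the first sample of the sustained
toe-pressure fall in each cycle that reaches below 20% of that cycle's toe
maximum within a short fall episode. Smoothing is zero-phase (10 Hz) —
the labeler is an offline tool.

Temporal error = 100·(t_ref − t_det)/T (% gait cycle, positive = early);
frequency error = 100·(n_det − n_ref)/n_ref. Detected events are matched
one-to-one to the nearest reference event of the same kind within half a
cycle; unmatched events count as extras/misses in the frequency error
only. MAE is the mean absolute temporal error over matched strides.

The conventional baseline replaces the regression with one fixed
thigh-angle threshold (the training-split mean heel-strike angle) and
emits only genuine downward crossings: a cycle whose peak never reaches
the threshold is a structural miss. This isolates exactly what adaptivity
buys; it is not a reconstruction of published shank- or foot-based
threshold methods.

## Numerical choices and degenerate inputs

- Butterworth design via `scipy.signal.butter`; causal runs use
  `lfilter` with `lfilter_zi`-scaled initial conditions (linear in the
  input, so filter linearity holds to 1e−9); zero-phase uses `filtfilt`.
- The assembled 6×6 correlation matrix is positive definite by
  construction (HS features are regressions on peak features with
  independent residuals); a nearest-PD projection (eigenvalue clipping +
  diagonal rescale) guards user-supplied matrices.
- Keyframe ordering is enforced by explicit clamps (trough below both
  neighbours, heel-strike angle at least 2° below its peak), so the PCHIP
  interpolant is monotone on every segment and a threshold crossing always
  exists for a well-trained model.
- Equal consecutive samples do not extend a rising run (they end it, via
  the hysteresis margin); zero-length trials yield empty outputs; flat
  pressure channels yield a warning and no events; constant feature
  columns raise an undefined-correlation error naming the column.
- Correlation estimates on hierarchical data converge in the number of
  *subjects* (most feature variance is between-subject), so
  correlation-structure checks pool many subjects with few strides each.

## Known limitations

- Zero-noise detections land within 2 samples of ground truth at the
  nominal 0.3 Hz cadence; across 0.25–0.4 Hz a residual ±10–16 ms
  frequency-systematic remains, inherent to a single pooled regression
  compensating a fixed group delay against frequency-dependent descent
  slopes.
- Toe-off detection is deliberately late-biased for slow-swing strides
  (the ϖ* bound sits one SD below the mean toe-off angular velocity) and
  misses ~0.3–1% of cycles at default noise when a slow swing coincides
  with an early zero-recrossing of the thigh angle.
- The problem sizes used by the tests and the acceptance script (cohorts
  of 10–20 subjects, 30–50 strides per frequency) mirror the study design
  they emulate; all runs complete in seconds.
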