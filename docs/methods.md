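# Methods

This note documents the models and conventions implemented in
`matchfatigue`, the defaults chosen where the underlying experimental
protocol leaves the analysis open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Time-motion analysis (`tracking`)

Player court coordinates (nominally 30 Hz) are low-pass filtered with a
3rd-order Butterworth at 0.4 Hz.  Filtering is **zero-phase**
(forward–backward, `sosfiltfilt`): phase lag would bias step lengths, at
the cost of squaring the single-pass attenuation — a 5-Hz jitter component
is suppressed by ≈ (12.5³)² ≈ 1.5 × 10⁻⁷.  Endpoints are handled by odd
reflective padding of three filter lengths (`3·fs/fc` samples ≈ 7.5 s at
30 Hz); each 10-min period is filtered independently so rest intervals
never leak across period boundaries.  Uniformity of the timebase is
checked and the track resampled if timestamp jitter exceeds 1%.

Distance covered is the sum of Euclidean steps of the filtered track.
Speed comes from central finite differences of the filtered positions
(one-sided at segment ends) — the protocol does not define a speed
estimator, and this one is unbiased for the piecewise-linear motion that
matters here.  A sprint is a maximal contiguous run of samples with speed
strictly above the player's vVO2max; an optional minimum bout duration
(default 0 — every crossing counts) absorbs the ambiguity of whether very
short excursions were counted in the original protocol.

DC_MIN divides by an explicit, configurable denominator: the scheduled
10 min per period (default) or the analyzed effective time span.  The two
differ in published tables (1986.6 m at 103.2 m·min⁻¹ implies ≈ 19.25
effective minutes per half rather than 20); both modes are provided and
neither is asserted as canonical.

## Finishing-kick kinematics (`kicks`)

Axes: y horizontal toward the goal centre, z vertical up, x lateral
(right-handed).  Over the ten frames after foot contact (240 Hz, raw
unfiltered positions), the horizontal velocity components are OLS slopes
of x(t) and y(t); the vertical component is the linear term of a quadratic
fit of z(t) with the curvature **fixed at −g/2** (equivalently an OLS line
through z + ½·g·t²).  Fixing the curvature removes one degree of freedom
and demonstrably lowers the variance of the vertical-velocity estimate
relative to a free quadratic (tested by Monte Carlo).  Time is measured
from foot contact, so fitted slopes are release velocities directly.
"Peak speed per attempt" is the one regression-derived release speed —
with a single fitted derivative there is nothing else to take a peak over.

The goal-plane crossing solves the fitted y(t) = 10 m and evaluates the
fitted x and constrained z there.  Crossings below floor level or outside
the 3 × 2 m goal mouth are flagged, not rejected — every attempt that
crossed the line is scored.  Accuracy is the distance to the nearest point
of the closed 1 × 1 m target square (coordinate clamping); the target
centre height defaults to 1.0 m (the centre of the goal mouth), which the
protocol leaves unstated.

At the default 2-mm digitization noise, closed-form OLS prediction
variance puts the per-axis crossing error at ≈ 0.018 m SD over the 10-m
extrapolation, i.e. ≈ 0.014 m mean absolute error per coordinate and
≈ 0.022 m mean Euclidean error — the same scale as (slightly above) the
0.02 m goal-plane reconstruction error reported for the original
measurement chain, which measured the crossing directly rather than by
extrapolation.  Accuracy errors are no larger: the point-to-rectangle
distance is 1-Lipschitz in the crossing point.

## Neuromuscular assessment (`neuro`)

Force traces (1000 Hz) are zero-phase low-pass filtered (4th-order
Butterworth, 15 Hz).  The force plateau is located as the argmax of the
100-ms moving average over windows free of stimulation artifact (windows
overlapping stimulus → stimulus + 300 ms are masked); F_PEAK is that
maximal windowed mean.  This makes plateau detection deterministic; note
the twitch tail decays exponentially, so ≈ 0.3% of a large superimposed
twitch can outlast the 300-ms mask and perturb F_PEAK by a couple of
newtons at most.

Twitch amplitudes are peak force in (stimulus, stimulus + 300 ms] minus
the mean of the 50 ms immediately pre-stimulus — the same rule serves the
relaxed doublet (baseline ≈ 0 → TC) and the superimposed doublet (baseline
= voluntary force at stimulation → TS, with the baseline itself reported
as F_stim).  Voluntary activation uses the uncorrected formula when
F_stim ≥ 95% of F_PEAK (a declared convention for "on the plateau" — the
protocol says only "slightly before or after") and otherwise the
correction scaling TS by F_stim/F_PEAK.  Out-of-range VA values are
flagged, never silently clamped.  Two MVC attempts per session are reduced
by keeping the attempt with the higher F_PEAK (configurable to the mean).

EMG (2000 Hz) is zero-phase band-passed 20–500 Hz.  RMS is computed over
1 s centred on the force plateau; the M-wave is max − min in the 50 ms
after the relaxed stimulus.  An M-wave is flagged unreliable when its
amplitude is below 3 × the peak-to-peak excursion of an equal-length
pre-stimulus window — peak-to-peak rather than SD because the measurement
itself is a range statistic and the range of 50 ms of band-limited noise
already spans ~4–5 SD.

## Incremental-test physiology (`physio`)

Breath-by-breath VO2, VCO2 and HR are smoothed with a centred 5-breath
moving average (the original smoothing is unspecified; the kernel is
configurable) and linearly interpolated to 1 value per second.  VO2max is
the highest mean over the final 30 s of a stage; the criteria are
(1) final-two-stage range < 2.1 mL·kg⁻¹·min⁻¹, (2) max RER > 1.1,
(3) max HR > 90% of (220 − age) (the predicted-HRmax coefficients are
configurable), accepted when ≥ 2 are met.  vVO2max is the lowest stage
speed whose final-30-s mean reaches VO2max within 1.0 mL·kg⁻¹·min⁻¹ — a
declared operationalization of "the lowest speed at which VO2max was
reached".  Lactate and HR summaries are max / arithmetic mean over the
scope's samples, with between-period rests excluded by default.

## Statistics (`stats`)

Per variable, the paired comparison reports: moment means ± SD, mean and
SD (n−1) of the per-subject differences, paired *t* (df = n−1, two-sided
p), Cohen's *d* = (m₂ − m₁)/√((s₁² + s₂²)/2) with thresholds trivial ≤ 0.2
< small ≤ 0.5 < moderate ≤ 0.8 < large, SWC = 0.2 × between-subject SD
(pooled moment SD by default, baseline SD optionally), and the
magnitude-based chances that the true mean change lies above +SWC /
within ±SWC / below −SWC, taking the true change as distributed around the
observed mean with SE = SD_diff/√n.

The sampling distribution for the chances is the **normal approximation**
by default (this is the convention that reproduces the published 98%
negative chance for the MVC force change from its printed summary
statistics); a t-distribution mode (df = n−1) is available behind a flag.
Chances are mapped to the qualitative scale ≤1% *almost certainly not*,
1–5% *very unlikely*, 5–25% *unlikely*, 25–75% *possibly*, 75–95%
*likely*, 95–99% *very likely*, >99% *almost certain*; when both the
positive and the negative chance exceed 5% the verdict is *unclear*, as it
is when two categories tie for the maximum.  Display percentages are
rounded half-up to integers; full precision is kept internally.  The
normal CDF is evaluated via `erf`, which makes the positive/negative swap
under Δ → −Δ exact in floating point.

Under a true null (Δ = 0, n = 6) the long-run rate of *very likely* or
stronger directional verdicts is ≈ 6% (Monte Carlo) — small, but a
reminder that magnitude-based inference at this sample size is a
qualitative screen, not a hypothesis test.

## Synthetic data (`synthgame`)

The generators emulate the study conditions with exactly recoverable
truth:

* **Tracks** — piecewise-constant-speed locomotion bouts (stand / walk /
  jog / run / sprint at 0.3–5.0 m·s⁻¹, 2.5–5-s durations, Markov weights
  tuned to ≈ 103 m·min⁻¹ mean intensity and roughly one sprint per ~24 s)
  along a heading that turns smoothly (two sinusoids ≤ 0.05 Hz), so the
  true path has no spectral content the 0.4-Hz tracking filter would
  remove.  The second half runs at a configurable speed decrement (default
  6.6%, the scale of the published between-half distance drop).
  Positional noise is i.i.d. Gaussian, default 0.05 m — digitization-scale
  jitter, configurable because the original static-position error (0.14 m)
  does not pin down frame-to-frame noise.  True distance is the exact
  integral of the scheduled speed.
* **Kicks** — drag-free projectile flight (z quadratic under gravity, x, y
  linear) at 240 Hz with 2-mm Gaussian digitization noise.  Generator and
  estimator share the flight model deliberately: the recovery tests close
  the loop on the regression scheme, not on aerodynamics (drag robustness
  would be a separate stretch study).
* **MVC traces** — half-cosine ramp to a flat plateau; twitches are a
  peak-normalized difference of exponentials (τ_rise 15 ms, τ_decay 80 ms,
  doublet-like time-to-peak ≈ 70 ms), a shape chosen because its peak is
  analytically normalizable so truth amplitudes are exact.  The
  superimposed amplitude is constructed as TC × (1 − VA/100) (scaled by
  F_PEAK/F_stim off-plateau), making the VA formulas exactly invertible.
  Force noise default 2 N.
* **EMG** — band-limited Gaussian noise rescaled to the target RMS over
  the contraction window, a 0.02-mV resting floor elsewhere, and one
  Hann-windowed biphasic wave with exact peak-to-peak at the stimulus.
* **Breaths** — gamma-distributed inter-breath intervals (mean 2 s),
  stage targets approached with 20-s first-order kinetics, per-breath VO2
  noise 1.0 mL·kg⁻¹·min⁻¹ (representative of cart-processed
  breath-by-breath variability), linear RER and HR ramps.  The default
  stage profile plateaus at 50.6 mL·kg⁻¹·min⁻¹ with onset at 15 km·h⁻¹.
* **Cohorts** — paired tables with configured true mean change and SD of
  changes per variable.

What passing the recovery tests shows: the estimators invert the stated
measurement models at realistic noise levels (kick speed to < 1%, VA to
< 2 percentage points across 60–95%, DC to ≪ 1%, VO2max to ≈ 0.2
mL·kg⁻¹·min⁻¹ mean absolute error — with a ≈ +0.18 bias from selecting
the maximum over noisy stage means).  What it does not show: robustness to
un-modelled physics (ball drag and spin, gait mechanics, occlusion and
identity switches in tracking, electrode movement, VO2 slow-component
kinetics), none of which the generators attempt.

## End-to-end study replica (`study`)

`run_study` draws a cohort (default 10 players; 6 instrumented for twitch
interpolation, matching the published sample sizes), gives each player a
latent fatigue factor ~ N(1, 0.35²) that scales both the second-half
running decrement and the neuromuscular losses, and runs every pipeline
stage on generated raw signals in protocol order.  The planted coupling
makes the ΔDC–ΔF_PEAK correlation recoverable (≈ 0.8–0.9 under a strong
coupling, the published analysis's r = 0.83 scale).  The full default run
(40 min of tracking at 30 Hz × 10 players, 24 MVC traces, 90 kicks,
10 incremental tests) completes in a few seconds on one CPU; tests use a
480-s play duration for speed, stated here as the package's own choice of
test problem size.

## Known limitations

* No video, calibration or 3-D reconstruction: the pipeline starts at
  reconstructed coordinates.
* The simulated cohort reproduces the *structure* and *direction* of the
  published group results, not their exact values, which depend on the
  unavailable raw athlete data.
* Magnitude-based inference is implemented as specified by its users, with
  its known caveats; a Bayesian reinterpretation is out of scope.
* The published effect sizes for most table rows are not recoverable from
  the printed summary statistics (they were evidently computed on raw
  data); the package makes no attempt to match them.
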