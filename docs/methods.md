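# Methods

## The phenomenon and the measurement

When a visual stimulus captures attention, the two eyes transiently
rotate toward each other: a small event-locked convergence beginning
roughly 300 ms after stimulus onset, peaking near 450 ms, followed by a
sustained component through the 600–1250 ms range.  In an oddball task
this *cognitive vergence* response is larger for rare, behaviourally
relevant targets than for frequent distractors, which makes the
target/distractor contrast a candidate marker of cognitive processing.
This package implements the full measurement chain from raw binocular
gaze samples to that contrast.

## From gaze pixels to vergence angle

Each tracker sample gives the on-screen gaze point of the left and
right eye in pixels.  With the eyes assumed at (±ipd/2, 0) on the line
normal to the screen centre, the horizontal gaze direction (azimuth) of
one eye is

    azimuth = atan( (x_mm − eye_offset) / viewing_distance ),

where `x_mm = (gaze_x − screen_w_px/2) · screen_w_mm/screen_w_px` and
`eye_offset` is −ipd/2 (left) or +ipd/2 (right).  The vergence angle is

    γ = azimuth_left − azimuth_right   (degrees),

measured in a common frame with rightward positive, so symmetric
fixation at distance d gives the closed form γ = 2·atan(ipd/2d), and γ
grows with convergence.  Vertical coordinates are carried through I/O
but ignored here: the analysed quantity is the single horizontal
vergence angle.  Head movement (the task is run without a chin rest) is
treated as noise, not modelled.

Geometry defaults: viewing distance 500 mm; screen 1366 × 768 px on a
15.6″ 16:9 panel (345.2 × 194.2 mm); interocular distance 63 mm, the
adult population mean, used because individual IPDs are generally not
recorded.  All are overridable in `GeometryConfig`.

## Preprocessing

* **Epoching.**  Trials are cut to a window of (−200, +2000) ms around
  stimulus onset.  The post-onset 2000 ms covers the stimulus epoch and
  every analysis window; the 200 ms pre-stimulus span supports baseline
  inspection.  The uniform grid covers `[start, end)` at the tracker's
  nominal rate (66 points at 30 Hz); window membership tests use a
  1 µs tolerance so that exact float grid points are never lost.
* **Validity.**  A sample is invalid when *either* eye's validity code
  is non-zero, since vergence needs both eyes.  Trials with ≥ 15
  invalid samples inside the epoch window are excluded; the boundary is
  exact (14 retains, 15 discards).  Webcam-style streams carry validity
  0 everywhere, so they are never excluded by this rule.
* **Interpolation.**  Invalid samples are removed, then each coordinate
  channel is linearly interpolated onto the grid — the simplest scheme
  consistent with evenly spaced output.  Grid points outside the span
  of valid timestamps take the nearest valid value (clamped ends, no
  extrapolation slope).  Fewer than two valid samples excludes the
  trial with reason "insufficient data".  Every exclusion is recorded
  in the QC table with its reason; retained + excluded always equals
  the number of events.

## The relative vergence modulation V(t)

Absolute vergence offsets differ across subjects and trackers, so each
trial is reduced to its normalised modulation

    V(t) = (γ(t) − γ₀) / max_w |γ(t) − γ₀| ,

with γ₀ the single interpolated sample at the onset grid point (not a
pre-stimulus average) and the maximum taken over the normalisation
window w, default (0, 2000) ms — the stimulus epoch, chosen so that
every response window (which extend to 1250 ms) lies inside it, and
exposed as configuration because the choice between "stimulus epoch
only" and "including pre-stimulus samples" is genuinely open.
Normalisation is per trial; averaging within condition happens
afterwards.  A perfectly flat trial would divide by zero; it is instead
assigned V ≡ 0 and kept in the averages.  On every non-flat trial
V(onset) = 0 and max |V| over w is exactly 1.

An important consequence of the normalisation: V is invariant to any
affine rescaling γ → aγ + b with a > 0.  Response *amplitude* is
deliberately removed; what remains is response *shape* and, in noisy
data, the signal-to-noise ratio — a trial whose evoked response is
small relative to tracker noise has its normaliser set by noise
excursions and its windowed V means shrunk toward 0.  This is exactly
the mechanism by which the target/distractor contrast survives
normalisation (targets have the higher SNR), and it is why, in a
noise-free simulation with shape-proportional kernels, the modulation
index is exactly 0: the zero-noise positive-contrast check therefore
uses a response present only on target trials.

## Windowed statistics

* Window means over closed intervals: initial (0, 200) ms, peak
  (400, 433) ms, delay (600, 1250) ms.  At 30 Hz the 33-ms peak window
  can contain a single grid point; that is legitimate (the window width
  equals one sampling interval) and never an error.
* Modulation index: `mi = (T − D)/(T + D)` with T (D) the mean over
  target (distractor) trials of the trial-wise V mean in (300, 600) ms.
  mi is scale-invariant and unbounded as T + D → 0; |mi| > 1 is an
  expected outcome, not an error.  |T + D| < 1e-12 yields NaN,
  excluded from group means with a logged count.
* Response slope: OLS slope of a curve against time, reported per mean
  curve both on V(t) (1/ms) and on the recovered unnormalised
  γ − γ₀ (deg/ms) over (0, 1250) ms.
* Two-tailed t-tests: Welch by default for unpaired contrasts (robust
  to unequal variances across conditions and trackers); pooled Student
  t available by configuration; paired contrasts use the one-sample t
  on differences.  Zero-variance equal-mean degenerate input returns
  (t, p) = (0, 1).  Group contrasts are run at both the trial level and
  the subject level and reported side by side, since both are
  defensible units of analysis; no multiple-testing correction is
  applied.  Cross-tracker agreement is summarised as a 2×2 table of
  per-subject mi signs (zero counted as non-positive) with per-tracker
  positive fractions.

## The synthetic cohort

The simulator generates the data the analysis assumes, so the whole
pipeline is testable without any recordings:

* **Design.**  28 subjects; 100 trials per session on a fixed
  2000 ms mask + 2000 ms stimulus cadence; exactly 20 target trials per
  session (fixed proportion, not Bernoulli draws) placed by seeded
  shuffle; 11-character random mixed-case strings, re-drawn on the rare
  chance they spell a blacklisted English word.
* **Response model.**  The event-locked vergence increment is a
  parametric kernel: zero before a 300 ms latency, raised-cosine rise
  to the peak amplitude at 450 ms, exponential relaxation (time
  constant 80 ms) onto a sustained plateau held through 1250 ms, then
  the same relaxation back to zero.  The shape is an invented smooth
  stand-in — only its landmarks (latency, peak time, sustained span)
  are constrained by the phenomenon; the parameters, not the shape,
  carry the science.  Default amplitudes: target peak 0.3°, distractor
  0.05°, sustained component 40% of peak.  True effect sizes in degrees
  are not established (published curves are normalised), so these are
  plausible placeholders, configurable everywhere.
* **Heterogeneity.**  Each subject draws a log-normal amplitude factor
  (σ = 0.5) applied to both kernels — between-subject response
  amplitudes in oculomotor work commonly spread by a factor of a few,
  and a coefficient of variation around 50% encodes that.
* **Tracker front-ends.**  The subject fixates the screen centre; γ(t)
  is inverted through the viewing geometry (fixation depth d with
  γ = 2 atan(ipd/2d), lines of sight intersected with the screen
  plane) into per-eye pixel coordinates.  Per-eye white Gaussian noise
  is added, expressed in degrees and converted to pixels at the viewing
  distance: 0.05° for the infrared-like tracker ("ET") and 0.15° for
  the webcam-like tracker ("WC"), reflecting the precision gap between
  research-grade pupil trackers (sample-to-sample RMS a few hundredths
  of a degree) and visible-light iris tracking.  ET additionally drops
  each sample with probability 0.2 (validity code 4, coordinates
  blanked); under the 15-of-66 exclusion rule this discards
  P(Binom(66, 0.2) ≥ 15) ≈ 34% of trials, emulating the roughly
  one-third exclusion rates seen with remote pupil trackers in elderly
  populations.  WC has no dropouts.
* **What it does not emulate.**  Real tracker noise is temporally
  correlated (drift, head motion) and dropouts come in blink-length
  bursts, not per-sample coin flips; there are no pupil-size dynamics,
  no saccades or fixational eye movements, no vertical-gaze structure,
  and no gaze-estimation bias fields.  Passing tests on this generator
  therefore validates the *pipeline arithmetic and its contracts* —
  geometry inversion, exclusion accounting, normalisation, window
  statistics — not robustness to every artefact of real recordings.

## Verification problem sizes

The consistency checks run at desk scale: parameter recovery uses ten
28-subject single-tracker cohorts (seeds 0–9), requiring a positive
mean subject-level mi in ≥ 9/10 seeds and Spearman ρ > 0.7 between true
amplitude factors and estimated T in ≥ 8/10; the zero-noise contrast
runs 6-subject cohorts; the normalisation contract is property-checked
on > 1000 random trials; windowed statistics are verified against
plain-loop brute-force recomputation on 100 random instances at 1e-12.

## Known limitations

* The amplitude-removal property of V(t) means group mi values depend
  on the noise level as much as on the underlying response sizes;
  comparisons across trackers with different noise are qualitative.
* γ₀ is a single sample, so onset noise propagates into the whole
  trial's V(t); a pre-stimulus baseline average would be more stable
  but is a different estimator, not the one implemented.
* The geometry assumes a head fixed on the screen-centre normal at a
  known distance; real seating error biases absolute γ but largely
  cancels in V(t).
* Exclusion thresholds and windows are calendar-fixed defaults; no
  data-driven artifact detection (blinks, saccades) is attempted.
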