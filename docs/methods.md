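# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic data can and cannot certify.

## The measurement chain

A thin capacitive strain sensor (an elastic dielectric film strainable in
one direction) is attached between two points on the medial foot; its
capacitance varies linearly with the extension of the strainable section.
The acquisition chain samples capacitance at 200 Hz with a quantization of
0.13 pF. A single-camera marker system tracks the navicular and two
reference markers at 114 Hz. A sync box stamps the current strain-sample
number into the camera's field of view on 16 LEDs in binary-reflected gray
code (plus two always-on fiducial LEDs), so every frame can be mapped to a
strain-sample index; marker-derived signals are then interpolated onto the
200 Hz timeline and the two streams compared step by step.

## Synthetic trials

`gait_sim` generates walking trials with exact ground truth. Design
choices, with defaults:

- **Stride template.** Navicular height (NH) per stride is piecewise
  raised-cosine and C¹ everywhere: descent from the HS baseline to a
  minimum of depth `d_k` at `nhl_fraction_of_stance` (default 0.40) of
  stance, recovery to baseline at toe off, and a shallow raised-cosine
  **swing dip** (default 1.0 mm) between toe off and the next HS. The
  swing dip is the template's representation of the characteristic drop in
  sensor strain just before the stance rise; it is what makes the
  sensor-side heel-strike rules (minimum search) well-posed. Real NH
  waveforms are not raised-cosine, but the template shares the features
  the event rules key on: a plateau, one descent, one minimum, one
  recovery, and a pre-HS strain drop.
- **Per-step truth.** `d_k ~ Normal(nd_mean_mm, nd_sd_mm)` truncated at 0,
  default 5.0 ± 0.8 mm (healthy adults average about 5.3 ± 1.8 mm; the
  tighter SD reflects a single subject's stride-to-stride variability
  rather than a population). Cadence default 0.9 strides/s (~5 km/h
  preferred treadmill speed), stance fraction 0.62.
- **Event times are snapped to the 200 Hz grid**, so a noiseless sampled
  minimum equals `baseline − d_k` exactly and truth comparisons are free
  of sub-sample ambiguity.
- **Transduction.** `ℓ = geometry_gain · (baseline − NH) + crosstalk`;
  capacitance `C = intercept + ℓ/slope` plus Gaussian noise, rounded to
  the 0.13 pF grid. Defaults: rest length 40 mm (so the 20 mm bench sweep
  reaches exactly the 50% strain limit), slope 0.5 mm/pF, intercept
  100 pF. Elongation beyond 50% of rest length raises an over-strain
  error — the film would be damaged — and is never silently clipped.
- **Crosstalk** models frontal-plane foot motion the single camera cannot
  see: one smooth raised-cosine bump per stride, zero at each HS, with
  per-stride amplitude `~Normal(crosstalk_mm, crosstalk_mm/2)` truncated
  at 0. The stride-to-stride amplitude variation is what decorrelates the
  per-step sensor and camera drops; a constant bump would only shift them.
- **Markers.** Pixel y points down (image convention), scale 0.2 mm/px;
  reference markers are rigid, the navicular marker encodes NH on y.
  Frames carry `gray(round(t·200) mod 2¹⁶)` and both fiducial bits on.
  Noise is additive Gaussian on capacitance and on pixels; real sensor
  noise (drift, temperature, triboelectric artifacts) and marker-tracking
  failures are not modeled, so passing tests certify the algorithms, not
  robustness to every field artifact.
- The timer-circuit stage (capacitance → timer frequency) is modeled only
  as the optional generic pair `f = k/(C + C_parasitic)`; the default
  pipeline works on capacitance directly.

## Calibration

Extension is regressed on capacitance (slope in mm/pF). R² is reported for
bench sweeps; a two-point everyday calibration carries **no** R² rather
than a vacuous 1.0. Slope drift between calibrations is reported as
absolute percent; a drift of *p* percent scales every measured drop by the
same factor, so the worst-case drop error is `ND · p/100` (0.4 mm for 4%
on a 10 mm drop). Nonlinear calibration is deliberately out of scope: on
collinear-to-within-noise sweeps the linear fit's inaccuracy is negligible
(R² ≈ 0.9999 on simulated sweeps with one quantum of noise).

## Synchronization

Gray words are stored LSB-first (bit *i* of the integer word = LED *i*;
the physical ordering is a file-format convention, not a claim about the
hardware). Decoding unwraps the 16-bit counter by nearest continuation of
the expected increment (200/114 ≈ 1.754 samples/frame); a decoded index
jumping more than 3× the expected per-frame increment from the
continuation is invalidated as a glitch without disturbing neighbors;
frames with fiducial bits off are invalid; fewer than two valid frames is
a hard error. Upsampling is **linear** interpolation against decoded
sample indices — monotone and ringing-free at the sharp HS feature; no
extrapolation (out-of-span samples are NaN). On noiseless trials the
camera→strain transfer of an event time is exact to half a strain sample
(2.5 ms), which is the information limit of integer sample stamps.

## Placement analysis

The local foot frame is a rigid transform (rotation + translation, no
scaling): calcaneus marker B ↦ (0,0), front-foot marker A ↦ (‖A−B‖, 0).
A marker's displacement cloud is its local position over frames, centered;
its major axis is the principal eigenvector of the 2×2 covariance, with
the angle folded into [0°, 180°). Clouds with a major/minor eigenvalue
ratio under 1.05 are refused as isotropic rather than yielding a noise
direction. The attachment score for a candidate upper site is
`|cos(angle between its major axis and the sensor line)|` — 0 (motion
perpendicular to the sensor) is ideal because that motion adds no spurious
strain. Both this score and the raw between-axes angle are exposed; they
are different readings of "optimal" and the package does not collapse
them.

## Event detection

Steps are segmented from the signal's own periodicity: autocorrelation
period estimate (peak in 0.4–2.5 s lags; normalized peak below 0.2 means
no gait and is an error), peak picking at ≥ 0.7 periods spacing, and
boundaries midway between consecutive elongation peaks — each window then
contains one full HS→NHL→TO sequence for any plausible stance timing.

- Camera rules: NHL = within-step NH minimum; HS = last pre-NHL sample at
  the plateau (maximum) level, i.e. the descent onset; TO = first
  post-NHL return to within 5% of the step's NH range of the HS level.
  Steps with NH range < 0.1 mm are skipped with a warning, never
  fabricated.
- Sensor rules (anchored): HS = elongation minimum within ±10% of the
  **step duration in samples** around the camera HS (duration is the only
  reading of "step length" that defines a temporal window); NHL = maximal
  elongation in the step.
- Standalone (in-shoe) rules: steps from segmentation alone; NHL = step
  elongation maximum, HS = minimum preceding it (the bottom of the
  pre-rise strain drop). Output is flagged `standalone` because no
  reference stream vouches for these events.
- Ties break to the earliest index everywhere; results are deterministic.

Both event streams are detected on lightly smoothed series (zero-phase
35 ms boxcar): short against the ~120 ms descent, so waveform distortion
is ~0.015 mm, while suppressing the argmin/argmax bias that sample-level
noise would otherwise add to extremum-based drop estimates.

## Statistics

Session mean with t-based 95% CI; Pearson r with the two-sided t-transform
p-value; mean difference (camera − sensor) with t-based CI — the slope-1
line through the ND scatter intercepts the y-axis at this value.
Test–retest change uses Welch's unpaired t-test: the two sessions contain
different numbers of steps, so a paired test is impossible, and Welch
drops the equal-variance assumption. All p-values are two-sided at the 5%
level. Degenerate zero-variance sessions take the by-definition limits
(p = 1 for no change, p = 0 for a shift).

## Problem sizes

The test suite and the acceptance script run on simulated sessions of
20–88 steps (one 3×500-step sweep for the crosstalk monotonicity check) —
a deliberate match to a real single-subject treadmill session, which also
keeps the whole suite around ten seconds. Statistical calibration checks
use 300–2000 replicates, enough to pin a 5% rejection rate to ±1.5 points.

## Known limitations

- The simulator's gait is strictly periodic walking with i.i.d. step
  depths; no drift in cadence, no turning, no running, no missing frames.
- Marker and capacitance noise are white and Gaussian; real noise is not.
- The camera model is a fixed-scale orthographic plane; no lens
  distortion or out-of-plane foot motion on the camera side.
- Standalone in-shoe events have no reference stream; their accuracy is
  certified only against the simulator's truth, which shares its waveform
  family with the detector's assumptions.
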