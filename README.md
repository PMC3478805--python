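# navdrop

Measurement pipeline for the **dynamic navicular drop** — the sagittal
lowering of the navicular bone from heel strike (HS) to its lowest point
(NHL) during the stance phase of gait, a standard clinical measure of
midfoot pronation — estimated **in-shoe** with a thin capacitive strain
sensor (a dielectric electroactive polymer film, "PBS") worn on the medial
side of the foot, and validated against a marker-based video reference
("MVSA") that tracks reflective skin markers on the bare foot.

The package is aimed at gait researchers and biomedical engineers who want
to work with this measurement chain without the hardware: a synthetic gait
and sensor simulator with exact ground truth stands in for treadmill
recordings, and every processing stage is an importable, tested function.

## What it computes

Per step *k* the navicular drop is

```
ND_k = NH(HS_k) − NH(NHL_k)          (camera stream, navicular height NH in mm)
ND_k = ℓ(NHL_k) − ℓ(HS_k)            (sensor stream, calibrated elongation ℓ in mm)
```

with the sensor calibrated by an ordinary least-squares line
`ℓ = a·C + b` (slope *a* in mm/pF) fitted to a bench sweep, or a two-point
everyday calibration. The two 200 Hz / 114 Hz streams are aligned sample
by sample through a 16-bit **gray-coded** sample counter displayed to the
camera by a sync box, and marker signals are upsampled onto the strain
timeline by linear interpolation against the decoded sample indices.
Sessions are summarized as `mean ± t₀.₉₇₅,ₙ₋₁·SD/√n` (95% CI); agreement
between streams uses the Pearson product–moment *r* (two-sided *p* via
`t = r√((n−2)/(1−r²))`) and the mean difference; test–retest change uses a
Welch two-sample t-test.

Modules: `gait_sim` (synthetic trials + truth), `calibration`, `sync`
(gray codes, decode, upsample), `placement` (local foot frame, marker
displacement clouds, major axes, attachment scoring), `events` (step
segmentation and HS/NHL/TO rules), `stats`, `io` + `cli`.

## Worked example

```python
import navdrop as nd

# simulate a 60-step treadmill walk with a true mean drop of 5.0 mm
profile = nd.GaitProfile(n_steps=60, nd_mean_mm=5.0, nd_sd_mm=0.8, seed=42,
                         noise_cap_pf=0.13, noise_nh_mm=0.1)
trial = nd.generate_trial(profile)

# calibrate the sensor from a simulated bench sweep and analyze
model = nd.fit_calibration(nd.simulate_calibration_sweep(trial.sensor))
report = nd.analyze_validate(trial.strain, trial.markers, model)
```

prints (via the summaries in `report`):

```
true mean ND : 5.05 mm
MVSA mean ND : 5.10 mm (95%CI: 4.94;5.27), n=60
PBS  mean ND : 5.05 mm (95%CI: 4.89;5.21), n=60
mean diff    : 0.05 mm, Pearson r = 0.991 (p = 1.49e-52)
```

Both streams recover the generator's realized mean drop to well under
0.1 mm despite one quantization step (0.13 pF) of capacitance noise and
half a pixel of marker jitter; the per-step correlation is near 1 because
this simulated sensor has no frontal-plane crosstalk (set
`SensorModel(crosstalk_mm=...)` to make the scatter realistic).

The same chain is available from the shell:

```
navdrop simulate --out-dir sim --seed 42
navdrop calibrate --sweep sweep.csv --out cal.json
navdrop analyze --strain sim/strain.csv --markers sim/markers.csv \
                --calibration sim/calibration.json --out report.json
navdrop report report.json
```

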