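# Methods

## Signal model and processing pipeline

A light-based motor-mapping trial records, per instrumented limb, three
accelerometer voltage channels and one EEG channel at 5 kHz, spanning a
0.5-s pre-stimulus baseline and 1 s after a 5-ms light pulse. The
analysis assumes that at rest the accelerometer reads only gravity, so
the baseline-mean vector **ḡ** fixes the sensor's orientation and
sensitivity.

**Calibration.** Acceleration in g is voltage divided by the
manufacturer sensitivity (default 0.22 V/g). Note the division: a
sensitivity in V/g converts volts to g only by division.

**Gravity frame.** The estimated frame is the pair (R, s) with
s = 1/‖**ḡ**‖ and R the *minimal* (shortest-arc) rotation taking
**ḡ**/‖**ḡ**‖ to (0, 0, −1). The scale absorbs small calibration error
so static gravity is exactly −1 g. Shortest-arc is the only
deterministic choice: aligning a single vector leaves rotation about the
vertical free, and the minimal rotation perturbs the sensor's X/Y axes
least. Consequently horizontal-plane angles are comparable across
trials and sessions only under consistent sensor mounting — an
assumption of the experimental protocol, not something analysis can
restore. A baseline mean below 0.1 g is rejected as a disconnected
sensor; antiparallel gravity (upside-down sensor) rotates π about a
fixed perpendicular axis.

**Movement detection.** The movement magnitude is the gravity-subtracted
norm m(t) = ‖**A**′(t) − (0, 0, −1)‖, so a still limb gives m ≈ 0 and
peak amplitudes and movement vectors measure evoked movement rather than
the static 1 g. The detection threshold is

    threshold = mean(m over baseline) + k · σ_b,   k = 5 (default)

where σ_b is the **pooled per-axis SD** of the baseline acceleration
about its mean. The pooled per-axis SD, rather than the SD of m itself,
is the deliberate reading of the five-SD rule: m is a folded (chi-like)
quantity whose own μ+5σ level is crossed by pure noise with probability
≈ 2·10⁻⁵ per sample — about 5% of 0.5-s no-movement windows at 5 kHz,
which would contaminate every map with false-positive pixels. (Temporal
smoothing of the noise does not rescue the magnitude-SD variant: at 5-σ
levels the level-crossing rate of a band-limited process nearly equals
the discrete white-noise rate.) Against the per-axis noise scale the
Gaussian 5-σ intuition holds and the measured false-positive rate on
1000 simulated no-movement trials is below 2% (typically zero). Both
variants agree on the published examples (baseline σ ≈ 0.01 g, μ ≈ 0,
threshold 0.05 g).

Onset is the first sample exceeding threshold inside the response window
(default 0–0.5 s post-stimulus); peak is the maximum of m there. The
movement vector integrates **A**′ − (0,0,−1) per axis (trapezoid) over
30 ms starting at the detected onset; anchoring at the stimulus instead
is available (`integration_anchor="stimulus"`). Angles use the
two-argument arctangent, in degrees: horizontal ∈ (−180°, 180°] with 0°
anterior, elevation ∈ [−90°, 90°] with +90° dorsal.

**EEG.** The evoked deflection is the mean rectified baseline-subtracted
amplifier output over the 70 ms after the pulse, divided by the window
and by the amplifier gain (default 1000×), reported electrode-referred.
Rectification prevents mixed-polarity deflections from cancelling; a
signed mode exists (`rectified=False`). No filtering or detrending is
applied.

**Maps.** Motor and direction maps are masked to the active pixels (the
five-SD criterion); EEG maps keep every stimulated site — sites that
depolarize without moving the limb are precisely what the EEG map is
for — and are smoothed by a 3×3 neighbourhood mean (self included;
borders and unstimulated neighbours average over the available cells,
which keeps constant maps fixed and output bounded by input extrema).

**Map statistics.** Area = active pixels × spacing². Mean motor output
= mean peak acceleration over active pixels. The centre of gravity is
computed two ways: `quadrant_balance` (default) finds, per axis, the
coordinate where the cumulative amplitude — each pixel's amplitude
spread uniformly over its 300-µm extent — reaches half the total, so the
amplitude mass is equal on both sides of each axis through the COG (the
closest well-defined discrete analogue of an equal-quadrants balance
point; when the half-mass point falls exactly in a zero-mass gap the
midpoint of the gap is returned); `weighted_mean` is the amplitude-
weighted mean of pixel centres. Cross-session comparison reports
per-session statistics plus pairwise COG displacement, active-pixel
Jaccard overlap, and mean-output ratios.

## Synthetic sessions

The simulator emulates the structure the pipeline must invert, one seed
driving everything:

| parameter | default | meaning |
|---|---|---|
| grid | 18 × 23, 0.3 mm, bregma at (8, 3) | stimulation raster (414 sites, stimulated once each in seeded random order) |
| sample_rate_hz | 5000 | acquisition rate |
| baseline_s / post_s | 0.5 / 1.0 | recording spans around the pulse |
| sensor_tilt_deg | (25, −15, 40) | sensor mounting orientation (XYZ Euler) |
| noise_sd_g | 0.01 | white Gaussian sensor noise per axis |
| respiration | 0.005 g at 2 Hz | breathing-locked sway along a fixed oblique direction, random phase per trial |
| motor field | Gaussian, centre (1.65, 0.735) mm, σ 0.45 mm, peak 5 g | evoked-amplitude field over the map plane |
| detection_floor_g | 0.5 | field amplitude below which no movement is injected |
| movement template | latency 18 ms, 50-ms half-sine-windowed damped oscillation (30-Hz carrier, 10-ms decay), unit peak | evoked transient shape |
| direction | anterior, 20° elevation | injected movement direction (per-pixel override available) |
| EEG field | Gaussian, same centre, σ 1.0 mm, peak 200 µV | depolarization amplitude field (broader than motor) |
| eeg_noise_uV / eeg_tau_s | 10 / 0.015 | EEG background and alpha-function transient time constant |

The motor-field defaults place roughly 32 sites (≈ 2.9 mm²) above the
0.5-g floor with amplitudes spanning 0.5–5 g, centred 1.65 mm lateral
and 0.735 mm anterior of bregma — the canonical forelimb-map scale. The
respiration amplitude is an invented but plausible magnitude (its role
is to justify the five-SD rule, which must ignore it). Laser power
scales both fields linearly about a 1-mW reference; no light-transport
model is implied.

Injected movement directions are defined in the gravity frame the
analysis reconstructs (sensor trace = R_alignᵀ · gravity-frame signal
with R_align the exact shortest-arc rotation of the tilted gravity).
This encodes the consistent-mounting assumption; directions specified in
an arbitrary world frame would differ from any recoverable direction by
the mounting yaw, which no single-vector alignment can recover.

What the simulator does **not** emulate — and what passing recovery
tests therefore do not certify on real data: non-stationary anesthesia
depth, movement-waveform variability and multi-phasic twitches,
EEG spectral content and spontaneous slow oscillations, photoelectric
artifacts, sensor-cable resonances, and bilateral/ipsilateral responses
at high power (representable via per-limb fields, but not defaulted).

## Numerical choices

- Baseline statistics use the full pre-stimulus span; SDs use ddof = 1.
- Detected onset is the first *strict* threshold exceedance; with zero
  noise and a zero-rise-time transient this is exactly one sample after
  the injected onset. Threshold-crossing delay on the default (smooth)
  template is ~0.5–1 ms at 2 g — detected latencies read ≈ 18.8 ms for
  an 18-ms injected latency.
- Integrals (movement vector, EEG deflection) are trapezoidal on the
  sample grid; windows are closed intervals in time.
- The session container round-trips floats at ≥ 9 significant digits
  (`%.12g`); identical seed + config reproduces every output file byte
  for byte.
- Map TSVs mark inactive pixels with the literal token `NA`; geometry
  and units travel in a YAML sidecar.

## Test problem sizes

Session-level tests and recovery checks run the full 18 × 23 grid with
shortened traces (0.3-s baseline, 0.5-s post-stimulus, 0.4-s response
window); single-trial checks use the full protocol spans. These sizes
exercise every code path while keeping the suite fast; the statistics
they probe (detection rates, COG/direction recovery) are insensitive to
the trailing, movement-free portion of the post-stimulus span.

## Known limitations

- Horizontal angles are only as comparable as the sensor mounting is
  consistent (inherent to gravity-only alignment).
- The quadrant-balance COG is a per-axis construction; a true
  equal-mass-in-all-four-quadrants point need not exist on a discrete
  map, and the two COG methods differ on asymmetric maps by design.
- The EEG quantification is a single-channel windowed mean: no artifact
  rejection, source localization, or spectral analysis.
- Digit/wrist movements are below the sensitivity of a wrist-mounted
  accelerometer and are not differentiated from proximal limb movement.
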