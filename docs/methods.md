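# Methods

This note documents the models, algorithms and numerical choices behind
`ppgox`, in the order data flows through the package.

## Signal model and calibration

A reflective PPG channel is modelled as

    x(t) = DC(t) + A(t) · p(φ(t)) + ε(t)

where `DC(t)` is a large slowly varying baseline, `A(t)` the pulsatile (AC)
amplitude, `p` a periodic beat waveform with phase `φ(t) = (HR/60)·t`, and
`ε` white sensor noise. The ratio of ratios

    R = (AC_red / DC_red) / (AC_ir / DC_ir)

is scale-free in each channel and maps to saturation through the empirical
linear calibration `SpO₂ = 104 − 17 R` (a typical manufacturer single-segment
calibration; at R = 0.41, SpO₂ ≈ 97%). Outputs above 100% are arithmetically
possible and are reported as-is by default; a `clip` option restricts to
[0, 100]. The calibration is deliberately not fitted per subject or device —
site comparison, not absolute accuracy, is the analysis target.

## SpO₂ extraction chain

1. **AC isolation** — 4th-order Butterworth band-pass, 1–30 Hz, applied
   forward–backward (`sosfiltfilt`, reflective padding) for zero phase.
   Records must exceed roughly three filter transients (~1 s at 100 Hz);
   shorter input is an error. If the sampling rate cannot represent the
   30 Hz edge, the edge is reduced to 0.45·fs with a warning.
2. **Extrema** — `scipy.signal.find_peaks` with a minimum topographic
   prominence: 150 ADC counts (infrared) and 30 (red) by default. These are
   sensor-scale-dependent and fully configurable; troughs are peaks of the
   negated signal.
3. **AC envelope** — peak values and trough values are each linearly
   interpolated over the full time grid (end-value hold beyond the outermost
   extremum); the AC amplitude is `|peak_env| + |trough_env|`, i.e. the
   running peak-to-peak for a zero-mean AC signal. Linear interpolation was
   chosen over splines: it cannot overshoot between beats and its error is
   easy to bound against analytic envelopes.
4. **DC baseline** — 2nd-order Butterworth low-pass at 0.01 Hz, zero-phase.
   Order 2 (not 4) keeps the filter transient small relative to a ~435 s
   record. Records shorter than 60 s fall back to the record mean.
5. **R and SpO₂** — pointwise ratio of ratios and linear calibration.
   Samples with non-positive denominators are masked; mask gaps shorter
   than 2 s are linearly interpolated, longer gaps stay missing.
6. **Smoothing** — a 3 s centered moving average (odd sample count) is
   stored alongside the raw trace and used only for event/trough detection;
   all averages (resting SpO₂) use the unsmoothed trace.

Heart rate is 60 / median inter-peak interval of the infrared peaks; the
median is robust to occasional missed or doubled beats. For cohort
correlations the ear infrared channel is used.

A structural property worth noting: both wavelengths share the same beat
waveform shape, so any linear-filter attenuation of the waveform (e.g. the
1 Hz high-pass edge acting on a ~1.1 Hz fundamental) cancels exactly in R.
This is why the chain recovers injected SpO₂ to within ~0.1% noiselessly
even though the filtered peak-to-peak amplitude itself is attenuated.

## Breath-hold segmentation and delay estimation

The button channel is run-length encoded; high runs separated by gaps
< 0.2 s are merged (dropout debounce), runs shorter than 2 s discarded
(bounce/spike debounce), and an unterminated final run is dropped with a
warning. Press = exhale start; release = hold end = reference time of
minimal alveolar oxygen.

The per-site delay is the time from release to the **first** trough of the
smoothed SpO₂ trace with prominence ≥ 1.0 percentage point, searched in
`[release − 1 s, release + 45 s]`. Prominence is evaluated on the full
series so a dip's depth is judged against the surrounding baseline rather
than a window edge; the 1 s lead tolerates smoothing/noise jitter when a dip
is centered exactly at the release. Ties between equal-depth minima break to
the earliest. Holds with no qualifying trough are excluded from the mean and
logged; a site with no qualifying troughs at all is an error for that
subject. Per subject: mean delay and range (max − min) over the holds per
site, and relative delay = finger mean − ear mean, positive when the ear
leads.

## Cohort statistics

* Resting SpO₂ per site: mean of the unsmoothed trace over the 60 s before
  the first button press.
* Agreement: RMS and mean of the per-subject ear − finger difference
  (positive mean = higher saturation in the ear), and the fraction of
  subjects where both sites agree on membership of the closed healthy range
  [94, 100]% (two out-of-range sites also agree).
* Amplitudes: per subject/site, the mean infrared AC-amplitude envelope over
  the same resting window, normalized by the cohort maximum (max = 1.0);
  the finger/ear ratio is computed before normalization and is scale-free.
* Sex comparison of delays: Welch unpaired t-test by default. A paired test
  is available for completeness but is not the default because the two sex
  groups have no natural pairing.
* Correlations: Pearson r with two-sided p for age ↔ relative delay and
  heart rate ↔ ear/finger absolute delay.

Statistics whose sample-size preconditions fail (single-subject cohorts,
zero-variance groups) are reported as NaN with a logged warning rather than
failing the cohort.

## Synthetic cohort generator

The generator exists so that every stage above can be validated by parameter
recovery. Defaults describe a healthy young adult cohort performing the
guided protocol: 14 subjects, alternating F/M (balanced), ages U[19, 38] y,
heart rate U[55, 85] beats/min, resting SpO₂ U[95.5, 98.5]%, protocol
120 s rest + 3 × (5 s exhale + 20 s hold) + 60 s inter-hold rest + 120 s
rest = 435 s, sampling rate 100 Hz.

Per site: infrared AC half-amplitude U[200, 450] counts (ear), finger =
2.35 × ear; DC level 50 000 counts (red DC at 0.6 × infrared); transit
delays drawn per sex from normal distributions (ear ≈ 4.3 ± 2 s both sexes;
finger 14.0 ± 4.25 s F, 19.5 ± 6.28 s M) clipped to the plausible ranges
[0.97, 7.31] s and [8.52, 28.14] s; desaturation depth U[4, 8]% with time
constant U[4, 8] s; respiration 0.2–0.3 Hz with 10% amplitude modulation;
noise SD 5 counts; drift 200 counts with a 300 s period. The per-subject
ear − finger resting offset is drawn N(0.23, 1.45)%, giving a population RMS
site difference of ≈ 1.47%. Values without an external anchor (sampling
rate, ADC scale, noise, drift, respiration) are realistic choices for a
reflective pulse-oximeter front-end and are set once here, not fitted.

Key constructions:

* **Beat template** — a skewed low-harmonic waveform (fundamental + 2nd and
  3rd harmonics at relative amplitudes 1 : 0.18 : 0.05 with phase offsets),
  normalized to zero mean and peak-to-peak exactly 2 so a train scaled by
  `a` has AC peak-to-peak `2a`. The harmonic budget guarantees exactly one
  local maximum and one minimum per beat both before and after the 1–30 Hz
  band-pass across heart rates 50–100 bpm (verified numerically in the
  tests). A template with a pronounced dicrotic bump was rejected: its
  secondary post-filter peak crosses a fixed prominence threshold in strong
  channels but not weak ones, biasing R asymmetrically between channels.
* **Inverse calibration** — the infrared AC amplitude is the configured
  value (with respiration modulation); the red AC amplitude is set
  instant-by-instant to `R(t) · DC_red(t)/DC_ir(t) · AC_ir(t)` with
  `R(t) = (104 − SpO₂(t))/17`, so the generated per-beat ratio of ratios
  equals the target exactly (to 1e−6) by construction.
* **Desaturation dips** — each hold subtracts a two-sided exponential
  (Laplacian-shaped) dip `depth · exp(−|t − t_min|/τ)` with its minimum at
  `hold_end + transit_delay` exactly. Equal rise/fall time constants make
  the dip locally symmetric, so the centered moving-average smoother does
  not shift the trough — ground-truth trough times stay exact. The dip's
  tail at the hold start is `depth · e^{−Δ/τ}` (< 0.2% for the defaults), so
  the resting window is effectively uncontaminated.
* **Seeding** — subject seed = base seed + index; per-site noise streams are
  derived from (subject seed, site index). Identical seeds give bit-identical
  output.

### What the generator does and does not emulate

It reproduces the *structure* real dual-site recordings would have (scales,
timing, amplitude ratios, delays, noise) but not motion artefacts, sensor
displacement, perfusion/melanin optics, heart-rate variability, or
non-linear multi-wavelength physics. Passing recovery tests therefore
demonstrates that the pipeline measures what it claims under the stated
signal model — not that the model captures every failure mode of field
recordings.

### Known numerical behaviour

* With the default noise (SD 5 counts), envelope peak-picking inflates the
  AC amplitude slightly more in low-amplitude channels; this biases
  extracted resting SpO₂ downward by ≈ 0.4% at the ear and ≈ 0.15% at the
  finger. Both are inside the ±1.0% noisy round-trip tolerance and small
  against the ±1.45% between-subject site-difference scatter, so they are
  documented rather than corrected; a bias correction would presume the
  noise model.
* SpO₂ from envelopes is effectively sampled at the beat rate, so trough
  times carry up to ~half a beat interval of quantization; averaged over
  three holds the per-subject delay RMSE is < 0.1 s in the noiseless case.

## Problem sizes

Default simulations are 435 s at 100 Hz (43 500 samples per channel); a full
14-subject cohort (2 sites × 2 channels each) simulates and analyzes in a
few seconds. The statistical-calibration check uses 400 replicate cohorts of
parameter draws (no signal synthesis), which is the statistic-level
granularity the t-test operates on.

## Limitations

* Single linear calibration segment; no per-device fitting and no handling
  of R ranges where the linear approximation fails (SpO₂ < ~70%).
* The "first trough" rule assumes one desaturation dip per hold window; it
  is untested against double-dip artefacts.
* The button is trusted as ground truth for hold timing; reaction-time
  error between physiology and button press is not modelled.
* Two-site support is fixed to the ear/finger comparison in the cohort
  statistics layer (the extraction and delay layers are site-agnostic).
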