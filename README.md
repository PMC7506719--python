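# ppgox

Dual-site pulse-oximetry analysis for wearable photoplethysmography (PPG):
SpO₂ extraction from red/infrared channels, breath-hold desaturation-delay
estimation, and cohort-level agreement statistics — built around comparing
the **ear canal** (a candidate site for "hearable" devices) with the
conventional **index finger**.

## The problem

Peripheral oxygen saturation (SpO₂) is estimated optically from the pulsatile
absorption of red (~660 nm) and infrared (~880 nm) light. Because the ear
canal is supplied by central circulation, it responds to a drop in blood
oxygen seconds earlier than the finger — a difference that matters for apnea
detection and any application where SpO₂ response time is critical. Comparing
the two sites requires a pipeline that (a) turns raw two-wavelength PPG into
a calibrated SpO₂ trace, (b) anchors desaturation events to ground truth
(a button held during each exhale + breath-hold manoeuvre), and (c) measures
per-site delays and agreement statistics across a cohort.

## The method

For each channel the pulsatile (AC) component is isolated with a 1–30 Hz
zero-phase band-pass; peaks and troughs are detected with a topographic
prominence threshold (defaults 150 ADC counts for infrared, 30 for red),
interpolated into upper/lower envelopes, and summed in absolute value into a
running peak-to-peak AC amplitude. The quasi-static (DC) baseline is a
0.01 Hz low-pass of the raw signal. The two wavelengths combine into the
**ratio of ratios**

    R = (AC_red / DC_red) / (AC_ir / DC_ir)

which maps to saturation through the linear calibration

    SpO₂ = 104 − 17 · R .

Breath holds are segmented from the button channel (press = exhale start,
release = hold end = moment of minimal alveolar oxygen). The **desaturation
delay** of a site is the time from button release to the first
prominence-qualified trough of the smoothed SpO₂ trace; the **relative
delay** is finger-mean minus ear-mean (positive when the ear leads). Cohort
statistics cover resting SpO₂ agreement (RMS and mean ear−finger difference,
healthy-range [94, 100]% agreement), normalized resting AC amplitudes and
the finger/ear amplitude ratio, sex comparisons (Welch t-test by default),
and Pearson correlations of delay with age and heart rate.

Because no recorded data ship with the package, a **synthetic cohort
generator** produces dual-site recordings with known ground truth: the
435 s guided protocol (120 s rest, 3 × [5 s exhale + 20 s hold] separated by
60 s rest, 120 s rest), a low-harmonic cardiac beat template, red/IR
amplitudes driven by a target SpO₂ trajectory through the inverse
calibration, site-specific transit delays, respiration amplitude modulation,
baseline drift, and sensor noise. Every pipeline stage is tested by
parameter recovery against this ground truth.

## Worked example

```python
from ppgox import (SubjectParams, make_protocol, simulate_subject,
                   extract_spo2, segment_breath_holds, compute_delays)

recordings, truth = simulate_subject(SubjectParams(seed=42), make_protocol())
events = segment_breath_holds(recordings["ear"].button, recordings["ear"].fs)
result = compute_delays(events,
                        extract_spo2(recordings["ear"]),
                        extract_spo2(recordings["finger"]))
print(result.mean_delay, result.relative_delay)
```

Running `python examples/03_breathhold_delays.py` prints:

```
ear: per-hold delays [4.15, 4.35, 4.01] s -> mean 4.17 s (range 0.34), injected 4.35 s
finger: per-hold delays [16.81, 16.59, 16.79] s -> mean 16.73 s (range 0.22), injected 16.75 s
relative delay (finger - ear): 12.56 s
```

i.e. the estimator recovers the injected ear (4.35 s) and finger (16.75 s)
transit delays from the raw signals to within a few tenths of a second, and
the ear canal sees the desaturation ~12.6 s before the finger. The other
`examples/` scripts walk through simulation (`01`), SpO₂ extraction (`02`)
and cohort statistics (`04`), each printing the numbers it computes and what
they mean.

A thin CLI wraps the same functions:

```bash
ppgox run --subjects 14 --seed 1 --out cohort_out   # simulate + analyze
ppgox simulate --subjects 2 --seed 7 --out demo
ppgox analyze --in demo --out demo
```

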