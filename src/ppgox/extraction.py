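"""Raw red/infrared PPG -> calibrated SpO2 series.

The pipeline mirrors standard transmissive/reflective pulse-oximetry
processing:

1. band-pass 1-30 Hz to isolate the cardiac pulsatile (AC) component;
2. prominence-thresholded peak and trough detection on the AC signal;
3. linear interpolation of peak and trough values over the full time grid,
   absolute values summed to give a per-sample AC (peak-to-peak) amplitude;
4. low-pass 0.01 Hz on the raw signal for the quasi-static (DC) baseline;
5. ratio of ratios R = (AC_red/DC_red) / (AC_ir/DC_ir);
6. linear calibration SpO2 = 104 - 17 R.

Default prominence thresholds are 150 ADC counts (infrared) and 30 (red);
they are sensor-scale dependent and fully configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateSignalError, InvalidParameterError, UndefinedResultError
from .io import PPGRecording
from .simulate import CAL_INTERCEPT, CAL_SLOPE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable knobs of the SpO2 extraction chain."""

    bandpass_low_hz: float = 1.0
    bandpass_high_hz: float = 30.0
    dc_cutoff_hz: float = 0.01
    prominence_ir: float = 150.0
    prominence_red: float = 30.0
    smooth_window_s: float = 3.0
    clip: bool = False
    #: invalid-R gaps shorter than this are linearly interpolated (seconds)
    max_interp_gap_s: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExtractionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EnvelopePair:
    """Interpolated peak/trough envelopes of a band-passed channel.

    ``ac_amplitude = |peak_env| + |trough_env|`` pointwise, i.e. the running
    peak-to-peak amplitude for a zero-mean AC signal.
    """

    peak_env: np.ndarray
    trough_env: np.ndarray
    ac_amplitude: np.ndarray
    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray


@dataclass
class SpO2Series:
    """Calibrated SpO2 trace with its intermediate signals retained."""

    t: np.ndarray
    spo2: np.ndarray           # unsmoothed, unclipped unless config.clip
    spo2_smooth: np.ndarray    # moving-average smoothed (event detection)
    R: np.ndarray
    dc_red: np.ndarray
    dc_ir: np.ndarray
    envelopes: dict[str, EnvelopePair]
    fs: float
    config: ExtractionConfig
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _sosfiltfilt(sos: np.ndarray, x: np.ndarray, what: str) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= 3 * padlen:
        raise DegenerateSignalError(
            f"record too short for {what}: need more than {3 * padlen} samples "
            f"(~3 filter transients), got {len(x)}",
            stage=what,
        )
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def bandpass_ac(raw: np.ndarray, fs: float,
                low_hz: float = 1.0, high_hz: float = 30.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass isolating the AC component.

    If ``fs`` is too low for the requested upper edge the edge is reduced to
    ``0.45 * fs`` with a warning.
    """
    if fs <= 2 * low_hz:
        raise InvalidParameterError(f"fs={fs} Hz too low for band-pass low edge {low_hz} Hz")
    if high_hz >= 0.5 * fs:
        new_high = 0.45 * fs
        warnings.warn(
            f"band-pass upper edge {high_hz} Hz not representable at fs={fs} Hz; "
            f"reducing to {new_high:.3g} Hz",
            stacklevel=2,
        )
        high_hz = new_high
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return _sosfiltfilt(sos, np.asarray(raw, dtype=float), "bandpass_ac")


def lowpass_dc(raw: np.ndarray, fs: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass for the DC baseline.

    Records shorter than 60 s carry no information below 0.01 Hz worth
    filtering for; they fall back to the record mean with a warning.
    """
    x = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("lowpass_dc: input contains non-finite samples")
    if len(x) / fs < 60.0:
        warnings.warn(
            "record shorter than 60 s: DC estimated as the record mean",
            stacklevel=2,
        )
        return np.full_like(x, x.mean())
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return _sosfiltfilt(sos, x, "lowpass_dc")


# ---------------------------------------------------------------------------
# extrema and envelopes
# ---------------------------------------------------------------------------

def detect_extrema(ac: np.ndarray, fs: float, min_prominence: float):
    """Prominence-thresholded peaks and troughs of an AC signal.

    Troughs are found as peaks of the negated signal. Returns
    ``(peak_times, peak_values, trough_times, trough_values)`` on the record
    clock; empty arrays when nothing qualifies.
    """
    if min_prominence <= 0:
        raise InvalidParameterError("min_prominence must be positive")
    ac = np.asarray(ac, dtype=float)
    pk, _ = sps.find_peaks(ac, prominence=min_prominence)
    tr, _ = sps.find_peaks(-ac, prominence=min_prominence)
    return pk / fs, ac[pk], tr / fs, -(-ac[tr])


def ac_envelope(
    peak_times: np.ndarray, peak_values: np.ndarray,
    trough_times: np.ndarray, trough_values: np.ndarray,
    t: np.ndarray, channel: str = "",
) -> EnvelopePair:
    """Interpolate extrema over the full grid and form the AC amplitude.

    Linear interpolation between extremum values; beyond the outermost
    extremum the envelope holds its end value. Requires at least two peaks
    and two troughs.
    """
    if len(peak_times) < 2 or len(trough_times) < 2:
        raise DegenerateSignalError(
            f"need >= 2 peaks and >= 2 troughs, got {len(peak_times)} peaks / "
            f"{len(trough_times)} troughs",
            channel=channel or None, stage="ac_envelope",
        )
    peak_env = np.interp(t, peak_times, peak_values)
    trough_env = np.interp(t, trough_times, trough_values)
    return EnvelopePair(
        peak_env=peak_env,
        trough_env=trough_env,
        ac_amplitude=np.abs(peak_env) + np.abs(trough_env),
        peak_times=np.asarray(peak_times), trough_times=np.asarray(trough_times),
        peak_values=np.asarray(peak_values), trough_values=np.asarray(trough_values),
    )


# ---------------------------------------------------------------------------
# ratio of ratios and calibration
# ---------------------------------------------------------------------------

def ratio_of_ratios(ac_red, dc_red, ac_ir, dc_ir) -> np.ndarray:
    """Pointwise R = (AC_red/DC_red) / (AC_ir/DC_ir).

    Samples with non-positive denominators are returned as NaN (masked);
    their count is logged.
    """
    ac_red, dc_red = np.asarray(ac_red, float), np.asarray(dc_red, float)
    ac_ir, dc_ir = np.asarray(ac_ir, float), np.asarray(dc_ir, float)
    bad = (dc_red <= 0) | (dc_ir <= 0) | (ac_ir <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (ac_red / dc_red) / (ac_ir / dc_ir)
    if bad.any():
        logger.warning("ratio_of_ratios: %d samples masked (non-positive denominator)",
                       int(bad.sum()))
        R = np.where(bad, np.nan, R)
    return R


def calibrate_spo2(R: np.ndarray, clip: bool = False) -> np.ndarray:
    """Linear pulse-oximetry calibration SpO2 = 104 - 17 R (percent).

    Values above 100% are reported as-is unless ``clip`` is set, in which
    case the output is clipped to [0, 100].
    """
    spo2 = CAL_INTERCEPT - CAL_SLOPE * np.asarray(R, dtype=float)
    if clip:
        spo2 = np.clip(spo2, 0.0, 100.0)
    return spo2


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered boxcar moving average with an odd sample count."""
    size = int(round(window_s * fs))
    size = max(size, 1)
    if size % 2 == 0:
        size += 1
    return uniform_filter1d(np.asarray(x, float), size=size, mode="nearest")


def _interp_small_gaps(x: np.ndarray, fs: float, max_gap_s: float) -> np.ndarray:
    """Linearly fill NaN runs shorter than ``max_gap_s``; longer runs stay NaN."""
    x = np.asarray(x, float).copy()
    isnan = np.isnan(x)
    if not isnan.any() or isnan.all():
        return x
    idx = np.arange(len(x))
    # identify NaN runs
    edges = np.diff(isnan.astype(int))
    starts = list(idx[1:][edges == 1])
    ends = list(idx[1:][edges == -1])
    if isnan[0]:
        starts = [0] + starts
    if isnan[-1]:
        ends = ends + [len(x)]
    filled = np.interp(idx, idx[~isnan], x[~isnan])
    for s, e in zip(starts, ends):
        if (e - s) / fs < max_gap_s and s > 0 and e < len(x):
            x[s:e] = filled[s:e]
    return x


def estimate_heart_rate(peak_times: np.ndarray) -> float:
    """Heart rate as 60 / median inter-peak interval (beats/min)."""
    peak_times = np.asarray(peak_times, float)
    if len(peak_times) < 2:
        raise UndefinedResultError("heart rate undefined: fewer than 2 peaks")
    return 60.0 / float(np.median(np.diff(peak_times)))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def extract_spo2(rec: PPGRecording, config: ExtractionConfig | None = None) -> SpO2Series:
    """Run the full extraction chain on one recording."""
    if config is None:
        config = ExtractionConfig()
    rec.validate()
    fs = rec.fs
    prominences = {"infrared": config.prominence_ir, "red": config.prominence_red}

    envelopes: dict[str, EnvelopePair] = {}
    dcs: dict[str, np.ndarray] = {}
    for name in ("red", "infrared"):
        raw = rec.channels[name]
        ac = bandpass_ac(raw, fs, config.bandpass_low_hz, config.bandpass_high_hz)
        pt, pv, tt, tv = detect_extrema(ac, fs, prominences[name])
        envelopes[name] = ac_envelope(pt, pv, tt, tv, rec.t, channel=name)
        dcs[name] = lowpass_dc(raw, fs, config.dc_cutoff_hz)

    R = ratio_of_ratios(
        envelopes["red"].ac_amplitude, dcs["red"],
        envelopes["infrared"].ac_amplitude, dcs["infrared"],
    )
    spo2 = calibrate_spo2(R, clip=config.clip)
    spo2 = _interp_small_gaps(spo2, fs, config.max_interp_gap_s)
    spo2_smooth = moving_average(spo2, fs, config.smooth_window_s)

    return SpO2Series(
        t=rec.t,
        spo2=spo2,
        spo2_smooth=spo2_smooth,
        R=R,
        dc_red=dcs["red"],
        dc_ir=dcs["infrared"],
        envelopes=envelopes,
        fs=fs,
        config=config,
        meta=dict(rec.meta),
    )
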