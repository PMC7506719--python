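"""Breath-hold segmentation and site-specific desaturation delays.

The button channel marks each manoeuvre from exhale start to breath-hold
end; the hold end (button release) is the moment of minimal blood oxygen at
the lungs. Each measurement site then shows its SpO2 trough only after the
site's vascular transit delay. The delay estimate is the time from button
release to the first qualified SpO2 trough; per subject the three holds are
averaged, their range reported as variability, and the relative delay is
finger mean minus ear mean (positive when the ear leads).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, UndefinedResultError
from .extraction import SpO2Series

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BreathHoldEvent:
    press_time: float    # exhale start, seconds
    release_time: float  # hold end, seconds
    index: int           # 1-based hold number

    def __post_init__(self):
        if not self.press_time < self.release_time:
            raise InvalidParameterError(
                f"press_time {self.press_time} must precede release_time {self.release_time}"
            )


@dataclass
class DelayResult:
    """Per-subject desaturation-delay summary across holds and sites."""

    per_hold_delay: dict[str, list[float]]   # NaN where no trough qualified
    trough_times: dict[str, list[float]]
    mean_delay: dict[str, float]
    range: dict[str, float]                  # max - min over valid holds
    relative_delay: float                    # finger mean - ear mean


def segment_breath_holds(
    button: np.ndarray,
    fs: float,
    min_duration: float = 2.0,
    max_gap: float = 0.2,
) -> list[BreathHoldEvent]:
    """Pair button rising/falling edges into breath-hold events.

    Debounce rules: high runs separated by gaps shorter than ``max_gap`` are
    merged; runs shorter than ``min_duration`` (button bounces, stray
    spikes) are discarded. An unmatched rising edge at the record end is
    dropped with a warning.
    """
    b = np.asarray(button)
    vals = np.unique(b)
    if not np.all(np.isin(vals, (0, 1))):
        raise InvalidParameterError("button channel must be binary 0/1")
    b = b.astype(bool)
    if not b.any():
        return []

    # run-length extraction of high segments as [start, end) sample indices
    padded = np.concatenate(([0], b.astype(int), [0]))
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]

    truncated = b[-1]  # high at record end: final run has no falling edge
    if truncated:
        warnings.warn(
            "button high at record end: unmatched rising edge, event dropped",
            stacklevel=2,
        )
        starts, ends = starts[:-1], ends[:-1]

    # merge runs separated by sub-max_gap dropouts
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) / fs < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        if (e - s) / fs >= min_duration:
            events.append(BreathHoldEvent(
                press_time=s / fs, release_time=e / fs, index=len(events) + 1,
            ))
    return events


def find_spo2_trough(
    spo2: SpO2Series,
    release_time: float,
    window: float = 45.0,
    min_prominence: float = 1.0,
    lead: float = 1.0,
) -> float:
    """Time of the first qualified SpO2 trough after a button release.

    Troughs are prominence-thresholded local minima of the smoothed SpO2
    trace; the earliest one in ``[release_time - lead, release_time +
    window]`` is returned (the small lead tolerates smoothing/noise jitter
    for dips centered at the release itself). Equal-depth ties break to the
    earliest. Returns NaN when no trough qualifies; the caller excludes such
    holds from means.
    """
    if window <= 0:
        raise InvalidParameterError("window must be positive")
    t = spo2.t
    if not (t[0] <= release_time <= t[-1]):
        raise InvalidParameterError(
            f"release_time {release_time} outside record [{t[0]}, {t[-1]}]"
        )
    x = spo2.spo2_smooth
    # prominence is evaluated on the full series so dip depth is judged
    # against the surrounding baseline, not an arbitrary window edge
    tr, _ = sps.find_peaks(-x, prominence=min_prominence)
    tr_times = t[tr]
    in_window = (tr_times >= release_time - lead) & (tr_times <= release_time + window)
    if not in_window.any():
        logger.warning("no qualifying SpO2 trough within %.1f s after release at %.1f s",
                       window, release_time)
        return float("nan")
    return float(tr_times[in_window][0])


def compute_delays(
    events: list[BreathHoldEvent],
    spo2_ear: SpO2Series,
    spo2_finger: SpO2Series,
    window: float = 45.0,
    min_prominence: float = 1.0,
) -> DelayResult:
    """Per-hold, mean, range, and relative desaturation delays for a subject."""
    if not events:
        raise UndefinedResultError("no breath-hold events: delays undefined")
    series = {"ear": spo2_ear, "finger": spo2_finger}
    per_hold: dict[str, list[float]] = {s: [] for s in series}
    troughs: dict[str, list[float]] = {s: [] for s in series}
    for site, sp in series.items():
        for ev in events:
            tt = find_spo2_trough(sp, ev.release_time, window, min_prominence)
            troughs[site].append(tt)
            per_hold[site].append(tt - ev.release_time)

    mean_delay, rng = {}, {}
    for site in series:
        valid = [d for d in per_hold[site] if np.isfinite(d)]
        if not valid:
            raise UndefinedResultError(
                f"all troughs missing for site '{site}': delay undefined"
            )
        if len(valid) < len(per_hold[site]):
            logger.warning("site '%s': %d of %d holds had no qualifying trough",
                           site, len(per_hold[site]) - len(valid), len(per_hold[site]))
        mean_delay[site] = float(np.mean(valid))
        rng[site] = float(np.max(valid) - np.min(valid))

    return DelayResult(
        per_hold_delay=per_hold,
        trough_times=troughs,
        mean_delay=mean_delay,
        range=rng,
        relative_delay=mean_delay["finger"] - mean_delay["ear"],
    )
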