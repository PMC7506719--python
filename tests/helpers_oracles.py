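"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities from first principles (exhaustive
scans, direct arithmetic) without touching the implementation paths they
check.
"""

import numpy as np


def bruteforce_prominent_peaks(x: np.ndarray, min_prominence: float):
    """Exhaustive topographic-prominence peak scan.

    A peak is a strict local maximum. Its prominence is its height above the
    higher of the two minima found while walking outward on each side until
    a sample higher than the peak (or the signal edge) is met.
    Returns (indices, prominences) of peaks whose prominence >= threshold.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    peaks, proms = [], []
    for i in range(1, n - 1):
        if not (x[i - 1] < x[i] > x[i + 1]):
            continue
        # walk left
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        # walk right
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        prom = x[i] - max(left_min, right_min)
        if prom >= min_prominence:
            peaks.append(i)
            proms.append(prom)
    return np.array(peaks, dtype=int), np.array(proms, dtype=float)


def bruteforce_button_events(button: np.ndarray, fs: float, min_duration: float,
                             max_gap: float = 0.2):
    """Run-length edge pairing with the documented debounce rule.

    Scans the binary sequence sample by sample, collects high runs, merges
    runs separated by gaps shorter than ``max_gap``, drops runs shorter than
    ``min_duration`` and an unterminated final run.
    Returns a list of (press_time, release_time).
    """
    runs = []
    start = None
    for i, v in enumerate(button):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append([start, i])
            start = None
    # unterminated run at record end is dropped
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) / fs < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s / fs, e / fs) for s, e in merged if (e - s) / fs >= min_duration]
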