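"""Reading and writing PPG recordings and cohort results.

Formats are deliberately plain text for auditability:

* recording: one CSV per site with header ``time_s,green,red,infrared,button``
  (``green`` may be blank) plus a JSON sidecar ``<name>.meta.json`` holding the
  sampling rate and subject metadata, versioned via ``format_version``;
* cohort results: a per-subject CSV table plus one JSON file of cohort-level
  scalar statistics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"

#: channels that must be present in every recording
REQUIRED_CHANNELS = ("red", "infrared")
OPTIONAL_CHANNELS = ("green",)

# relative tolerance on the uniformity of the time grid
_GRID_RTOL = 1e-6


@dataclass
class PPGRecording:
    """A single-site, multichannel reflective PPG recording.

    Attributes
    ----------
    t : np.ndarray
        Sample times in seconds, uniform grid starting at 0.
    channels : dict[str, np.ndarray]
        Raw photodiode counts keyed by wavelength name
        (``red`` ~660 nm, ``infrared`` ~880 nm, optional ``green`` ~537 nm).
    button : np.ndarray
        Binary event-marker channel; 1 while the subject holds the button
        (exhale start through breath-hold end).
    fs : float
        Sampling rate in Hz.
    meta : dict
        Subject/site metadata: ``subject_id``, ``site`` ("ear"/"finger"),
        ``sex``, ``age``.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    button: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs

    def validate(self) -> None:
        """Raise :class:`FormatError` on any invariant violation."""
        if self.fs <= 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        n = len(self.t)
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise FormatError(f"missing channel: {name}")
        for name, x in self.channels.items():
            if len(x) != n:
                raise FormatError(
                    f"channel '{name}' length {len(x)} != time grid length {n}"
                )
        if len(self.button) != n:
            raise FormatError(f"button length {len(self.button)} != time grid length {n}")
        vals = np.unique(self.button)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"button channel must be binary 0/1, found values {vals[:5]}")
        if n >= 2:
            dt = np.diff(self.t)
            step = 1.0 / self.fs
            if np.any(dt <= 0):
                raise FormatError("time grid must be strictly increasing")
            if not np.allclose(dt, step, rtol=_GRID_RTOL, atol=step * _GRID_RTOL * 10):
                raise FormatError(
                    "non-uniform time grid or fs mismatch: "
                    f"spacing range [{dt.min():.6g}, {dt.max():.6g}] vs 1/fs={step:.6g}"
                )


def write_recording(rec: PPGRecording, path: str | Path) -> Path:
    """Write ``rec`` as CSV + JSON sidecar; returns the CSV path."""
    rec.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_s": rec.t}
    for name in ("green",) + REQUIRED_CHANNELS:
        if name in rec.channels:
            cols[name] = rec.channels[name]
        elif name in OPTIONAL_CHANNELS:
            cols[name] = np.full(len(rec.t), np.nan)
    cols["button"] = rec.button.astype(int)
    df = pd.DataFrame(cols)[["time_s", "green", "red", "infrared", "button"]]
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")
    sidecar = {"format_version": FORMAT_VERSION, "fs": rec.fs, **rec.meta}
    meta_path = path.parent / (path.stem + ".meta.json")
    meta_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_recording(path: str | Path) -> PPGRecording:
    """Read a recording written by :func:`write_recording`.

    Invariant violations (missing channel, non-binary button, non-uniform
    grid, fs mismatch) are fatal and raise :class:`FormatError` naming the
    offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = path.parent / (path.stem + ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar: {meta_path.name}")
    sidecar = json.loads(meta_path.read_text())
    if "fs" not in sidecar:
        raise FormatError("sidecar missing field: fs")
    fs = float(sidecar["fs"])
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("missing column: time_s")
    for name in REQUIRED_CHANNELS:
        if name not in df.columns:
            raise FormatError(f"missing channel: {name}")
    if "button" not in df.columns:
        raise FormatError("missing column: button")
    channels = {}
    for name in REQUIRED_CHANNELS + OPTIONAL_CHANNELS:
        if name in df.columns:
            x = df[name].to_numpy(dtype=float)
            if name in OPTIONAL_CHANNELS and np.all(np.isnan(x)):
                continue
            channels[name] = x
    meta = {k: v for k, v in sidecar.items() if k not in ("format_version", "fs")}
    return PPGRecording(
        t=df["time_s"].to_numpy(dtype=float),
        channels=channels,
        button=df["button"].to_numpy(dtype=float),
        fs=fs,
        meta=meta,
    )


def write_results(summary, outdir: str | Path) -> Path:
    """Write a :class:`~ppgox.stats.CohortSummary` to ``outdir``.

    Produces ``per_subject.csv`` (one row per subject) and ``cohort.json``
    (cohort-level scalars). An empty cohort yields a header-only table; a
    one-subject cohort yields NaN for between-subject statistics (a warning
    is logged when the summary is computed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.per_subject.to_csv(outdir / "per_subject.csv", index=False, float_format="%.10g")
    scalars = _jsonify(summary.scalars)
    scalars["format_version"] = FORMAT_VERSION
    (outdir / "cohort.json").write_text(json.dumps(scalars, indent=1, sort_keys=True) + "\n")
    return outdir


def read_results(outdir: str | Path):
    """Round-trip counterpart of :func:`write_results`."""
    from .stats import CohortSummary  # local import to avoid a cycle

    outdir = Path(outdir)
    per_subject = pd.read_csv(outdir / "per_subject.csv")
    scalars = json.loads((outdir / "cohort.json").read_text())
    scalars.pop("format_version", None)
    return CohortSummary(per_subject=per_subject, scalars=scalars)


def _jsonify(obj):
    """Convert numpy scalars/arrays and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
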