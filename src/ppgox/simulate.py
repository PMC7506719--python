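"""Synthetic dual-site, dual-wavelength PPG cohort generator.

Emulates a guided breath-hold protocol recorded simultaneously from the ear
canal and the index finger: a rest period, repeated exhale+hold manoeuvres
marked by a subject-held button, and a final rest period. Each site's red and
infrared channels carry a cardiac pulsatile (AC) component riding on a large
slowly drifting baseline (DC), with respiration amplitude modulation and
additive sensor noise. The red/infrared amplitude balance is driven by a
target SpO2 trajectory through the inverse of the linear pulse-oximetry
calibration SpO2 = 104 - 17*R, so every downstream stage can be tested
against known ground truth.

Breath holds produce site-specific desaturation dips whose troughs lag the
hold end by a configurable vascular transit delay per site — the central
quantity the analysis pipeline estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import PPGRecording

logger = logging.getLogger(__name__)

SITES = ("ear", "finger")

#: floor below which simulated SpO2 trajectories are clipped (percent)
SPO2_FLOOR = 50.0

#: calibration constants of the linear SpO2 <-> ratio-of-ratios map
CAL_INTERCEPT = 104.0
CAL_SLOPE = 17.0


# ---------------------------------------------------------------------------
# protocol timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolStage:
    label: str      # "rest" | "exhale" | "hold"
    duration: float  # seconds


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered breath-hold protocol stages.

    ``hold_windows`` gives one ``(press_time, release_time)`` pair per
    manoeuvre: the button is held from exhale start to hold end.
    """

    stages: tuple[ProtocolStage, ...]

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.stages))

    @property
    def hold_windows(self) -> list[tuple[float, float]]:
        windows = []
        t = 0.0
        press = None
        for s in self.stages:
            if s.label == "exhale":
                press = t
            elif s.label == "hold":
                start = press if press is not None else t
                windows.append((start, t + s.duration))
                press = None
            t += s.duration
        return windows


def make_protocol(
    n_holds: int = 3,
    rest_pre: float = 120.0,
    exhale: float = 5.0,
    hold: float = 20.0,
    rest_between: float = 60.0,
    rest_post: float = 120.0,
) -> ProtocolTimeline:
    """Build the guided breath-hold timeline.

    Defaults reproduce the 435 s protocol: 120 s rest, three repeats of
    5 s exhale + 20 s hold separated by 60 s rest, then 120 s rest.
    """
    durations = dict(rest_pre=rest_pre, exhale=exhale, hold=hold,
                     rest_between=rest_between, rest_post=rest_post)
    for name, d in durations.items():
        if d < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {d}")
    if n_holds < 0 or int(n_holds) != n_holds:
        raise InvalidParameterError(f"n_holds must be a non-negative integer, got {n_holds}")

    stages: list[ProtocolStage] = []

    def add(label: str, duration: float):
        if duration > 0:
            stages.append(ProtocolStage(label, float(duration)))

    add("rest", rest_pre)
    for i in range(int(n_holds)):
        if i > 0:
            add("rest", rest_between)
        add("exhale", exhale)
        add("hold", hold)
    add("rest", rest_post)
    return ProtocolTimeline(stages=tuple(stages))


# ---------------------------------------------------------------------------
# subject parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteParams:
    """Per-site ground-truth signal parameters.

    ``ac_amplitude`` is the half peak-to-peak infrared pulsatile amplitude in
    ADC counts (the generated resting AC peak-to-peak equals twice this
    value). ``transit_delay`` is the lag from breath-hold end to the SpO2
    trough at this site. ``spo2_offset`` shifts the site's resting SpO2
    relative to the subject baseline (models inter-site calibration offset).
    """

    ac_amplitude: float = 300.0
    dc_level: float = 50000.0
    transit_delay: float = 4.35
    desat_depth: float = 6.0
    desat_tau: float = 6.0
    spo2_offset: float = 0.0
    red_dc_fraction: float = 0.6  # red DC level relative to infrared DC


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str = "S01"
    sex: str = "F"                    # "F" | "M"
    age: float = 28.0
    heart_rate: float = 70.0          # beats/min
    resting_spo2: float = 97.0        # percent
    site_params: dict[str, SiteParams] = field(default_factory=lambda: {
        "ear": SiteParams(ac_amplitude=300.0, transit_delay=4.35),
        "finger": SiteParams(ac_amplitude=705.0, transit_delay=16.75),
    })
    respiration_rate: float = 0.25    # Hz
    respiration_mod_depth: float = 0.1
    noise_sd: float = 5.0             # ADC counts
    drift_amplitude: float = 200.0    # ADC counts
    drift_period: float = 300.0       # seconds
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.resting_spo2 <= 100):
            raise InvalidParameterError(f"resting_spo2 must be in (0, 100], got {self.resting_spo2}")
        if self.heart_rate <= 0:
            raise InvalidParameterError("heart_rate must be positive")
        if not (0 <= self.respiration_mod_depth < 1):
            raise InvalidParameterError("respiration_mod_depth must be in [0, 1)")
        for site, sp in self.site_params.items():
            if sp.ac_amplitude <= 0 or sp.dc_level <= 0:
                raise InvalidParameterError(f"{site}: ac_amplitude and dc_level must be positive")
            if sp.transit_delay < 0:
                raise InvalidParameterError(f"{site}: transit_delay must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    t: np.ndarray
    spo2_trajectory: dict[str, np.ndarray]
    true_R: dict[str, np.ndarray]
    true_trough_times: dict[str, list[float]]
    true_delays: dict[str, float]
    true_resting_spo2: dict[str, float]
    true_heart_rate: float


# ---------------------------------------------------------------------------
# beat template
# ---------------------------------------------------------------------------

# Skewed low-harmonic beat template: fundamental plus two decaying harmonics.
# Harmonic amplitudes/phases are chosen so that the waveform — before and
# after the 1-30 Hz band-pass used in extraction, across heart rates
# 50-100 bpm — has exactly one local maximum and one local minimum per beat.
# This keeps fixed peak-prominence thresholds meaningful at every channel
# scale; a pronounced dicrotic bump would cross such thresholds
# inconsistently between strong and weak channels.
_TEMPLATE_HARMONICS = ((1, 1.0, 0.0), (2, 0.18, np.pi / 2), (3, 0.05, np.pi))
_TEMPLATE_GRID = np.linspace(0.0, 1.0, 2049)


def _raw_template(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    for k, a, phi in _TEMPLATE_HARMONICS:
        out += a * np.cos(2 * np.pi * k * u + phi)
    return out


def beat_template(phase: np.ndarray) -> np.ndarray:
    """Evaluate the normalized beat template at fractional phase.

    Normalized to zero mean and peak-to-peak exactly 2, so a train scaled by
    ``a`` has AC peak-to-peak ``2a``.
    """
    g = _raw_template(_TEMPLATE_GRID)
    g = g - g.mean()
    g = 2.0 * g / (g.max() - g.min())
    # recenter so |max| + |min| still equals the peak-to-peak after the
    # mean shift (max > 0 > min is preserved: the template straddles zero)
    return np.interp(np.mod(phase, 1.0), _TEMPLATE_GRID, g)


# ---------------------------------------------------------------------------
# SpO2 trajectory
# ---------------------------------------------------------------------------

def build_spo2_trajectory(
    timeline: ProtocolTimeline,
    params: SubjectParams,
    site: str,
    fs: float = 100.0,
    t: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Ground-truth SpO2 trace for one site.

    The trace sits at the site's resting SpO2 and dips around each breath
    hold with a two-sided exponential (time constant ``desat_tau``, depth
    ``desat_depth``); each dip's minimum falls exactly ``transit_delay``
    seconds after the hold end. Returns ``(trace, trough_times)``.
    """
    if site not in params.site_params:
        raise InvalidParameterError(f"unknown site '{site}'")
    sp = params.site_params[site]
    if t is None:
        n = int(round(timeline.total_duration * fs))
        t = np.arange(n) / fs
    base = params.resting_spo2 + sp.spo2_offset
    trace = np.full_like(t, base, dtype=float)
    troughs: list[float] = []
    for _, release in timeline.hold_windows:
        t_min = release + sp.transit_delay
        troughs.append(t_min)
        trace -= sp.desat_depth * np.exp(-np.abs(t - t_min) / sp.desat_tau)
    if base - sp.desat_depth < SPO2_FLOOR:
        warnings.warn(
            f"desaturation depth {sp.desat_depth} drives SpO2 below {SPO2_FLOOR}%; clipping",
            stacklevel=2,
        )
        trace = np.clip(trace, SPO2_FLOOR, None)
    return trace, troughs


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def simulate_subject(
    params: SubjectParams,
    timeline: ProtocolTimeline | None = None,
    fs: float = 100.0,
) -> tuple[dict[str, PPGRecording], GroundTruth]:
    """Synthesize one subject's per-site recordings plus ground truth.

    For each site the infrared channel is ``DC + drift + AC*template`` with
    respiration amplitude modulation and white noise; the red channel shares
    the same waveform, scaled instant-by-instant so the per-beat ratio of
    ratios equals ``(104 - SpO2(t)) / 17``. The button channel is 1 from
    exhale start to hold end.
    """
    if timeline is None:
        timeline = make_protocol()
    if fs < 25:
        raise InvalidParameterError(f"fs must be >= 25 Hz to preserve pulse morphology, got {fs}")

    n = int(round(timeline.total_duration * fs))
    t = np.arange(n) / fs

    button = np.zeros(n)
    for press, release in timeline.hold_windows:
        button[(t >= press) & (t < release)] = 1.0

    recordings: dict[str, PPGRecording] = {}
    spo2_truth: dict[str, np.ndarray] = {}
    R_truth: dict[str, np.ndarray] = {}
    trough_truth: dict[str, list[float]] = {}
    pulse = beat_template(params.heart_rate / 60.0 * t)
    resp = 1.0 + params.respiration_mod_depth * np.sin(
        2 * np.pi * params.respiration_rate * t
    )

    for site_idx, site in enumerate(sorted(params.site_params)):
        sp = params.site_params[site]
        rng = np.random.default_rng([max(int(params.seed), 0), site_idx])
        spo2, troughs = build_spo2_trajectory(timeline, params, site, t=t)
        R = (CAL_INTERCEPT - spo2) / CAL_SLOPE

        drift_phase = rng.uniform(0, 2 * np.pi)
        drift = params.drift_amplitude * np.sin(2 * np.pi * t / params.drift_period + drift_phase)
        dc_ir = sp.dc_level + drift
        dc_red = sp.red_dc_fraction * sp.dc_level + drift

        amp_ir = sp.ac_amplitude * resp
        # red AC chosen so (AC_red/DC_red)/(AC_ir/DC_ir) == R(t) exactly
        amp_red = R * (dc_red / dc_ir) * amp_ir

        ir = dc_ir + amp_ir * pulse
        red = dc_red + amp_red * pulse
        if params.noise_sd > 0:
            ir = ir + rng.normal(0.0, params.noise_sd, n)
            red = red + rng.normal(0.0, params.noise_sd, n)

        recordings[site] = PPGRecording(
            t=t.copy(),
            channels={"red": red, "infrared": ir},
            button=button.copy(),
            fs=float(fs),
            meta={
                "subject_id": params.subject_id,
                "site": site,
                "sex": params.sex,
                "age": params.age,
            },
        )
        spo2_truth[site] = spo2
        R_truth[site] = R
        trough_truth[site] = troughs

    truth = GroundTruth(
        t=t,
        spo2_trajectory=spo2_truth,
        true_R=R_truth,
        true_trough_times=trough_truth,
        true_delays={s: params.site_params[s].transit_delay for s in params.site_params},
        true_resting_spo2={
            s: params.resting_spo2 + params.site_params[s].spo2_offset
            for s in params.site_params
        },
        true_heart_rate=params.heart_rate,
    )
    return recordings, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Default parameter distributions for a healthy young adult cohort.
# Each entry is a constant, ("uniform", lo, hi), ("normal", mean, sd) or
# ("normal", mean, sd, lo, hi) with clipping; a dict keyed "F"/"M" makes the
# draw sex-specific.
DEFAULT_PARAM_RANGES: dict = {
    "age": ("uniform", 19.0, 38.0),
    "heart_rate": ("uniform", 55.0, 85.0),
    "resting_spo2": ("uniform", 95.5, 98.5),
    # per-subject ear-minus-finger resting SpO2 difference (percent)
    "site_diff": ("normal", 0.23, 1.45),
    "ear_ac_amplitude": ("uniform", 200.0, 450.0),
    "finger_ear_amp_ratio": 2.35,
    "ear_delay": {
        "F": ("normal", 4.33, 2.37, 0.97, 7.31),
        "M": ("normal", 4.36, 1.42, 0.97, 7.31),
    },
    "finger_delay": {
        "F": ("normal", 14.00, 4.25, 8.52, 28.14),
        "M": ("normal", 19.49, 6.28, 8.52, 28.14),
    },
    "desat_depth": ("uniform", 4.0, 8.0),
    "desat_tau": ("uniform", 4.0, 8.0),
    "respiration_rate": ("uniform", 0.2, 0.3),
    "respiration_mod_depth": 0.1,
    "noise_sd": 5.0,
    "drift_amplitude": 200.0,
    "dc_level": 50000.0,
}


def _draw(spec, rng: np.random.Generator, sex: str) -> float:
    if isinstance(spec, dict):
        spec = spec[sex]
    if isinstance(spec, (int, float)):
        return float(spec)
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        v = float(rng.normal(spec[1], spec[2]))
        if len(spec) == 5:
            v = float(np.clip(v, spec[3], spec[4]))
        return v
    raise InvalidParameterError(f"unknown distribution spec {spec!r}")


def draw_subject_params(
    index: int,
    base_seed: int,
    param_ranges: dict | None = None,
    sex: str | None = None,
) -> SubjectParams:
    """Draw one subject's parameters; subject seed is ``base_seed + index``."""
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    seed = base_seed + index
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = "F" if index % 2 == 0 else "M"  # alternate -> balanced cohorts

    d = {k: _draw(v, rng, sex) for k, v in ranges.items()}
    ear_amp = d["ear_ac_amplitude"]
    return SubjectParams(
        subject_id=f"S{index + 1:02d}",
        sex=sex,
        age=d["age"],
        heart_rate=d["heart_rate"],
        resting_spo2=d["resting_spo2"],
        site_params={
            "ear": SiteParams(
                ac_amplitude=ear_amp,
                dc_level=d["dc_level"],
                transit_delay=d["ear_delay"],
                desat_depth=d["desat_depth"],
                desat_tau=d["desat_tau"],
                spo2_offset=+d["site_diff"] / 2.0,
            ),
            "finger": SiteParams(
                ac_amplitude=ear_amp * d["finger_ear_amp_ratio"],
                dc_level=d["dc_level"],
                transit_delay=d["finger_delay"],
                desat_depth=d["desat_depth"],
                desat_tau=d["desat_tau"],
                spo2_offset=-d["site_diff"] / 2.0,
            ),
        },
        respiration_rate=d["respiration_rate"],
        respiration_mod_depth=d["respiration_mod_depth"],
        noise_sd=d["noise_sd"],
        drift_amplitude=d["drift_amplitude"],
        seed=seed,
    )


@dataclass
class CohortDataset:
    """A simulated cohort: per-subject recordings, params, and ground truth."""

    subjects: list[SubjectParams]
    recordings: dict[str, dict[str, PPGRecording]]  # subject_id -> site -> rec
    ground_truth: dict[str, GroundTruth]            # subject_id -> truth
    truth_table: pd.DataFrame                       # one row per subject


def simulate_cohort(
    n_subjects: int = 14,
    base_seed: int = 0,
    param_ranges: dict | None = None,
    timeline: ProtocolTimeline | None = None,
    fs: float = 100.0,
) -> CohortDataset:
    """Simulate a cohort of ``n_subjects`` with balanced, alternating sexes."""
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    if not param_ranges:
        logger.info("simulate_cohort: no param_ranges given, using defaults")
    if timeline is None:
        timeline = make_protocol()

    subjects, recs, truths, rows = [], {}, {}, []
    for i in range(n_subjects):
        p = draw_subject_params(i, base_seed, param_ranges)
        site_recs, truth = simulate_subject(p, timeline, fs=fs)
        subjects.append(p)
        recs[p.subject_id] = site_recs
        truths[p.subject_id] = truth
        rows.append({
            "subject_id": p.subject_id,
            "sex": p.sex,
            "age": p.age,
            "heart_rate": p.heart_rate,
            "resting_spo2_ear": truth.true_resting_spo2["ear"],
            "resting_spo2_finger": truth.true_resting_spo2["finger"],
            "ear_delay": truth.true_delays["ear"],
            "finger_delay": truth.true_delays["finger"],
            "ear_ac_amplitude": p.site_params["ear"].ac_amplitude,
            "finger_ac_amplitude": p.site_params["finger"].ac_amplitude,
            "desat_depth": p.site_params["ear"].desat_depth,
            "seed": p.seed,
        })
    return CohortDataset(
        subjects=subjects,
        recordings=recs,
        ground_truth=truths,
        truth_table=pd.DataFrame(rows),
    )
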