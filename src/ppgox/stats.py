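"""Cohort-level comparison statistics between measurement sites.

Covers resting SpO2 agreement (RMS and mean ear-minus-finger difference,
healthy-range [94, 100]% agreement), normalized resting AC amplitudes and
the finger/ear amplitude ratio, sex comparisons of the desaturation delays,
and Pearson correlations of delay against age and heart rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sct

from .errors import InvalidParameterError, UndefinedResultError
from .extraction import SpO2Series

logger = logging.getLogger(__name__)

HEALTHY_LO = 94.0
HEALTHY_HI = 100.0


@dataclass
class CohortSummary:
    """Per-subject table plus cohort-level scalar statistics."""

    per_subject: pd.DataFrame
    scalars: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

def resting_spo2(spo2: SpO2Series, first_press: float, window: float = 60.0) -> float:
    """Mean SpO2 over the ``window`` seconds of rest before the first exhale."""
    if first_press - window < spo2.t[0]:
        raise InvalidParameterError(
            f"insufficient pre-press data: need {window} s before first press at "
            f"{first_press} s (record starts at {spo2.t[0]} s)"
        )
    mask = (spo2.t >= first_press - window) & (spo2.t <= first_press)
    return float(np.nanmean(spo2.spo2[mask]))


def site_difference_summary(ear_means, finger_means) -> tuple[float, float]:
    """RMS and mean of the per-subject ear-minus-finger resting SpO2 difference.

    Positive mean difference means higher saturation in the ear.
    """
    ear = np.asarray(ear_means, float)
    fin = np.asarray(finger_means, float)
    if ear.shape != fin.shape:
        raise InvalidParameterError("ear and finger vectors must have equal length")
    if ear.size < 1:
        raise InvalidParameterError("need at least one subject")
    d = ear - fin
    return float(np.sqrt(np.mean(d**2))), float(np.mean(d))


def healthy_range_agreement(ear_means, finger_means,
                            lo: float = HEALTHY_LO, hi: float = HEALTHY_HI) -> float:
    """Fraction of subjects where both sites agree on healthy-range membership.

    The range is the closed interval [lo, hi]; two out-of-range sites also
    count as agreement.
    """
    ear = np.asarray(ear_means, float)
    fin = np.asarray(finger_means, float)
    in_ear = (ear >= lo) & (ear <= hi)
    in_fin = (fin >= lo) & (fin <= hi)
    return float(np.mean(in_ear == in_fin))


def group_ttest(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Two-sided t-test between two groups (Welch unpaired by default)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if paired:
        if len(a) != len(b):
            raise InvalidParameterError("paired test needs equal-length groups")
        if np.std(a - b) == 0:
            raise UndefinedResultError(
                "paired differences have zero variance: t statistic undefined"
            )
        res = sct.ttest_rel(a, b)
    else:
        res = sct.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidParameterError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidParameterError("zero variance input")
    res = sct.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# amplitude analysis
# ---------------------------------------------------------------------------

def amplitude_summary(
    spo2_by_subject: dict[str, dict[str, SpO2Series]],
    first_press: dict[str, float],
    sexes: dict[str, str] | None = None,
    window: float = 60.0,
) -> pd.DataFrame:
    """Normalized resting infrared AC amplitudes and finger/ear ratios.

    For each subject and site, the mean of the infrared AC-amplitude
    envelope over the ``window`` seconds before the first button press;
    all values are then divided by the cohort maximum (so the largest equals
    1.0). Returns a tidy per-subject frame with columns ``amp_ear``,
    ``amp_finger`` (normalized), ``amp_ratio`` (finger/ear, scale-free).
    """
    rows = []
    for sid, sites in spo2_by_subject.items():
        row = {"subject_id": sid}
        if sexes:
            row["sex"] = sexes.get(sid)
        ok = True
        for site, sp in sites.items():
            mask = (sp.t >= first_press[sid] - window) & (sp.t <= first_press[sid])
            amp = sp.envelopes["infrared"].ac_amplitude[mask]
            if amp.size == 0 or not np.all(np.isfinite(amp)):
                warnings.warn(f"subject {sid} site {site}: degenerate resting envelope; "
                              "subject excluded", stacklevel=2)
                ok = False
                break
            row[f"amp_{site}"] = float(np.mean(amp))
        if ok:
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cohort_max = max(df["amp_ear"].max(), df["amp_finger"].max())
    df["amp_ratio"] = df["amp_finger"] / df["amp_ear"]
    df["amp_ear"] = df["amp_ear"] / cohort_max
    df["amp_finger"] = df["amp_finger"] / cohort_max
    return df


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def _sex_stats(df: pd.DataFrame, col: str) -> dict:
    out = {}
    for sex in ("F", "M"):
        vals = df.loc[df["sex"] == sex, col].dropna()
        out[sex] = {"mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals))}
    out["total"] = {"mean": float(df[col].mean()), "sd": float(df[col].std(ddof=1)),
                    "n": int(df[col].notna().sum())}
    return out


def summarize_cohort(per_subject: pd.DataFrame, paired_sex_test: bool = False) -> CohortSummary:
    """Compute cohort scalars from a fully populated per-subject table.

    Expected columns: ``subject_id, sex, age, heart_rate, resting_spo2_ear,
    resting_spo2_finger, amp_ear, amp_finger, amp_ratio, mean_delay_ear,
    mean_delay_finger, relative_delay``. Statistics whose sample-size
    requirements are not met are reported as NaN with a logged warning
    rather than failing the whole summary.
    """
    df = per_subject.copy()
    scalars: dict = {"n_subjects": int(len(df))}
    if df.empty:
        logger.warning("empty cohort: no scalar statistics computed")
        return CohortSummary(per_subject=df, scalars=scalars)
    if len(df) == 1:
        logger.warning("single-subject cohort: between-subject statistics are NaN")

    rms, mean = site_difference_summary(df["resting_spo2_ear"], df["resting_spo2_finger"])
    scalars["rms_site_diff"] = rms
    scalars["mean_site_diff"] = mean
    scalars["healthy_agreement"] = healthy_range_agreement(
        df["resting_spo2_ear"], df["resting_spo2_finger"])

    if "amp_ratio" in df:
        scalars["amp_ratio_mean"] = float(df["amp_ratio"].mean())
        scalars["amp_finger_by_sex"] = _sex_stats(df, "amp_finger")
        scalars["amp_ear_by_sex"] = _sex_stats(df, "amp_ear")

    for col in ("relative_delay", "mean_delay_ear", "mean_delay_finger"):
        if col in df:
            scalars[f"{col}_by_sex"] = _sex_stats(df, col)

    # sex comparison of delays
    f = df.loc[df["sex"] == "F", "relative_delay"].dropna()
    m = df.loc[df["sex"] == "M", "relative_delay"].dropna()
    try:
        stat, p = group_ttest(f, m, paired=paired_sex_test)
        scalars["sex_ttest_relative_delay"] = {"statistic": stat, "p": p,
                                               "paired": paired_sex_test}
    except (InvalidParameterError, UndefinedResultError) as e:
        logger.warning("sex t-test skipped: %s", e)
        scalars["sex_ttest_relative_delay"] = {"statistic": float("nan"),
                                               "p": float("nan"),
                                               "paired": paired_sex_test}

    def _corr(key, x, y):
        try:
            r, p = pearson(*_aligned(x, y))
            scalars[key] = {"r": r, "p": p}
        except InvalidParameterError as e:
            logger.warning("correlation %s skipped: %s", key, e)
            scalars[key] = {"r": float("nan"), "p": float("nan")}

    _corr("corr_age_relative_delay", df["age"], df["relative_delay"])
    if "heart_rate" in df:
        _corr("corr_hr_ear_delay", df["heart_rate"], df["mean_delay_ear"])
        _corr("corr_hr_finger_delay", df["heart_rate"], df["mean_delay_finger"])

    return CohortSummary(per_subject=df, scalars=scalars)


def _aligned(x: pd.Series, y: pd.Series):
    mask = x.notna() & y.notna()
    return x[mask].to_numpy(), y[mask].to_numpy()


def format_delay_table(scalars: dict) -> str:
    """Render the sex-stratified delay summary as an aligned text table."""
    rows = [("", "Relative", "Finger", "Ear Canal")]
    for label, key in (("Female", "F"), ("Male", "M"), ("Total", "total")):
        cells = [label]
        for col in ("relative_delay", "mean_delay_finger", "mean_delay_ear"):
            s = scalars.get(f"{col}_by_sex", {}).get(key, {})
            if s and np.isfinite(s.get("mean", float("nan"))):
                sd = s.get("sd", float("nan"))
                cells.append(f"{s['mean']:.2f} ± {sd:.2f}" if np.isfinite(sd)
                             else f"{s['mean']:.2f}")
            else:
                cells.append("--")
        rows.append(tuple(cells))
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip()
                     for r in rows)
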