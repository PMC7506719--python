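import math

import numpy as np
import pandas as pd
import pytest

from ppgox import (InvalidParameterError, UndefinedResultError, amplitude_summary,
                   format_delay_table, group_ttest, healthy_range_agreement,
                   pearson, resting_spo2, site_difference_summary,
                   summarize_cohort)
from conftest import make_spo2_series

FS = 100.0


def flat_series(level, duration=200.0):
    t = np.arange(0, duration, 1 / FS)
    return make_spo2_series(t, np.full_like(t, float(level)), FS)


class TestRestingSpO2:
    def test_constant_trace(self):
        assert resting_spo2(flat_series(98.0), first_press=120.0) == pytest.approx(98.0)

    def test_window_excludes_post_press_samples(self):
        t = np.arange(0, 200, 1 / FS)
        x = np.where(t < 120.0, 96.0, 90.0)
        sp = make_spo2_series(t, x, FS)
        assert resting_spo2(sp, first_press=120.0) == pytest.approx(96.0, abs=0.01)

    def test_linear_ramp_mean_oracle(self):
        t = np.arange(0, 200, 1 / FS)
        x = 95.0 + 2.0 * np.clip((t - 60.0) / 60.0, 0, None)  # 95 -> 97 over window
        sp = make_spo2_series(t, x, FS)
        # oracle: mean of a linear ramp is its midpoint value
        assert resting_spo2(sp, first_press=120.0) == pytest.approx(96.0, abs=0.01)

    def test_insufficient_pre_press_data(self):
        with pytest.raises(InvalidParameterError, match="60"):
            resting_spo2(flat_series(97.0), first_press=30.0)


class TestSiteDifference:
    def test_identical_vectors(self):
        assert site_difference_summary([96, 97, 98], [96, 97, 98]) == (0.0, 0.0)

    def test_constant_offset(self):
        rms, mean = site_difference_summary([97, 98, 99], [96, 97, 98])
        assert (rms, mean) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_plus_minus_one_oracle(self):
        rms, mean = site_difference_summary([97, 95], [96, 96])
        assert rms == pytest.approx(1.0)
        assert mean == pytest.approx(0.0)

    def test_sign_convention_ear_minus_finger(self):
        _, mean = site_difference_summary([97.0], [96.5])
        assert mean == pytest.approx(0.5)  # positive => higher in the ear

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            site_difference_summary([1, 2], [1, 2, 3])

    def test_rms_bounds_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ear = rng.normal(97, 1, 10)
            fin = rng.normal(97, 1, 10)
            rms, mean = site_difference_summary(ear, fin)
            assert rms >= abs(mean) - 1e-12


class TestHealthyAgreement:
    def test_all_in_range(self):
        assert healthy_range_agreement([95, 96], [97, 99]) == 1.0

    def test_disagreement_counted(self):
        assert healthy_range_agreement([93, 95], [95, 95]) == 0.5

    def test_both_out_of_range_is_agreement(self):
        assert healthy_range_agreement([92, 95], [93, 95]) == 1.0

    def test_closed_interval_boundaries(self):
        assert healthy_range_agreement([94.0, 100.0], [94.0, 100.0]) == 1.0


class TestGroupTTest:
    def test_identical_groups(self):
        stat, p = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, 4)
        b = 10 + rng.normal(0, 0.01, 4)
        _, p = group_ttest(a, b)
        assert p < 0.001

    def test_welch_matches_closed_form(self):
        # closed-form Welch t for n_a = n_b = 2 computed by hand
        a, b = np.array([1.0, 3.0]), np.array([6.0, 10.0])
        stat, _ = group_ttest(a, b)
        se = math.sqrt(np.var(a, ddof=1) / 2 + np.var(b, ddof=1) / 2)
        assert stat == pytest.approx((a.mean() - b.mean()) / se)

    def test_paired_mode_degenerate_differences(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedResultError):
            group_ttest(x, x + 5.0, paired=True)

    def test_insufficient_n(self):
        with pytest.raises(InvalidParameterError):
            group_ttest([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        r, _ = pearson([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            pearson([1, 1, 1], [1, 2, 3])


class TestAmplitudeSummary:
    @staticmethod
    def subject_series(amp_ear, amp_finger, duration=200.0):
        t = np.arange(0, duration, 1 / FS)
        out = {}
        for site, amp in (("ear", amp_ear), ("finger", amp_finger)):
            sp = make_spo2_series(t, np.full_like(t, 97.0), FS)
            env = type("E", (), {})()
            env.ac_amplitude = np.full_like(t, float(amp))
            sp.envelopes = {"infrared": env}
            out[site] = sp
        return out

    def test_single_subject_normalization(self):
        df = amplitude_summary({"S01": self.subject_series(300, 705)},
                               {"S01": 120.0})
        assert df["amp_finger"].iloc[0] == pytest.approx(1.0)
        assert df["amp_ear"].iloc[0] == pytest.approx(300 / 705)
        assert df["amp_ratio"].iloc[0] == pytest.approx(705 / 300)

    def test_identical_subjects_identical_rows(self):
        subj = {"S01": self.subject_series(300, 705),
                "S02": self.subject_series(300, 705)}
        df = amplitude_summary(subj, {"S01": 120.0, "S02": 120.0})
        assert df["amp_ear"].nunique() == 1 and df["amp_finger"].nunique() == 1

    def test_normalized_max_is_one(self):
        subj = {"S01": self.subject_series(200, 400),
                "S02": self.subject_series(350, 900)}
        df = amplitude_summary(subj, {"S01": 120.0, "S02": 120.0})
        assert max(df["amp_ear"].max(), df["amp_finger"].max()) == pytest.approx(1.0)
        assert (df[["amp_ear", "amp_finger"]] > 0).all().all()


class TestSummarize:
    def test_empty_cohort(self):
        summary = summarize_cohort(pd.DataFrame())
        assert summary.scalars["n_subjects"] == 0

    def test_delay_table_renders_all_rows(self):
        df = pd.DataFrame({
            "subject_id": ["S1", "S2", "S3", "S4"],
            "sex": ["F", "M", "F", "M"],
            "age": [20, 30, 25, 35],
            "heart_rate": [60, 70, 65, 75],
            "resting_spo2_ear": [97, 96, 98, 97],
            "resting_spo2_finger": [96, 96, 97, 97],
            "mean_delay_ear": [4, 5, 3, 6],
            "mean_delay_finger": [14, 18, 12, 20],
            "relative_delay": [10, 13, 9, 14],
        })
        summary = summarize_cohort(df)
        table = format_delay_table(summary.scalars)
        for label in ("Female", "Male", "Total", "Relative", "Ear Canal"):
            assert label in table
        assert summary.scalars["rms_site_diff"] >= abs(summary.scalars["mean_site_diff"])
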