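"""Day- and subject-level metrics, the outlier rule, daily TiB and Bland-Altman."""

import numpy as np
import pandas as pd
import pytest

from tibhip.evaluation import (
    DayReport,
    baseline_accuracy,
    bland_altman,
    build_day_reports,
    daily_tib_summary,
    day_metrics,
    flag_outliers,
    pooled_metrics,
    subject_summary,
)
from tibhip.io import MinuteSeries, split_noon_days

NOON = pd.Timestamp("2024-03-04T12:00:00")


def _report(subject, tib, acc=None, day=0):
    return DayReport(day_id=f"{subject}_d{day}", subject_id=subject,
                     predicted_tib=tib, accuracy=acc)


class TestDayMetrics:
    def test_perfect_prediction(self):
        labels = np.array([0, 1, 1, 0, 1])
        m = day_metrics(labels, labels)
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_zero_denominator_is_absent_not_zero(self):
        labels = np.zeros(10, dtype=int)
        m = day_metrics(np.zeros(10, dtype=int), labels)
        assert m["sensitivity"] is None
        assert m["accuracy"] == 1.0

    def test_confusion_arithmetic(self):
        # TP=420, TN=900, FP=60, FN=60
        labels = np.concatenate([np.ones(480), np.zeros(960)]).astype(int)
        pred = labels.copy()
        pred[:60] = 0  # 60 FN among the positives
        pred[480:540] = 1  # 60 FP among the negatives
        m = day_metrics(pred, labels)
        assert m["accuracy"] == pytest.approx(1320 / 1440)
        assert m["sensitivity"] == pytest.approx(420 / 480)
        assert m["specificity"] == pytest.approx(900 / 960)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            day_metrics(np.zeros(5), np.zeros(6))

    def test_prevalence_decomposition_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = (rng.random(500) < rng.random()).astype(int)
            pred = (rng.random(500) < rng.random()).astype(int)
            m = day_metrics(pred, labels)
            prev = labels.mean()
            if m["sensitivity"] is None or m["specificity"] is None:
                continue
            assert m["accuracy"] == pytest.approx(
                prev * m["sensitivity"] + (1 - prev) * m["specificity"]
            )

    def test_agrees_with_naive_loop(self):
        rng = np.random.default_rng(1)
        labels = (rng.random(200) < 0.3).astype(int)
        pred = (rng.random(200) < 0.5).astype(int)
        tp = sum(1 for p, l in zip(pred, labels) if p == 1 and l == 1)
        tn = sum(1 for p, l in zip(pred, labels) if p == 0 and l == 0)
        m = day_metrics(pred, labels)
        assert m["accuracy"] == pytest.approx((tp + tn) / 200)


class TestBaseline:
    def test_one_third_in_bed(self):
        labels = np.array([1, 0, 0] * 10)
        assert baseline_accuracy(labels) == pytest.approx(2 / 3)

    def test_all_out_of_bed(self):
        assert baseline_accuracy(np.zeros(50)) == 1.0

    def test_equals_all_zero_prediction_accuracy(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(300) < 0.4).astype(int)
        m = day_metrics(np.zeros(300, dtype=int), labels)
        assert baseline_accuracy(labels) == pytest.approx(m["accuracy"])


class TestOutlierRule:
    @pytest.mark.parametrize(
        "tib,expected",
        [(30, True), (59, True), (60, False), (61, False),
         (1380, False), (1381, True), (1440, True)],
    )
    def test_strict_boundaries(self, tib, expected):
        [r] = flag_outliers([_report("s1", tib)])
        assert r.outlier is expected

    def test_exclusion_never_decreases_accuracy_when_outliers_fail(self):
        # outlier days are constructed to be mispredicted entire days
        good = [_report("s1", 480, acc=0.95, day=i) for i in range(4)]
        bad = [_report("s1", 1440, acc=480 / 1440, day=9)]
        reports = flag_outliers(good + bad)
        accs = [r.accuracy for r in reports]
        kept = [r.accuracy for r in reports if not r.outlier]
        assert np.mean(kept) >= np.mean(accs)


class TestSubjectSummary:
    def test_single_subject_sd_absent(self):
        out = subject_summary([_report("s1", 480, acc=0.9)], "accuracy")
        assert out == {"mean": 0.9, "sd": None, "n_subjects": 1}

    def test_two_subject_mean(self):
        reports = [
            _report("s1", 480, acc=0.88, day=0),
            _report("s1", 480, acc=0.92, day=1),
            _report("s2", 480, acc=0.94, day=0),
        ]
        out = subject_summary(reports, "accuracy")
        assert out["mean"] == pytest.approx((0.90 + 0.94) / 2)
        assert out["n_subjects"] == 2

    def test_matches_brute_force_two_stage(self):
        rng = np.random.default_rng(3)
        reports = []
        for s in range(6):
            for d in range(int(rng.integers(1, 7))):
                reports.append(_report(f"s{s}", 480, acc=float(rng.random()),
                                       day=d))
        out = subject_summary(reports, "accuracy")
        per_subject = {}
        for r in reports:
            per_subject.setdefault(r.subject_id, []).append(r.accuracy)
        means = [float(np.mean(v)) for v in per_subject.values()]
        assert out["mean"] == pytest.approx(np.mean(means))
        assert out["sd"] == pytest.approx(np.std(means, ddof=1))


class TestDailyTib:
    def _windows(self, start, n_minutes, labels=None):
        return split_noon_days(MinuteSeries(start, np.zeros((n_minutes, 3)),
                                            labels=labels))

    def test_regular_nights(self):
        # recording noon -> noon over 5 full days, prediction 23:00-07:00
        windows = self._windows(NOON, 5 * 1440)
        tracks = []
        for w in windows:
            t = np.zeros(w.series.n_minutes, dtype=int)
            t[660:1140] = 1
            tracks.append(t)
        assert daily_tib_summary(windows, tracks) == pytest.approx(480)

    def test_partial_days_excluded(self):
        start = NOON - pd.Timedelta(hours=3)  # 09:00 start: first day partial
        windows = self._windows(start, 1440 + 180)
        tracks = [np.ones(w.series.n_minutes, dtype=int) for w in windows]
        assert daily_tib_summary(windows, tracks) == pytest.approx(1440)

    def test_zero_full_days_absent_with_warning(self):
        windows = self._windows(NOON, 600)
        with pytest.warns(UserWarning, match="no fully recorded"):
            assert daily_tib_summary(
                windows, [np.zeros(600, dtype=int)]) is None

    def test_matches_minute_raster_brute_force(self):
        rng = np.random.default_rng(4)
        windows = self._windows(NOON - pd.Timedelta(hours=5), 7 * 1440)
        tracks = [(rng.random(w.series.n_minutes) < 0.3).astype(int)
                  for w in windows]
        expected = np.mean([t.sum() for w, t in zip(windows, tracks) if w.full])
        assert daily_tib_summary(windows, tracks) == pytest.approx(expected)


class TestBlandAltman:
    def test_identical_estimates(self):
        out = bland_altman(np.array([600.0, 500.0]), np.array([600.0, 500.0]))
        assert out["bias"] == 0.0
        assert out["loa_low"] == 0.0 and out["loa_high"] == 0.0

    def test_hand_computed_pairs(self):
        out = bland_altman(np.array([600.0, 500.0]), np.array([580.0, 510.0]))
        assert out["bias"] == pytest.approx(5.0)
        np.testing.assert_allclose(out["differences"], [20.0, -10.0])

    def test_recovers_injected_constant_offset(self):
        rng = np.random.default_rng(6)
        truth = rng.uniform(400, 700, size=40)
        x = truth + rng.normal(0, 10, size=40) + 25.0
        y = truth + rng.normal(0, 10, size=40)
        out = bland_altman(x, y)
        assert out["bias"] == pytest.approx(25.0, abs=3 * 15 / np.sqrt(40))
        assert out["loa_low"] < 25.0 < out["loa_high"]


class TestBuildDayReports:
    def test_reports_align_with_windows(self):
        labels = np.zeros(2 * 1440, dtype=np.int8)
        labels[660:1140] = 1
        labels[1440 + 660:1440 + 1140] = 1
        series = MinuteSeries(NOON, np.zeros((2 * 1440, 3)), labels=labels)
        windows = split_noon_days(series)
        tracks = [w.series.labels.copy() for w in windows]
        tracks[1][:] = 1  # second day predicted fully in bed -> outlier
        reports = build_day_reports("s1", windows, tracks)
        assert len(reports) == 2
        assert reports[0].predicted_tib == 480 and not reports[0].outlier
        assert reports[1].predicted_tib == 1440 and reports[1].outlier
        assert reports[0].accuracy == 1.0
        assert reports[1].labelled_tib == 480

    def test_pooled_metrics_merge_days(self):
        rng = np.random.default_rng(7)
        labels = [(rng.random(100) < 0.4).astype(int) for _ in range(3)]
        preds = [(rng.random(100) < 0.5).astype(int) for _ in range(3)]
        pooled = pooled_metrics(preds, labels)
        direct = day_metrics(np.concatenate(preds), np.concatenate(labels))
        assert pooled == direct
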