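"""Day- and subject-level evaluation of time-in-bed predictions.

Covers per-day confusion metrics (accuracy / sensitivity / specificity with
in-bed as the positive class), the trivial always-out-of-bed baseline, the
outlier rule flagging days with less than 1 h or more than 23 h of predicted
TiB, non-wear stratification, daily TiB totals restricted to fully recorded
noon-to-noon days, and Bland–Altman method comparison of paired per-subject
estimates.

Pooled (all-minutes) and subject-level (two-stage averaged) summaries are both
provided, as they answer different questions and can differ when day counts
vary between subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence
import warnings

import numpy as np

from .io import DayWindow, IntervalSet
from .nonwear import nwt_minutes_per_day

__all__ = [
    "DayReport",
    "day_metrics",
    "baseline_accuracy",
    "flag_outliers",
    "subject_summary",
    "daily_tib_summary",
    "bland_altman",
    "build_day_reports",
    "pooled_metrics",
    "OUTLIER_LOW_MIN",
    "OUTLIER_HIGH_MIN",
]

OUTLIER_LOW_MIN = 60  # < 1 h predicted TiB
OUTLIER_HIGH_MIN = 1380  # > 23 h predicted TiB


@dataclass(frozen=True)
class DayReport:
    """Per-24h-day prediction summary."""

    day_id: str
    subject_id: str
    predicted_tib: int  # minutes
    labelled_tib: int | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    outlier: bool = False
    nwt_minutes: int = 0
    full_day: bool = True


def day_metrics(pred: np.ndarray,
                labels: np.ndarray) -> dict[str, float | None]:
    """Accuracy, sensitivity and specificity of a binary minute track.

    Positive class is *in bed*. Ratios with a zero denominator are returned as
    ``None`` (absent), never as 0.
    """
    pred = np.asarray(pred).astype(np.int8)
    labels = np.asarray(labels).astype(np.int8)
    if pred.shape != labels.shape:
        raise ValueError("prediction and label tracks differ in length")
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / n if n else None,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
    }


def baseline_accuracy(labels: np.ndarray) -> float:
    """Accuracy of always answering "out of bed": the out-of-bed fraction."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    return float((labels == 0).mean())


def flag_outliers(reports: Iterable[DayReport]) -> list[DayReport]:
    """Flag days with predicted TiB < 60 min or > 1380 min (strict bounds)."""
    return [
        replace(r, outlier=(r.predicted_tib < OUTLIER_LOW_MIN
                            or r.predicted_tib > OUTLIER_HIGH_MIN))
        for r in reports
    ]


def subject_summary(reports: Iterable[DayReport],
                    metric: str) -> dict[str, float | None]:
    """Two-stage between-subject summary of a day-level metric.

    First average the metric over each subject's scored days, then report the
    mean and SD of those per-subject means across subjects. SD is ``None``
    with a single subject.
    """
    per_subject: dict[str, list[float]] = {}
    for r in reports:
        v = getattr(r, metric)
        if v is not None:
            per_subject.setdefault(r.subject_id, []).append(float(v))
    if not per_subject:
        raise ValueError(f"no day reports carry metric {metric!r}")
    means = np.array([np.mean(v) for v in per_subject.values()])
    return {
        "mean": float(means.mean()),
        "sd": float(means.std(ddof=1)) if means.size > 1 else None,
        "n_subjects": int(means.size),
    }


def daily_tib_summary(day_windows: Sequence[DayWindow],
                      pred_tracks: Sequence[np.ndarray]) -> float | None:
    """Mean daily predicted TiB (minutes) over fully recorded days only.

    Partial first/last days are excluded; with no full days the summary is
    absent (``None``) with a warning.
    """
    totals = []
    for w, track in zip(day_windows, pred_tracks):
        if not w.full:
            continue
        track = np.asarray(track)
        if track.shape[0] != w.series.n_minutes:
            raise ValueError("prediction track does not match the day window")
        totals.append(int(track.sum()))
    if not totals:
        warnings.warn("no fully recorded days; daily TiB summary is undefined")
        return None
    return float(np.mean(totals))


def bland_altman(x: np.ndarray, y: np.ndarray) -> dict:
    """Bland–Altman comparison of paired per-subject estimates.

    Returns per-pair means and differences (``x - y``), the bias (mean
    difference) and the 95% limits of agreement ``bias ± 1.96 sd(diff)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-d arrays")
    diff = x - y
    mean = (x + y) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return {
        "means": mean,
        "differences": diff,
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


def build_day_reports(subject_id: str,
                      day_windows: Sequence[DayWindow],
                      pred_tracks: Sequence[np.ndarray],
                      nwt: IntervalSet | None = None) -> list[DayReport]:
    """Assemble per-day reports from noon-day windows and prediction tracks.

    Metrics are filled only for windows whose series carry labels; the
    outlier rule is applied to full days.
    """
    reports = []
    for i, (w, track) in enumerate(zip(day_windows, pred_tracks)):
        track = np.asarray(track).astype(np.int8)
        if track.shape[0] != w.series.n_minutes:
            raise ValueError("prediction track does not match the day window")
        labels = w.series.labels
        metrics = (day_metrics(track, labels) if labels is not None
                   else {"accuracy": None, "sensitivity": None,
                         "specificity": None})
        nwt_min = (nwt_minutes_per_day(nwt, w.start, w.start + np.timedelta64(1, "D"))
                   if nwt is not None and len(nwt) else 0)
        r = DayReport(
            day_id=f"{subject_id}_d{i:02d}",
            subject_id=subject_id,
            predicted_tib=int(track.sum()),
            labelled_tib=None if labels is None else int(labels.sum()),
            accuracy=metrics["accuracy"],
            sensitivity=metrics["sensitivity"],
            specificity=metrics["specificity"],
            nwt_minutes=int(nwt_min),
            full_day=w.full,
        )
        reports.append(r)
    full = [r for r in reports if r.full_day]
    flagged = {r.day_id: r for r in flag_outliers(full)}
    return [flagged.get(r.day_id, r) for r in reports]


def pooled_metrics(pred_tracks: Sequence[np.ndarray],
                   label_tracks: Sequence[np.ndarray]) -> dict[str, float | None]:
    """Minute-pooled metrics over many days/subjects (single confusion table)."""
    pred = np.concatenate([np.asarray(p).ravel() for p in pred_tracks])
    labels = np.concatenate([np.asarray(l).ravel() for l in label_tracks])
    return day_metrics(pred, labels)
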