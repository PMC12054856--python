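"""End-to-end convenience pipeline over a synthetic cohort.

Stitches the stages together in the canonical order — calibrate the raw trace,
aggregate to minutes, fit the normalizer on the training subjects, train the
LSTM with augmentation, and score held-out subjects — so that examples,
the CLI and the acceptance checks all exercise one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentationConfig
from .calibration import calibrate
from .evaluation import pooled_metrics, baseline_accuracy
from .io import MinuteSeries, to_minutes
from .model import ModelConfig, TrainedModel, predict, train
from .preprocess import NormalizationStats, apply_normalizer, fit_normalizer
from .synthetic import SimConfig, SimRecording, simulate_cohort

__all__ = ["EndToEndResult", "labelled_minutes", "run_end_to_end"]


@dataclass
class EndToEndResult:
    model: TrainedModel
    stats: NormalizationStats
    test_accuracy: float
    test_sensitivity: float | None
    test_specificity: float | None
    baseline: float
    per_subject_accuracy: list[float]


def labelled_minutes(rec: SimRecording, apply_calibration: bool = True) -> MinuteSeries:
    """Calibrated, truth-labelled minute series for one simulated subject."""
    trace = rec.trace
    if apply_calibration:
        trace, _ = calibrate(trace)
    ms = to_minutes(trace)
    return MinuteSeries(ms.start_minute, ms.values,
                        labels=rec.truth_labels[: ms.n_minutes])


def run_end_to_end(sim_config: SimConfig,
                   model_config: ModelConfig,
                   aug_config: AugmentationConfig | None = None,
                   n_test_subjects: int = 15,
                   apply_calibration: bool = True) -> EndToEndResult:
    """Simulate, preprocess, train and evaluate on held-out subjects.

    The last ``n_test_subjects`` of the cohort are held out; the normalizer is
    fitted on the training subjects only and frozen for the test subjects.
    """
    cohort = simulate_cohort(sim_config)
    if n_test_subjects >= len(cohort) - 1:
        raise ValueError("need at least 2 training subjects after the holdout")
    series = [labelled_minutes(r, apply_calibration) for r in cohort]
    train_series = series[: len(series) - n_test_subjects]
    test_series = series[len(series) - n_test_subjects:]
    stats = fit_normalizer(train_series, source="e2e_train")
    train_norm = [apply_normalizer(s, stats) for s in train_series]
    model = train(train_norm, model_config, aug_config)
    pred_tracks, label_tracks, per_subject = [], [], []
    for s in test_series:
        sn = apply_normalizer(s, stats)
        _, track = predict(model, sn)
        pred_tracks.append(track)
        label_tracks.append(s.labels)
        per_subject.append(float((track == s.labels).mean()))
    pooled = pooled_metrics(pred_tracks, label_tracks)
    base = baseline_accuracy(np.concatenate(label_tracks))
    return EndToEndResult(
        model=model,
        stats=stats,
        test_accuracy=pooled["accuracy"],
        test_sensitivity=pooled["sensitivity"],
        test_specificity=pooled["specificity"],
        baseline=base,
        per_subject_accuracy=per_subject,
    )
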