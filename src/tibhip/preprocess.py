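"""Cohort-level z-normalization of per-minute acceleration series.

The sequence model consumes standardized inputs: per-axis mean and standard
deviation are pooled over every minute of every subject in the fitting cohort,
then frozen and applied unchanged to validation/test data (the statistics carry
a content hash so the training harness can verify that no validation data
leaked into them).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np

from .io import MinuteSeries

__all__ = [
    "NormalizationStats",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
]


class DegenerateCohortError(ValueError):
    """A pooled axis has zero variance; z-scores would be undefined."""


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled per-axis mean/sd (in g) of a fitting cohort, with provenance."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,)
    n_minutes: int
    source: str = "unknown"

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64)
        sd = np.asarray(self.sd, dtype=np.float64)
        if mean.shape != (3,) or sd.shape != (3,):
            raise ValueError("mean and sd must be length-3 vectors")
        if np.any(sd <= 0):
            raise ValueError("per-axis sd must be positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    @property
    def stats_hash(self) -> str:
        payload = np.round(np.concatenate([self.mean, self.sd]), 12).tobytes()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "n_minutes": self.n_minutes,
                "source": self.source,
                "hash": self.stats_hash,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(np.array(d["mean"]), np.array(d["sd"]),
                   d["n_minutes"], d.get("source", "unknown"))


def fit_normalizer(cohort: list[MinuteSeries],
                   source: str = "cohort") -> NormalizationStats:
    """Pool per-axis mean and sd over every minute of every series.

    The sd is the population standard deviation (ddof=0) of the pooled minutes.
    Raises :class:`DegenerateCohortError` if any axis has zero pooled variance.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if any(s.normalized for s in cohort):
        raise ValueError("fit_normalizer expects unnormalized series")
    pooled = np.concatenate([s.values for s in cohort], axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled minutes")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [ax for ax, v in zip("xyz", sd) if v == 0]
        raise DegenerateCohortError(
            f"zero pooled variance on axis/axes {bad}; cohort is degenerate"
        )
    return NormalizationStats(mean, sd, pooled.shape[0], source)


def apply_normalizer(series: MinuteSeries,
                     stats: NormalizationStats) -> MinuteSeries:
    """Standardize per axis: ``v' = (v - mean) / sd``. Labels are untouched."""
    if series.normalized:
        raise ValueError("series is already normalized (double-normalization guard)")
    values = (series.values - stats.mean) / stats.sd
    return replace(series, values=values, normalized=True,
                   norm_ref=stats.stats_hash)


def invert_normalizer(series: MinuteSeries,
                      stats: NormalizationStats) -> MinuteSeries:
    """Undo :func:`apply_normalizer`, restoring values in g."""
    if not series.normalized:
        raise ValueError("series is not normalized")
    if series.norm_ref is not None and series.norm_ref != stats.stats_hash:
        raise ValueError("stats hash mismatch: wrong NormalizationStats")
    values = series.values * stats.sd + stats.mean
    return replace(series, values=values, normalized=False, norm_ref=None)
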