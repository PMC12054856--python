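"""Inter-annotator agreement and quality control for time-in-bed annotations.

Two annotators independently mark bed and rise times as interval sets.
Agreement is scored by intersection over union (IoU) in continuous time:
the total duration both marked as in bed divided by the total duration at
least one marked as in bed. Recordings with IoU strictly above a cut-off
(0.9 by default) are kept, and their consensus labels are the intersection of
the two annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet, rasterize

__all__ = ["iou", "iou_rasterized", "qc_filter", "QCRecord"]


def iou(a: IntervalSet, b: IntervalSet) -> float:
    """Continuous-time intersection-over-union of two interval sets.

    Both sets empty is defined as perfect (vacuous) agreement, 1.0.
    """
    inter = a.intersect(b).total_seconds()
    union = a.union(b).total_seconds()
    if union == 0:
        return 1.0
    return inter / union


def iou_rasterized(a: IntervalSet, b: IntervalSet, start, n_minutes: int) -> float:
    """Minute-raster cross-check of :func:`iou` via set arithmetic on tracks."""
    ra = rasterize(a, start, n_minutes).astype(bool)
    rb = rasterize(b, start, n_minutes).astype(bool)
    union = (ra | rb).sum()
    if union == 0:
        return 1.0
    return float((ra & rb).sum() / union)


@dataclass(frozen=True)
class QCRecord:
    """One recording's agreement outcome."""

    recording_id: str
    iou: float
    kept: bool
    consensus: IntervalSet | None  # a ∩ b when kept, else None


def qc_filter(pairs: list[tuple[IntervalSet, IntervalSet]],
              threshold: float = 0.9,
              ids: list[str] | None = None) -> list[QCRecord]:
    """Keep pairs with IoU strictly above ``threshold``; consensus = a ∩ b.

    The strict inequality means a recording at exactly the threshold is
    excluded.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if ids is None:
        ids = [f"R{i:03d}" for i in range(len(pairs))]
    out = []
    for rid, (a, b) in zip(ids, pairs):
        score = iou(a, b)
        kept = score > threshold
        out.append(QCRecord(rid, score, kept, a.intersect(b) if kept else None))
    return out
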