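"""Non-wear time (NWT) detection from the raw acceleration signal.

A device lying on a table produces an almost perfectly still signal. NWT is
detected with the sliding-window variability criterion: a 60 min window,
advanced in 15 min steps, is flagged as non-wear if for at least 2 of the 3
axes the per-axis standard deviation is less than 3 mg *or* the per-axis value
range (max - min) is less than 50 mg. Flagged windows are unioned and merged
into maximal intervals. Detection runs on the raw-rate trace, never on
per-minute aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .io import IntervalSet, RawTrace, rasterize

__all__ = ["NWTConfig", "detect_nonwear", "nwt_minutes_per_day"]


@dataclass(frozen=True)
class NWTConfig:
    window_minutes: int = 60
    slide_minutes: int = 15
    sd_threshold_mg: float = 3.0
    range_threshold_mg: float = 50.0
    axes_required: int = 2

    def __post_init__(self):
        if self.slide_minutes > self.window_minutes:
            raise ValueError("slide must not exceed the window length")
        if self.sd_threshold_mg <= 0 or self.range_threshold_mg <= 0:
            raise ValueError("thresholds must be positive")
        if self.axes_required not in (1, 2, 3):
            raise ValueError("axes_required must be 1, 2 or 3")
        if self.window_minutes < 1 or self.slide_minutes < 1:
            raise ValueError("window and slide must be at least one minute")


def detect_nonwear(trace: RawTrace,
                   config: NWTConfig | None = None) -> IntervalSet:
    """Flag still windows and merge them into maximal non-wear intervals.

    Per window and axis the criterion is ``sd < sd_threshold`` OR
    ``range < range_threshold`` (strict comparisons); the window is non-wear
    when at least ``axes_required`` axes satisfy it. A trace shorter than one
    window yields an empty set with a warning.
    """
    if config is None:
        config = NWTConfig()
    w = int(round(config.window_minutes * 60 * trace.sample_rate))
    step = int(round(config.slide_minutes * 60 * trace.sample_rate))
    if trace.n_samples < w:
        warnings.warn("trace shorter than one non-wear window; nothing detected")
        return IntervalSet.empty()
    sd_thr = config.sd_threshold_mg / 1000.0
    rg_thr = config.range_threshold_mg / 1000.0
    # windowed view: (n_windows, w, 3)
    view = np.lib.stride_tricks.sliding_window_view(
        trace.samples, (w, 3)
    )[::step, 0]
    sds = view.std(axis=1, ddof=0)
    rngs = view.max(axis=1) - view.min(axis=1)
    ok = (sds < sd_thr) | (rngs < rg_thr)
    flagged = ok.sum(axis=1) >= config.axes_required
    if not flagged.any():
        return IntervalSet.empty()
    start_ns = trace.start_time.value
    step_ns = int(round(1e9 / trace.sample_rate))
    idx = np.flatnonzero(flagged)
    pairs = []
    for i in idx:
        s = start_ns + i * step * step_ns
        e = s + w * step_ns
        pairs.append((s, e))
    # union overlapping flagged windows
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return IntervalSet(
        np.array([m[0] for m in merged], dtype=np.int64).astype("datetime64[ns]"),
        np.array([m[1] for m in merged], dtype=np.int64).astype("datetime64[ns]"),
    )


def nwt_minutes_per_day(nwt: IntervalSet, day_start, day_end=None) -> int:
    """Whole minutes of a day window covered by non-wear intervals.

    A minute counts as non-wear iff its midpoint lies inside an NWT interval
    (the same midpoint rule used for rasterization); a day "contains NWT" iff
    the returned count is positive.
    """
    day_start = pd.Timestamp(day_start)
    if day_end is None:
        day_end = day_start + pd.Timedelta(days=1)
    else:
        day_end = pd.Timestamp(day_end)
    n_minutes = int((day_end - day_start) / pd.Timedelta(minutes=1))
    if n_minutes < 1:
        raise ValueError("day window must span at least one minute")
    return int(rasterize(nwt, day_start, n_minutes).sum())
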