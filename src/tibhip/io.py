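"""Containers and I/O for accelerometer traces, per-minute series and interval sets.

Three in-memory types carry the data through the pipeline:

``RawTrace``
    A uniformly sampled tri-axial acceleration signal in gravitational units (g).
``MinuteSeries``
    The per-minute aggregation the sequence model consumes, optionally with a
    per-minute binary in-bed label track and a normalization provenance tag.
``IntervalSet``
    An ordered set of non-overlapping half-open ``[start, end)`` time intervals,
    used for annotations, predictions and non-wear episodes alike.

All timestamps are timezone-naive local time; daylight-saving transitions are a
documented limitation. On-disk formats are plain CSV (see the ``read_*`` /
``write_*`` functions); readers tolerate comment lines starting with ``#``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RawTrace",
    "MinuteSeries",
    "IntervalSet",
    "DayWindow",
    "FormatError",
    "read_trace",
    "write_trace",
    "read_intervals",
    "write_intervals",
    "read_labels",
    "write_labels",
    "to_minutes",
    "rasterize",
    "intervals_from_track",
    "split_noon_days",
]

_NS_PER_S = 1_000_000_000
_NS_PER_MIN = 60 * _NS_PER_S


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def _as_ts(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts.tzinfo is not None:
        raise ValueError("timestamps must be timezone-naive local time")
    return ts


@dataclass(frozen=True)
class RawTrace:
    """Uniformly sampled tri-axial acceleration in g."""

    start_time: pd.Timestamp
    sample_rate: float  # Hz
    samples: np.ndarray  # shape (n, 3), float64, units of g

    def __post_init__(self):
        object.__setattr__(self, "start_time", _as_ts(self.start_time))
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.isfinite(samples).all():
            raise ValueError("samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def timestamps(self) -> pd.DatetimeIndex:
        step_ns = int(round(_NS_PER_S / self.sample_rate))
        start = self.start_time.value
        return pd.DatetimeIndex(start + step_ns * np.arange(self.n_samples))


@dataclass(frozen=True)
class MinuteSeries:
    """Per-minute tri-axial values with an optional per-minute binary label track.

    ``values`` are in g before normalization and in z-units afterwards
    (``normalized`` flag; ``norm_ref`` carries the hash of the statistics used).
    """

    start_minute: pd.Timestamp
    values: np.ndarray  # (n, 3)
    labels: np.ndarray | None = None  # (n,) in {0, 1}
    normalized: bool = False
    norm_ref: str | None = None

    def __post_init__(self):
        start = _as_ts(self.start_minute).floor("min")
        object.__setattr__(self, "start_minute", start)
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("values must have shape (n, 3)")
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (values.shape[0],):
                raise ValueError("labels must match values length")
            if not np.isin(labels, (0, 1)).all():
                raise ValueError("labels must be binary")
            object.__setattr__(self, "labels", labels.astype(np.int8))

    @property
    def n_minutes(self) -> int:
        return self.values.shape[0]

    def minute_starts(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            self.start_minute.value + _NS_PER_MIN * np.arange(self.n_minutes)
        )

    def slice(self, i: int, j: int) -> "MinuteSeries":
        """Sub-series covering minutes ``[i, j)``."""
        return replace(
            self,
            start_minute=pd.Timestamp(self.start_minute.value + i * _NS_PER_MIN),
            values=self.values[i:j],
            labels=None if self.labels is None else self.labels[i:j],
        )


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, non-overlapping, half-open ``[start, end)`` time intervals."""

    starts: np.ndarray  # datetime64[ns]
    ends: np.ndarray  # datetime64[ns]

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype="datetime64[ns]")
        ends = np.asarray(self.ends, dtype="datetime64[ns]")
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError("starts and ends must be 1-d arrays of equal length")
        if np.any(starts >= ends):
            raise ValueError("each interval must satisfy start < end")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("intervals must be sorted and non-overlapping")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "IntervalSet":
        pairs = [(np.datetime64(_as_ts(s)), np.datetime64(_as_ts(e))) for s, e in pairs]
        pairs.sort()
        return cls(
            np.array([p[0] for p in pairs], dtype="datetime64[ns]"),
            np.array([p[1] for p in pairs], dtype="datetime64[ns]"),
        )

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(
            np.array([], dtype="datetime64[ns]"), np.array([], dtype="datetime64[ns]")
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for s, e in zip(self.starts, self.ends):
            yield pd.Timestamp(s), pd.Timestamp(e)

    def total_seconds(self) -> float:
        return float((self.ends - self.starts).astype("timedelta64[ns]")
                     .astype(np.int64).sum()) / _NS_PER_S

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Interval-set intersection, computed by a two-pointer sweep."""
        out = []
        i = j = 0
        while i < len(self) and j < len(other):
            s = max(self.starts[i], other.starts[j])
            e = min(self.ends[i], other.ends[j])
            if s < e:
                out.append((s, e))
            if self.ends[i] <= other.ends[j]:
                i += 1
            else:
                j += 1
        if not out:
            return IntervalSet.empty()
        return IntervalSet(
            np.array([p[0] for p in out]), np.array([p[1] for p in out])
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        """Merged union of both interval sets."""
        starts = np.concatenate([self.starts, other.starts])
        ends = np.concatenate([self.ends, other.ends])
        if len(starts) == 0:
            return IntervalSet.empty()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        merged = [(starts[0], ends[0])]
        for s, e in zip(starts[1:], ends[1:]):
            ls, le = merged[-1]
            if s <= le:
                merged[-1] = (ls, max(le, e))
            else:
                merged.append((s, e))
        return IntervalSet(
            np.array([p[0] for p in merged]), np.array([p[1] for p in merged])
        )

    def overlap_seconds(self, start, end) -> float:
        """Total overlap of this set with the single window ``[start, end)``."""
        s = np.datetime64(_as_ts(start))
        e = np.datetime64(_as_ts(end))
        lo = np.maximum(self.starts, s)
        hi = np.minimum(self.ends, e)
        dur = (hi - lo).astype("timedelta64[ns]").astype(np.int64)
        return float(dur[dur > 0].sum()) / _NS_PER_S


@dataclass(frozen=True)
class DayWindow:
    """One noon-anchored 24 h window of a recording."""

    start: pd.Timestamp
    series: MinuteSeries
    full: bool


# ---------------------------------------------------------------------------
# CSV dialects


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trace(path) -> RawTrace:
    """Read a raw trace CSV with columns ``timestamp_iso8601,x_g,y_g,z_g``.

    The sampling grid must be uniform; the first irregular row is reported.
    """
    df = _read_csv(path)
    required = ["timestamp_iso8601", "x_g", "y_g", "z_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least two samples to infer the rate")
    ts = pd.to_datetime(df["timestamp_iso8601"]).to_numpy("datetime64[ns]")
    gaps = np.diff(ts).astype(np.int64)
    bad = np.flatnonzero(gaps <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: non-monotone timestamp at data row {int(bad[0]) + 1}"
        )
    step = int(np.median(gaps))
    irregular = np.flatnonzero(np.abs(gaps - step) > max(1, step // 1000))
    if irregular.size:
        row = int(irregular[0]) + 1
        raise FormatError(
            f"{path}: irregular sampling gap at data row {row} "
            f"({gaps[irregular[0]] / _NS_PER_S:.3f} s vs expected {step / _NS_PER_S:.3f} s)"
        )
    samples = df[["x_g", "y_g", "z_g"]].to_numpy(np.float64)
    return RawTrace(pd.Timestamp(ts[0]), _NS_PER_S / step, samples)


def write_trace(trace: RawTrace, path) -> None:
    """Write a trace CSV; values are rounded to 6 decimal places in g."""
    df = pd.DataFrame(
        {
            "timestamp_iso8601": trace.timestamps().strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x_g": trace.samples[:, 0],
            "y_g": trace.samples[:, 1],
            "z_g": trace.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_intervals(path) -> IntervalSet:
    df = _read_csv(path)
    required = ["start_iso8601", "end_iso8601"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        return IntervalSet.empty()
    return IntervalSet.from_pairs(
        zip(pd.to_datetime(df["start_iso8601"]), pd.to_datetime(df["end_iso8601"]))
    )


def write_intervals(intervals: IntervalSet, path) -> None:
    pd.DataFrame(
        {
            "start_iso8601": pd.DatetimeIndex(intervals.starts).strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "end_iso8601": pd.DatetimeIndex(intervals.ends).strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
        }
    ).to_csv(path, index=False)


def read_labels(path) -> tuple[pd.Timestamp, np.ndarray]:
    """Read a per-minute label CSV (``minute_start_iso8601,in_bed``)."""
    df = _read_csv(path)
    required = ["minute_start_iso8601", "in_bed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    start = pd.Timestamp(df["minute_start_iso8601"].iloc[0])
    return start, df["in_bed"].to_numpy(np.int8)


def write_labels(start_minute: pd.Timestamp, labels: np.ndarray, path) -> None:
    idx = pd.Timestamp(start_minute).value + _NS_PER_MIN * np.arange(len(labels))
    pd.DataFrame(
        {
            "minute_start_iso8601": pd.DatetimeIndex(idx).strftime("%Y-%m-%dT%H:%M"),
            "in_bed": np.asarray(labels, dtype=np.int8),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resampling and rasterization


def to_minutes(trace: RawTrace) -> MinuteSeries:
    """Aggregate a raw trace to one tri-axial value per minute.

    The per-minute value is the per-axis arithmetic mean of all samples whose
    timestamp falls in ``[minute, minute + 1 min)``. Partial leading and trailing
    minutes are dropped, so the output covers exactly the whole minutes fully
    inside the recording.
    """
    step_ns = int(round(_NS_PER_S / trace.sample_rate))
    start_ns = trace.start_time.value
    end_ns = start_ns + step_ns * trace.n_samples  # exclusive end of coverage
    first_minute = -(-start_ns // _NS_PER_MIN) * _NS_PER_MIN  # ceil to minute
    n_minutes = (end_ns - first_minute) // _NS_PER_MIN
    if n_minutes < 1:
        raise ValueError("trace does not span a full minute")
    # sample index range per minute, on the uniform grid
    minute_edges = first_minute + _NS_PER_MIN * np.arange(n_minutes + 1)
    idx = np.ceil((minute_edges - start_ns) / step_ns).astype(np.int64)
    idx = np.clip(idx, 0, trace.n_samples)
    csum = np.concatenate(
        [np.zeros((1, 3)), np.cumsum(trace.samples, axis=0)]
    )
    counts = np.diff(idx)
    if np.any(counts == 0):
        raise ValueError("sampling rate too low: a minute contains no samples")
    sums = csum[idx[1:]] - csum[idx[:-1]]
    values = sums / counts[:, None]
    return MinuteSeries(pd.Timestamp(first_minute), values)


def rasterize(intervals: IntervalSet, start, n_minutes: int) -> np.ndarray:
    """Minute-rasterize an interval set: minute ``m`` is 1 iff the midpoint of
    ``[m, m + 1 min)`` lies inside any interval."""
    if n_minutes < 1:
        raise ValueError("n_minutes must be >= 1")
    start_ns = _as_ts(start).floor("min").value
    mids = start_ns + _NS_PER_MIN * np.arange(n_minutes) + _NS_PER_MIN // 2
    track = np.zeros(n_minutes, dtype=np.int8)
    if len(intervals) == 0:
        return track
    s = intervals.starts.astype(np.int64)
    e = intervals.ends.astype(np.int64)
    # midpoint is inside iff the number of starts <= mid exceeds ends <= mid
    inside = np.searchsorted(s, mids, side="right") > np.searchsorted(
        e, mids, side="right"
    )
    track[inside] = 1
    return track


def intervals_from_track(track: np.ndarray, start) -> IntervalSet:
    """Inverse of :func:`rasterize`: merge runs of consecutive 1-minutes into
    minute-aligned intervals."""
    track = np.asarray(track).astype(np.int8)
    start_ns = _as_ts(start).floor("min").value
    if track.size == 0 or not track.any():
        return IntervalSet.empty()
    padded = np.concatenate([[0], track, [0]])
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    starts = (start_ns + run_starts * _NS_PER_MIN).astype("datetime64[ns]")
    ends = (start_ns + run_ends * _NS_PER_MIN).astype("datetime64[ns]")
    return IntervalSet(starts, ends)


def split_noon_days(series: MinuteSeries, anchor_hour: int = 12) -> list[DayWindow]:
    """Split a minute series into noon-to-noon 24 h day windows.

    Windows start at local ``anchor_hour``:00. A window is *full* iff all 1440
    minutes are present in the series; the first/last partial windows are
    returned flagged ``full=False``.
    """
    if series.n_minutes == 0:
        raise ValueError("series is empty")
    first = series.start_minute
    anchor = first.normalize() + pd.Timedelta(hours=anchor_hour)
    if anchor > first:
        anchor -= pd.Timedelta(days=1)
    end = pd.Timestamp(series.start_minute.value + series.n_minutes * _NS_PER_MIN)
    windows: list[DayWindow] = []
    while anchor < end:
        w_end = anchor + pd.Timedelta(days=1)
        i = max(0, (anchor.value - first.value) // _NS_PER_MIN)
        j = min(series.n_minutes, (w_end.value - first.value) // _NS_PER_MIN)
        sub = series.slice(int(i), int(j))
        windows.append(DayWindow(anchor, sub, full=(j - i) == 1440))
        anchor = w_end
    return windows
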