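"""Synthetic multi-day hip-accelerometer recordings with ground-truth time in bed.

The generator emulates the structure of free-living recordings from a hip-worn
tri-axial accelerometer under a 24 h wear protocol:

* **In bed** — the device reads a near-constant unit gravity vector in one of a
  small set of lying orientations, plus low-amplitude rest noise; positional
  turns are instantaneous re-orientations at Poisson-distributed times.
* **Out of bed** — a quiet upright orientation interleaved with Poisson-timed
  activity bursts whose amplitude is far above rest noise.
* **Non-wear** — the device sits on a table: an exactly constant signal (an
  optional sub-threshold jitter can be enabled for robustness tests).

Each simulated subject comes with per-minute ground-truth labels, the
continuous truth intervals, any non-wear episodes, and two "annotator" interval
tracks derived from the truth by Gaussian jitter of the interval boundaries
only — no interval is invented or dropped, so inter-annotator agreement is
controlled by a single parameter.

All randomness flows from one seed: subject ``i`` draws from
``SeedSequence(seed, spawn_key=(i,))``, so subjects are mutually independent
and individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    IntervalSet,
    MinuteSeries,
    RawTrace,
    intervals_from_track,
    rasterize,
    write_intervals,
    write_labels,
    write_trace,
)

__all__ = ["SimConfig", "SimRecording", "simulate_subject", "simulate_cohort",
           "write_recording", "REGIME_OUT", "REGIME_BED", "REGIME_NONWEAR",
           "REGIME_BURST"]

# per-sample regime codes (generator-internal ground truth, useful as an oracle)
REGIME_OUT = 0
REGIME_BED = 1
REGIME_NONWEAR = 2
REGIME_BURST = 3

_UPRIGHT = np.array([0.0, -1.0, 0.0])
_LYING = np.array(
    [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]
)
_TABLE = np.array([0.0, 0.0, 1.0])  # device flat on a table during non-wear


def _clock_minutes(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Times are clock strings (``"23:00"``), durations in minutes, rates in
    events per hour, noise levels in g. The default week-long recording at
    1 Hz mirrors a 7-day wear protocol at desk scale; downstream operators
    read the rate from the data, never assume it.
    """

    n_subjects: int = 5
    days_per_subject: int = 7
    sample_rate: float = 1.0  # Hz
    bed_time_mean: str = "23:00"
    bed_time_sd: float = 30.0  # minutes
    rise_time_mean: str = "07:00"
    rise_time_sd: float = 30.0  # minutes
    turn_rate: float = 2.0  # turns/hour while in bed
    activity_burst_rate: float = 6.0  # bursts/hour while out of bed
    activity_noise_sd: float = 0.25  # g, during bursts
    rest_noise_sd: float = 0.010  # g, whenever the device is worn
    nonwear_prob_per_day: float = 0.0
    nonwear_duration: tuple[float, float] = (90.0, 180.0)  # minutes
    nonwear_jitter_sd: float = 0.0  # g; 0 = perfectly constant non-wear
    miscalibration: tuple[tuple[float, float, float],
                          tuple[float, float, float]] | None = None  # (gain, offset_g)
    annotator_jitter_sd: float = 5.0  # minutes
    start_time: str = "2024-03-04T12:00:00"  # recordings are noon-anchored
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.days_per_subject < 1:
            raise ValueError("n_subjects and days_per_subject must be >= 1")
        if self.sample_rate < 1 / 60:
            raise ValueError("sample_rate must give at least one sample per minute")
        for name in ("bed_time_sd", "rise_time_sd", "turn_rate",
                     "activity_burst_rate", "activity_noise_sd", "rest_noise_sd",
                     "annotator_jitter_sd", "nonwear_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.nonwear_prob_per_day <= 1:
            raise ValueError("nonwear_prob_per_day must be a probability")
        lo, hi = self.nonwear_duration
        if not 0 < lo <= hi:
            raise ValueError("nonwear_duration must be a positive (lo, hi) range")
        bed = (_clock_minutes(self.bed_time_mean) - 720) % 1440
        rise = (_clock_minutes(self.rise_time_mean) - 720) % 1440
        if not bed < rise:
            raise ValueError(
                "bed/rise times must delimit a positive in-bed interval within "
                "each noon-to-noon day"
            )

    @property
    def bed_offset_min(self) -> int:
        """Mean bed time as minutes after the noon anchor."""
        return (_clock_minutes(self.bed_time_mean) - 720) % 1440

    @property
    def rise_offset_min(self) -> int:
        """Mean rise time as minutes after the noon anchor."""
        return (_clock_minutes(self.rise_time_mean) - 720) % 1440


@dataclass(frozen=True)
class SimRecording:
    """One simulated subject: signal, ground truth, and annotator tracks."""

    subject_id: str
    trace: RawTrace
    truth_labels: np.ndarray  # per-minute {0,1}
    truth_intervals: IntervalSet
    nonwear_intervals: IntervalSet
    annotator_a: IntervalSet
    annotator_b: IntervalSet
    applied_miscalibration: tuple[tuple[float, ...], tuple[float, ...]]
    regimes: np.ndarray  # per-sample regime code (generator oracle)

    def minute_series(self) -> MinuteSeries:
        """Truth-labelled minute series (without any calibration step)."""
        from .io import to_minutes

        ms = to_minutes(self.trace)
        return MinuteSeries(
            ms.start_minute, ms.values, labels=self.truth_labels[: ms.n_minutes]
        )


def _poisson_times(rng: np.random.Generator, rate_per_hour: float,
                   t0: float, t1: float) -> np.ndarray:
    """Event times (seconds) of a homogeneous Poisson process on [t0, t1)."""
    if rate_per_hour <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_per_hour * (t1 - t0) / 3600.0)
    return np.sort(rng.uniform(t0, t1, size=n))


def _jitter_intervals(intervals: IntervalSet, sd_min: float,
                      rng: np.random.Generator,
                      t_min: np.datetime64, t_max: np.datetime64) -> IntervalSet:
    """Gaussian boundary jitter preserving count, order and positive length."""
    starts = intervals.starts.astype(np.int64).astype(np.float64)
    ends = intervals.ends.astype(np.int64).astype(np.float64)
    ns = 60e9 * sd_min
    s = starts + rng.normal(0, ns, size=starts.shape)
    e = ends + rng.normal(0, ns, size=ends.shape)
    lo = float(np.datetime64(t_min, "ns").astype(np.int64))
    hi = float(np.datetime64(t_max, "ns").astype(np.int64))
    s = np.clip(s, lo, hi - 60e9)
    e = np.clip(e, lo + 60e9, hi)
    # keep intervals disjoint and of positive length
    for i in range(len(s)):
        if i > 0:
            s[i] = max(s[i], e[i - 1] + 60e9)
        e[i] = max(e[i], s[i] + 60e9)
    return IntervalSet(s.astype(np.int64).astype("datetime64[ns]"),
                       e.astype(np.int64).astype("datetime64[ns]"))


def simulate_subject(config: SimConfig, subject_index: int) -> SimRecording:
    """Simulate one subject's multi-day recording.

    Deterministic for a fixed ``(config.seed, subject_index)`` pair.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_index,))
    )
    start = pd.Timestamp(config.start_time)
    rate = config.sample_rate
    total_s = config.days_per_subject * 86400
    n = int(round(total_s * rate))
    t = np.arange(n) / rate  # seconds since start

    # --- nightly bed/rise schedule (seconds since start) ---------------------
    beds, rises = [], []
    for d in range(config.days_per_subject):
        bed = (d * 1440 + config.bed_offset_min + rng.normal(0, config.bed_time_sd)) * 60
        rise = (d * 1440 + config.rise_offset_min + rng.normal(0, config.rise_time_sd)) * 60
        bed = float(np.clip(bed, d * 86400, (d + 1) * 86400 - 120))
        rise = float(np.clip(rise, bed + 60, (d + 1) * 86400))
        beds.append(bed)
        rises.append(rise)
    truth_intervals = IntervalSet.from_pairs(
        (start + pd.Timedelta(seconds=b), start + pd.Timedelta(seconds=r))
        for b, r in zip(beds, rises)
    )

    # --- regimes and orientations --------------------------------------------
    regimes = np.full(n, REGIME_OUT, dtype=np.int8)
    orient = np.tile(_UPRIGHT, (n, 1))
    for b, r in zip(beds, rises):
        i0, i1 = int(np.ceil(b * rate)), int(np.ceil(r * rate))
        regimes[i0:i1] = REGIME_BED
        turns = _poisson_times(rng, config.turn_rate, b, r)
        cuts = np.concatenate([[b], turns, [r]])
        for s0, s1 in zip(cuts[:-1], cuts[1:]):
            j0, j1 = int(np.ceil(s0 * rate)), int(np.ceil(s1 * rate))
            orient[j0:j1] = _LYING[rng.integers(len(_LYING))]

    # activity bursts while out of bed
    out_segments = []
    prev = 0.0
    for b, r in zip(beds, rises):
        if b > prev:
            out_segments.append((prev, b))
        prev = r
    if total_s > prev:
        out_segments.append((prev, total_s))
    burst_mask = np.zeros(n, dtype=bool)
    for s0, s1 in out_segments:
        for bt in _poisson_times(rng, config.activity_burst_rate, s0, s1):
            dur = rng.uniform(30.0, 180.0)
            j0, j1 = int(np.ceil(bt * rate)), int(np.ceil(min(bt + dur, s1) * rate))
            burst_mask[j0:j1] = True
    burst_mask &= regimes == REGIME_OUT
    regimes[burst_mask] = REGIME_BURST

    # --- non-wear episodes (device on a table during daytime) ----------------
    nw_pairs = []
    for d in range(config.days_per_subject):
        if rng.random() < config.nonwear_prob_per_day:
            dur = rng.uniform(*config.nonwear_duration) * 60.0
            day_start = d * 86400.0
            latest = beds[d] - dur - 600.0
            if latest <= day_start + 600.0:
                continue
            nw0 = rng.uniform(day_start + 600.0, latest)
            nw_pairs.append((nw0, nw0 + dur))
    nonwear_intervals = (
        IntervalSet.from_pairs(
            (start + pd.Timedelta(seconds=a), start + pd.Timedelta(seconds=b))
            for a, b in nw_pairs
        )
        if nw_pairs
        else IntervalSet.empty()
    )

    # --- assemble the signal --------------------------------------------------
    signal = orient + rng.normal(0, config.rest_noise_sd, size=(n, 3))
    n_burst = int(burst_mask.sum())
    if n_burst:
        signal[burst_mask] += rng.normal(0, config.activity_noise_sd, size=(n_burst, 3))
    for a, b in nw_pairs:
        j0, j1 = int(np.ceil(a * rate)), int(np.ceil(b * rate))
        regimes[j0:j1] = REGIME_NONWEAR
        signal[j0:j1] = _TABLE
        if config.nonwear_jitter_sd > 0:
            signal[j0:j1] += rng.normal(
                0, config.nonwear_jitter_sd, size=(j1 - j0, 3)
            )

    if config.miscalibration is not None:
        gain, offset = config.miscalibration
        signal = signal * np.asarray(gain) + np.asarray(offset)
        applied = (tuple(float(g) for g in gain), tuple(float(o) for o in offset))
    else:
        applied = ((1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

    trace = RawTrace(start, rate, signal)
    n_minutes = config.days_per_subject * 1440
    truth_labels = rasterize(truth_intervals, start, n_minutes)

    t_max = np.datetime64(start + pd.Timedelta(seconds=total_s))
    annotator_a = _jitter_intervals(
        truth_intervals, config.annotator_jitter_sd, rng, np.datetime64(start), t_max
    )
    annotator_b = _jitter_intervals(
        truth_intervals, config.annotator_jitter_sd, rng, np.datetime64(start), t_max
    )

    return SimRecording(
        subject_id=f"S{subject_index:03d}",
        trace=trace,
        truth_labels=truth_labels,
        truth_intervals=truth_intervals,
        nonwear_intervals=nonwear_intervals,
        annotator_a=annotator_a,
        annotator_b=annotator_b,
        applied_miscalibration=applied,
        regimes=regimes,
    )


def simulate_cohort(config: SimConfig) -> list[SimRecording]:
    """Simulate ``config.n_subjects`` independent subjects in stable order."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]


def write_recording(rec: SimRecording, out_dir, config: SimConfig | None = None) -> None:
    """Write one recording as the plain-CSV dialect plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = rec.subject_id
    write_trace(rec.trace, out / f"{sid}_trace.csv")
    write_labels(rec.trace.start_time.floor("min"), rec.truth_labels,
                 out / f"{sid}_labels.csv")
    write_intervals(rec.truth_intervals, out / f"{sid}_truth_intervals.csv")
    write_intervals(rec.annotator_a, out / f"{sid}_annotator_a.csv")
    write_intervals(rec.annotator_b, out / f"{sid}_annotator_b.csv")
    write_intervals(rec.nonwear_intervals, out / f"{sid}_nonwear.csv")
    sidecar = {
        "subject_id": sid,
        "applied_miscalibration": {
            "gain": list(rec.applied_miscalibration[0]),
            "offset_g": list(rec.applied_miscalibration[1]),
        },
    }
    if config is not None:
        cfg = asdict(config)
        cfg["nonwear_duration"] = list(config.nonwear_duration)
        if config.miscalibration is not None:
            cfg["miscalibration"] = [list(x) for x in config.miscalibration]
        sidecar["config"] = cfg
    (out / f"{sid}_sidecar.json").write_text(json.dumps(sidecar, indent=2))
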