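"""Accelerometer-specific training-time data augmentation.

Four stochastic operators, applied in the fixed order crop → flip → reverse →
noise:

* **random crop** — from each source sequence, crop a window of uniform random
  length between 5 min and the full length (100 crops per sequence per pass);
* **flip** — negate a configurable axis subset to mimic a device worn upside
  down (default: vertical + medio-lateral, the 180° rotation about the
  anterior–posterior axis that a flipped hip band actually produces);
* **reverse** — reverse the sequence in time to mimic inverted turning
  behaviour;
* **noise** — add i.i.d. Gaussian noise (sd 0.1 in normalized units) in 10% of
  cases.

Flip and reverse fire with probability 0.5 each. Crops change length; nothing
else does, and no operator touches the label alphabet. Augmentation is meant
to run *after* cohort normalization, hence the noise sd is in z-units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MinuteSeries

__all__ = [
    "AugmentationConfig",
    "AugmentedSample",
    "random_crop",
    "flip",
    "reverse",
    "add_noise",
    "augment_batch",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class AugmentationConfig:
    """Operator probabilities and parameters; defaults follow the training recipe."""

    n_crops: int = 100
    min_crop_minutes: int = 5
    flip_prob: float = 0.5
    reverse_prob: float = 0.5
    noise_prob: float = 0.1
    noise_sd: float = 0.1  # normalized units
    flip_axes: tuple[str, ...] = ("x", "y")  # medio-lateral + vertical
    seed: int | None = None

    def __post_init__(self):
        for p in (self.flip_prob, self.reverse_prob, self.noise_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.min_crop_minutes < 1:
            raise ValueError("min_crop_minutes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_crops < 1:
            raise ValueError("n_crops must be >= 1")
        bad = set(self.flip_axes) - set(_AXIS_INDEX)
        if bad:
            raise ValueError(f"unknown flip axes {sorted(bad)}")


@dataclass(frozen=True)
class AugmentedSample:
    """A (values, labels) training pair plus a record of the operators applied."""

    values: np.ndarray  # (L, 3)
    labels: np.ndarray  # (L,)
    applied: tuple[str, ...] = ()
    crop_start: int | None = None  # minute offset into the source sequence

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int8)
        if values.shape != (labels.shape[0], 3):
            raise ValueError("values must be (L, 3) matching labels length L")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_series(cls, series: MinuteSeries) -> "AugmentedSample":
        if series.labels is None:
            raise ValueError("series must carry labels")
        return cls(series.values, series.labels)


def _as_sample(sample) -> AugmentedSample:
    if isinstance(sample, MinuteSeries):
        return AugmentedSample.from_series(sample)
    return sample


def random_crop(sample, config: AugmentationConfig,
                rng: np.random.Generator) -> AugmentedSample:
    """Crop a window of uniform random length in [min_crop_minutes, T].

    The start is uniform over the feasible positions; values and labels are
    cropped identically.
    """
    s = _as_sample(sample)
    T = s.values.shape[0]
    if T < config.min_crop_minutes:
        raise ValueError(
            f"sequence of {T} min is shorter than min_crop_minutes="
            f"{config.min_crop_minutes}"
        )
    L = int(rng.integers(config.min_crop_minutes, T + 1))
    start = int(rng.integers(0, T - L + 1))
    return AugmentedSample(
        s.values[start:start + L],
        s.labels[start:start + L],
        applied=s.applied + ("crop",),
        crop_start=start,
    )


def flip(sample, config: AugmentationConfig) -> AugmentedSample:
    """Negate the configured axes (upside-down wear); an involution that
    preserves the per-sample vector magnitude exactly."""
    s = _as_sample(sample)
    values = s.values.copy()
    for ax in config.flip_axes:
        values[:, _AXIS_INDEX[ax]] = -values[:, _AXIS_INDEX[ax]]
    return AugmentedSample(values, s.labels, s.applied + ("flip",), s.crop_start)


def reverse(sample, config: AugmentationConfig) -> AugmentedSample:
    """Reverse values and labels in time; total in-bed minutes are unchanged."""
    s = _as_sample(sample)
    return AugmentedSample(
        s.values[::-1].copy(), s.labels[::-1].copy(),
        s.applied + ("reverse",), s.crop_start,
    )


def add_noise(sample, config: AugmentationConfig,
              rng: np.random.Generator) -> AugmentedSample:
    """Add i.i.d. Gaussian(0, noise_sd²) to every axis value; labels untouched."""
    s = _as_sample(sample)
    if config.noise_sd == 0:
        return s
    values = s.values + rng.normal(0, config.noise_sd, size=s.values.shape)
    return AugmentedSample(values, s.labels, s.applied + ("noise",), s.crop_start)


def augment_batch(samples, config: AugmentationConfig,
                  rng: np.random.Generator | None = None) -> list[AugmentedSample]:
    """Produce ``n_crops`` augmented crops per source sequence.

    Per crop, independently: flip with ``flip_prob``, reverse with
    ``reverse_prob``, noise with ``noise_prob``, in the fixed order
    crop → flip → reverse → noise. Sequences shorter than the minimum crop
    length are skipped. Bit-reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[AugmentedSample] = []
    for sample in samples:
        s = _as_sample(sample)
        if s.values.shape[0] < config.min_crop_minutes:
            import warnings

            warnings.warn(
                f"skipping sequence of {s.values.shape[0]} min "
                f"(< min_crop_minutes={config.min_crop_minutes})"
            )
            continue
        for _ in range(config.n_crops):
            c = random_crop(s, config, rng)
            u_flip, u_rev, u_noise = rng.random(3)
            if u_flip < config.flip_prob:
                c = flip(c, config)
            if u_rev < config.reverse_prob:
                c = reverse(c, config)
            if u_noise < config.noise_prob:
                c = add_noise(c, config, rng)
            out.append(c)
    return out
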