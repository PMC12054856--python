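"""Autocalibration of raw acceleration: per-axis gain/offset from stationary epochs.

During stationary wear the accelerometer measures only gravity, so the measured
vector should lie on the unit sphere (|a| = 1 g). Sensor miscalibration shows up
as a per-axis affine distortion; we estimate a correction of the form

    a_corrected = gain * a + offset        (per axis)

by the classic sphere-fit scheme: collect low-variance epochs, then iteratively
regress each epoch mean onto its closest point on the unit sphere until the
mean radial residual |VM - 1| stops improving. With too few epochs or poor
orientation coverage the fit is ill-posed and we fall back to the identity
correction with a diagnostic flag rather than fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RawTrace

__all__ = [
    "CalibrationCoefficients",
    "find_stationary_epochs",
    "fit",
    "apply",
    "calibrate",
]

MIN_EPOCHS = 10
MIN_AXIS_RANGE_G = 0.3
MIN_DIVERSE_AXES = 2


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Affine correction ``a' = gain * a + offset`` plus fit diagnostics."""

    gain: np.ndarray  # (3,), unitless
    offset: np.ndarray  # (3,), g
    n_stationary_epochs: int
    residual: float  # mean |VM - 1| after fit, g
    flag: str = "ok"  # "ok" | "insufficient_sphere_coverage"
    residual_history: tuple[float, ...] = ()

    def __post_init__(self):
        gain = np.asarray(self.gain, dtype=np.float64)
        offset = np.asarray(self.offset, dtype=np.float64)
        if gain.shape != (3,) or offset.shape != (3,):
            raise ValueError("gain and offset must be length-3 vectors")
        if np.any(gain <= 0.5) or np.any(gain >= 1.5):
            raise ValueError("gains outside the plausible (0.5, 1.5) band")
        if np.any(np.abs(offset) >= 0.5):
            raise ValueError("offsets outside the plausible (-0.5, 0.5) g band")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "offset", offset)

    @classmethod
    def identity(cls, n_epochs: int = 0, residual: float = 0.0,
                 flag: str = "ok") -> "CalibrationCoefficients":
        return cls(np.ones(3), np.zeros(3), n_epochs, residual, flag)

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.gain == 1.0) and np.all(self.offset == 0.0))


def find_stationary_epochs(trace: RawTrace, window_s: float = 10.0,
                           sd_threshold_g: float = 0.013) -> np.ndarray:
    """Mean vectors of non-overlapping windows whose per-axis sd is below threshold.

    Returns an ``(n_epochs, 3)`` array (possibly empty). Defaults follow the
    common autocalibration practice of 10 s windows at a 13 mg threshold.
    """
    if window_s < 1:
        raise ValueError("window_s must be >= 1")
    if sd_threshold_g <= 0:
        raise ValueError("sd_threshold_g must be positive")
    w = int(round(window_s * trace.sample_rate))
    if w < 2 or trace.n_samples < w:
        return np.empty((0, 3))
    k = trace.n_samples // w
    windows = trace.samples[: k * w].reshape(k, w, 3)
    sds = windows.std(axis=1, ddof=1)
    keep = np.all(sds < sd_threshold_g, axis=1)
    return windows[keep].mean(axis=1)


def _mean_radial_residual(points: np.ndarray) -> float:
    return float(np.abs(np.linalg.norm(points, axis=1) - 1.0).mean())


def fit(epoch_means: np.ndarray, max_iter: int = 100,
        tol: float = 1e-6) -> CalibrationCoefficients:
    """Fit gain/offset by iteratively projecting epoch means onto the unit sphere.

    Each iteration regresses, per axis, the current calibrated points' closest
    unit-sphere targets on the raw epoch means (weighted least squares with the
    previous-iteration radial error as downweight), and stops when the mean
    radial residual improves by less than ``tol`` g. The returned residual
    never exceeds the pre-fit residual.

    With fewer than 10 epochs, or with per-axis mean ranges below 0.3 g on more
    than one axis (poor sphere coverage), the fit is refused and identity
    coefficients are returned flagged ``insufficient_sphere_coverage``.
    """
    means = np.asarray(epoch_means, dtype=np.float64)
    if means.size == 0:
        return CalibrationCoefficients.identity(0, 0.0,
                                                "insufficient_sphere_coverage")
    n = means.shape[0]
    diverse_axes = int(np.sum(np.ptp(means, axis=0) >= MIN_AXIS_RANGE_G))
    if n < MIN_EPOCHS or diverse_axes < MIN_DIVERSE_AXES:
        return CalibrationCoefficients.identity(
            n, _mean_radial_residual(means), "insufficient_sphere_coverage"
        )

    gain = np.ones(3)
    offset = np.zeros(3)
    cal = means.copy()
    best = _mean_radial_residual(cal)
    history = [best]
    for _ in range(max_iter):
        norms = np.linalg.norm(cal, axis=1)
        closest = cal / norms[:, None]
        # per-axis regression of the sphere target on the *current* calibrated
        # points; the step is composed into the accumulated affine correction
        step_gain = np.empty(3)
        step_offset = np.empty(3)
        for ax in range(3):
            A = np.column_stack([cal[:, ax], np.ones(n)])
            coef, *_ = np.linalg.lstsq(A, closest[:, ax], rcond=None)
            step_gain[ax], step_offset[ax] = coef
        new_gain = gain * step_gain
        new_offset = offset * step_gain + step_offset
        new_cal = means * new_gain + new_offset
        res = _mean_radial_residual(new_cal)
        if res > best:
            break  # the step no longer improves; keep the best correction
        gain, offset, cal, best = new_gain, new_offset, new_cal, res
        history.append(res)
        if history[-2] - history[-1] < tol:
            break

    return CalibrationCoefficients(gain, offset, n, best,
                                   residual_history=tuple(history))


def apply(trace: RawTrace, coeffs: CalibrationCoefficients) -> RawTrace:
    """Apply the affine correction to every sample: ``a' = gain * a + offset``."""
    if coeffs.is_identity:
        return trace
    return RawTrace(
        trace.start_time,
        trace.sample_rate,
        trace.samples * coeffs.gain + coeffs.offset,
    )


def calibrate(trace: RawTrace, window_s: float = 10.0,
              sd_threshold_g: float = 0.013) -> tuple[RawTrace, CalibrationCoefficients]:
    """Convenience pipeline: find epochs, fit, and apply in one call."""
    coeffs = fit(find_stationary_epochs(trace, window_s, sd_threshold_g))
    return apply(trace, coeffs), coeffs
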