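"""Recover an injected sensor miscalibration by sphere-fit autocalibration.

A simulated recording is distorted per axis (a' = gain*a + offset); the
calibration step finds stationary epochs and fits the correction that puts
them back on the 1 g sphere. The printed errors compare the fitted correction
with the exact inverse of the injected distortion.
"""

import numpy as np

from tibhip.calibration import calibrate, find_stationary_epochs
from tibhip.synthetic import SimConfig, simulate_subject

gain = (1.02, 1.00, 0.98)
offset = (0.030, 0.000, -0.020)  # g
cfg = SimConfig(n_subjects=1, days_per_subject=2, seed=7,
                miscalibration=(gain, offset))
rec = simulate_subject(cfg, 0)

before = find_stationary_epochs(rec.trace)
calibrated, coeffs = calibrate(rec.trace)
after = find_stationary_epochs(calibrated)

err_before = np.abs(np.linalg.norm(before, axis=1) - 1).mean()
err_after = np.abs(np.linalg.norm(after, axis=1) - 1).mean()
g = np.array(gain)
o = np.array(offset)

print(f"stationary epochs: {coeffs.n_stationary_epochs} ({coeffs.flag})")
print(f"mean |VM - 1|: {err_before:.4f} g before -> {err_after:.4f} g after")
print(f"gain  error vs exact inverse: {np.abs(coeffs.gain - 1 / g).max():.5f}")
print(f"offset error vs exact inverse: "
      f"{np.abs(coeffs.offset + o / g).max():.5f} g")
print("\nBoth errors should be well below 0.005: the fit inverts the "
      "injected affine distortion to within the rest-noise floor.")
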