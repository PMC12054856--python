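"""Apply the four training-time augmentations and inspect what each changes.

Crop shortens the sequence (labels follow), flip negates the configured axes
(vector magnitude untouched), reverse mirrors time (total in-bed minutes
untouched), and noise perturbs values only.
"""

import numpy as np

from tibhip.augment import AugmentationConfig, augment_batch
from tibhip.pipeline import labelled_minutes
from tibhip.synthetic import SimConfig, simulate_subject

rec = simulate_subject(SimConfig(n_subjects=1, days_per_subject=1, seed=9), 0)
series = labelled_minutes(rec, apply_calibration=False)

cfg = AugmentationConfig(n_crops=8)
crops = augment_batch([series], cfg, np.random.default_rng(0))

print(f"source: {series.n_minutes} minutes, "
      f"{int(series.labels.sum())} in bed\n")
for i, c in enumerate(crops):
    print(f"crop {i}: {c.values.shape[0]:4d} min "
          f"(start {c.crop_start:4d}), in-bed {int(c.labels.sum()):4d}, "
          f"ops: {'+'.join(c.applied)}")
print("\nCrop lengths are uniform between 5 min and the day length; flip and "
      "reverse each fire ~50% of the time and noise ~10%.")
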