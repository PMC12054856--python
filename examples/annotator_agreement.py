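"""Score inter-annotator agreement by IoU and apply the QC inclusion filter.

Two synthetic annotators mark the same nights with ~5 min of boundary jitter.
Recordings with IoU strictly above 0.9 are kept; their consensus labels are
the intersection of the two annotations.
"""

import numpy as np

from tibhip.annotation import qc_filter
from tibhip.synthetic import SimConfig, simulate_cohort

cfg = SimConfig(n_subjects=10, days_per_subject=2, seed=3,
                annotator_jitter_sd=5.0, sample_rate=1 / 60)
cohort = simulate_cohort(cfg)
records = qc_filter([(r.annotator_a, r.annotator_b) for r in cohort],
                    threshold=0.9,
                    ids=[r.subject_id for r in cohort])

for rec in records:
    status = "kept" if rec.kept else "excluded"
    print(f"{rec.recording_id}: IoU = {rec.iou:.4f} -> {status}")
print(f"\nkept {sum(r.kept for r in records)}/{len(records)}; "
      f"mean IoU {np.mean([r.iou for r in records]):.4f}. With ~9 h nightly "
      "intervals, 5-min jitter moves each boundary a few minutes, so IoU "
      "stays well above the 0.9 cut-off for nearly all recordings.")
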