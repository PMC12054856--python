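# tibhip

Time-in-bed (TiB) detection from hip-worn tri-axial accelerometer recordings.

Large epidemiological cohorts routinely collect week-long hip-accelerometer
recordings to measure physical activity. The hip placement is usually written
off for sleep-adjacent outcomes, yet time in bed — from going to bed to
getting out of bed, a superset of sleep — leaves a clear signature in the hip
signal: a near-constant gravity vector in a lying orientation, punctuated by
positional turns. `tibhip` implements a complete pipeline that recovers it:

1. **autocalibration** — per-axis gain/offset correction from stationary
   epochs (sphere fit), so stationary vectors sit on the 1 g sphere;
2. **per-minute aggregation** — per-axis mean of the raw signal per minute,
   the model's native resolution;
3. **cohort z-normalization** — pooled per-axis mean/sd, fitted on training
   subjects only and enforced end-to-end by a content hash;
4. **accelerometer-specific augmentation** — random crops (100 per sequence,
   uniform length ≥ 5 min), upside-down flips (p = 0.5), time reversal
   (p = 0.5) and Gaussian noise (p = 0.1, sd 0.1);
5. **LSTM sequence labelling** — stacked uni/bidirectional LSTMs (grid:
   {1, 2, 4} layers × {1 … 128} cells) emitting a per-minute in-bed
   probability, thresholded at 0.5; subject-level 10-fold cross-validation
   and a sparsest-within-one-SE selection rule;
6. **non-wear detection** — 60 min windows sliding by 15 min, flagged when
   ≥ 2 of 3 axes have sd < 3 mg or range < 50 mg;
7. **annotator quality control** — interval intersection-over-union, with a
   strict > 0.9 inclusion filter and intersection consensus labels;
8. **evaluation** — minute-level accuracy/sensitivity/specificity against the
   always-out-of-bed baseline, the < 1 h / > 23 h outlier rule, daily TiB on
   fully recorded noon-to-noon days, and Bland–Altman method comparison.

A bundled synthetic-cohort generator (`tibhip.synthetic`) emulates multi-day
free-living recordings — lying-still nights with Poisson turns, bursty
daytime activity, optional table-flat non-wear, jittered dual-annotator
tracks, optional miscalibration — so the entire pipeline runs and is tested
without any real data. See `docs/methods.md` for the models, parameters and
limitations.

## Worked example

```bash
python examples/train_and_evaluate.py
```

simulates 16 subjects × 2 days, trains the bidirectional 2-layer × 16-cell
LSTM on 12 of them and scores the 4 held-out subjects:

```
held-out pooled accuracy:  0.997
held-out sensitivity:      0.991
held-out specificity:      0.999
always-out-of-bed baseline: 0.677
per-subject accuracies:    [0.997, 0.996, 0.996, 0.998]
```

Accuracy is the fraction of held-out minutes labelled correctly; the baseline
is what always answering "out of bed" would score (the out-of-bed
prevalence), so the gap over the baseline is what the model actually learned.
Sensitivity is the fraction of true in-bed minutes recovered, specificity the
fraction of out-of-bed minutes kept out of bed. The synthetic task is easier
than field data — see the methods note before reading these numbers across.

Other examples, one per capability: `simulate_cohort.py`,
`calibration_recovery.py`, `nonwear_detection.py`, `annotator_agreement.py`,
`augmentation_demo.py`.

A thin CLI mirrors the stages for shell use:

```bash
tib-hip simulate --out cohort/ --seed 7
tib-hip calibrate cohort/S000_trace.csv --out coeffs.json
tib-hip nwt cohort/S000_trace.csv --out nwt.csv
tib-hip qc cohort/S000_annotator_a.csv cohort/S000_annotator_b.csv
```

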