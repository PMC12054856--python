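# Methods

`tibhip` labels every minute of a multi-day hip-worn tri-axial accelerometer
recording as *in bed* or *out of bed*. This note documents the models and
procedures each stage implements, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Problem setting

Hip-worn accelerometers are standard instruments for physical-activity
surveillance in epidemiological cohorts, typically worn around the clock for a
week. Unlike wrist devices, they are rarely used to estimate sleep-related
outcomes, although time in bed (TiB) — the interval from going to bed to
getting out of bed, a superset of sleep — is recoverable from the hip signal:
lying still produces a near-constant gravity vector in a lying orientation,
clearly distinct from upright postures and ambulatory bursts. The pipeline
turns the raw signal into per-minute tri-axial features and trains a recurrent
sequence model to classify each minute.

## Pipeline stages

### Autocalibration (`tibhip.calibration`)

During stationary wear the measured vector should have magnitude 1 g; sensor
error appears as a per-axis affine distortion. The correction
`a' = gain · a + offset` is estimated by the standard sphere-fit scheme:

1. collect non-overlapping low-variance epochs (default 10 s windows, all-axis
   sd < 13 mg) and take their per-axis means;
2. iterate: project the current calibrated epoch means onto the unit sphere,
   regress the projections per axis on the calibrated means, and compose the
   per-iteration slope/intercept into the accumulated gain/offset;
3. stop when the mean radial residual `mean |‖a'‖ − 1|` improves by less than
   1e−6 g or after 100 iterations. The residual is non-increasing by
   construction (steps that do not improve are rejected and end the loop).

The fit is refused — identity coefficients, flagged
`insufficient_sphere_coverage` — with fewer than 10 stationary epochs or with
a per-axis epoch-mean range of ≥ 0.3 g on fewer than 2 axes, since the sphere
fit is then ill-posed. Offsets are applied after gains so coefficients remain
interpretable. No temperature covariate is used (the simulator has no
temperature channel). Gains are constrained to (0.5, 1.5) and offsets to
±0.5 g as plausibility bounds.

### Per-minute aggregation (`tibhip.io`)

The model's native resolution is one tri-axial value per minute. The
aggregate is the per-axis arithmetic mean of all raw samples with timestamps
in `[minute, minute + 1)`; partial leading/trailing minutes are dropped.
Mean aggregation is the simplest magnitude-preserving choice; whether a mean,
a decimated sample or a vector magnitude is "the" right per-minute feature is
an open question, and the choice is isolated in `to_minutes`.

Intervals are half-open `[start, end)` throughout, and minute membership uses
the midpoint rule (minute m is inside an interval iff the midpoint of
`[m, m+1)` is), which avoids double-counting boundary minutes and makes
rasterize/de-rasterize an exact round trip on minute-aligned interval sets.
Timestamps are timezone-naive local time; daylight-saving transitions are out
of scope. Day windows are anchored at 12:00 noon (configurable), the
convention for 24 h wear protocols, and a day is "full" iff all 1440 minutes
are present.

### Cohort normalization (`tibhip.preprocess`)

Per-axis mean and population sd are pooled over every minute of every subject
of the fitting cohort and applied as a z-transform. The statistics are always
fitted on the training subjects only and frozen for validation/test data:
fitting on the whole dataset would leak held-out information into training.
The statistics carry a content hash; series normalized with them carry the
same hash, and both the training entry point and `predict` refuse mismatched
hashes. This makes normalization leakage a hard error rather than a silent
bug.

### Augmentation (`tibhip.augment`)

Four stochastic operators applied per training pass in the fixed order
crop → flip → reverse → noise (the order is a reproducibility choice; the
operators do not all commute with the noise draw):

| operator | default | what it emulates |
|---|---|---|
| random crop | 100 crops/sequence, length ~ U{5 min … T} | variable observation windows |
| flip (negate axes) | p = 0.5, axes {x, y} | device worn upside down |
| time reversal | p = 0.5 | inverted evening/morning dynamics |
| additive Gaussian noise | p = 0.1, sd 0.1 (z-units) | sensor noise |

Flip negates the vertical and medio-lateral axes — the 180° rigid rotation
about the anterior–posterior axis that a hip band actually undergoes when
worn upside down; negating all three axes is physically unrealizable by
re-wearing and is available only as a config option. Noise is applied after
normalization, hence its sd is in z-units: 0.1 g of raw noise would be an
order of magnitude above rest noise. Crops are resampled fresh each epoch to
keep effective data diversity high; a fixed seed makes the whole batch
bit-reproducible.

### Sequence model (`tibhip.model`, `tibhip._lstm`)

A stacked uni- or bidirectional LSTM maps the normalized per-minute series to
a per-minute in-bed probability through a per-timestep logistic read-out;
minutes with probability ≥ 0.5 are labelled in bed, with no post-hoc
smoothing. The loss is per-minute binary cross-entropy, optimized with Adam
(lr 1e−3, batch 32, global-norm gradient clip 5). The LSTM is implemented
directly in numpy with the recurrences JIT-compiled via numba; gradients are
exact back-propagation through time (verified against finite differences in
the test suite), and everything is deterministic given the seed.

Defaults train for up to 3 epochs with early stopping on the training-loss
plateau (patience 2, min delta 1e−4). Three epochs is deliberate: with 100
fresh crops per source sequence per epoch, a 45-subject cohort already yields
~400 gradient steps — the synthetic task reaches its loss plateau within
them, and more epochs only re-crop the same days. Early stopping monitors the
training loss rather than a held-back validation split so that the
cross-validation harness never consumes validation subjects for stopping
decisions.

The hyperparameter grid spans {1, 2, 4} layers × {1, 2, 4, 8, 16, 32, 64,
128} cells, uni- and bidirectional. Cross-validation splits *subjects*, never
minutes or days, to prevent within-person leakage; the normalizer is refitted
inside each training fold. Model selection takes, among grid cells whose mean
accuracy is within one standard error of the best, the one with the fewest
trainable parameters (ties broken by (layers, cells) lexicographic order) —
"sparsity" made precise as parameter count.

### Non-wear detection (`tibhip.nonwear`)

A 60 min window advanced in 15 min steps over the raw-rate signal (never the
per-minute aggregate) is flagged as non-wear when, for at least 2 of the 3
axes, the per-axis sd is below 3 mg *or* the per-axis range is below 50 mg;
comparisons are strict. Overlapping flagged windows are unioned into maximal
intervals. The criterion is applied symmetrically (each axis may satisfy
either the sd or the range test); the alternative reading in which only the
range test is per-axis was considered and rejected as less coherent. A day
"contains" non-wear iff at least one of its minute midpoints falls in a
detected interval.

### Annotator quality control (`tibhip.annotation`)

Agreement between two annotators' TiB interval sets is intersection over
union, computed exactly in continuous time (a minute-rasterized variant is
provided as a cross-check; the two agree exactly on minute-aligned sets and
to within one boundary minute per interval otherwise). Recordings with IoU
strictly greater than 0.9 are kept; consensus labels are the interval
intersection, hence a subset of both annotations. Two empty sets score 1.0
(vacuous agreement) — a convention, as the case cannot arise from the
generator.

### Evaluation (`tibhip.evaluation`)

In-bed is the positive class. Accuracy, sensitivity and specificity come from
the per-minute confusion table; ratios with a zero denominator are reported
as absent, never as 0. The trivial baseline is the accuracy of always
answering "out of bed" (the out-of-bed prevalence). Days with a predicted TiB
below 60 or above 1380 minutes are flagged as outliers (strict inequalities;
a day at exactly 60 min is not an outlier). Daily TiB totals are computed on
fully recorded noon-to-noon days only and averaged per subject. Both
minute-pooled and two-stage subject-level summaries are reported — they
answer different questions and differ when day counts vary per subject.
Bland–Altman comparison of paired per-subject estimates reports the bias
(mean difference) and 95% limits of agreement (bias ± 1.96 sd).

## The synthetic cohort (`tibhip.synthetic`)

The generator emulates the *structure* of free-living hip recordings, not
their physiology:

* **Schedule** — per night, bed time ~ N(23:00, 30 min) and rise time ~
  N(07:00, 30 min), independent across nights and subjects (real bed-time
  distributions are cohort-specific; these are conventional values, not
  fitted). Recordings are noon-anchored and span whole days (default 7, at
  1 Hz — a desk-scale rate; all downstream code reads the rate from the
  data).
* **In bed** — a constant unit gravity vector in one of four lying
  orientations plus Gaussian rest noise (sd 10 mg); turns are instantaneous
  re-orientations at Poisson times (2/h).
* **Out of bed** — a quiet upright orientation with Poisson activity bursts
  (6/h, 30–180 s, noise sd 250 mg).
* **Non-wear** — the device flat on a table: an exactly constant signal
  (optionally sub-threshold jitter for robustness tests), placed in daytime
  with configurable probability (default off).
* **Annotators** — the truth intervals with independent Gaussian boundary
  jitter (sd 5 min) per annotator; never an invented or dropped interval, so
  the IoU filter is controlled by a single parameter.
* **Miscalibration** — an optional per-axis affine distortion applied last.

All randomness flows from `SeedSequence(seed, spawn_key=(subject_index,))`,
so subjects are independent, individually reproducible and order-stable.

What passing tests on this generator show: the pipeline's plumbing, the
training loop, leakage guards and every contract above operate correctly, and
the model can exploit orientation and dynamics differences between regimes.
What they do not show: performance on real populations — real data has
gradual posture transitions, naps, restless nights, orientation drift of the
elastic band, device idiosyncrasies and annotation ambiguity, none of which
the generator produces. The synthetic task is *easier* than the real one
(held-out accuracy here approaches 100%, whereas low-to-mid 90s is a
realistic ceiling on field data), so accuracy numbers must not be read across.

## Problem sizes

The bundled end-to-end check simulates 60 subjects × 2 days at 1 Hz, trains
the bidirectional 2-layer × 16-cell model on 45 subjects and scores 15
held-out subjects; smaller configurations are used for the toy separable
problem and the determinism checks. These sizes were chosen so a full run
completes in minutes on one CPU while every stage is exercised at realistic
sequence lengths (2 880-minute recordings).

## Known limitations

* The LSTM is CPU-bound and desk-scale; training hour-resolution cohorts of
  hundreds of subjects would want a GPU framework.
* No DST handling; timestamps are naive local time.
* Bidirectional models are whole-sequence predictors; streaming use would
  need the unidirectional variant.
* The calibration module does not model temperature drift. With poor
  orientation coverage the sphere fit is only partially identified: the
  generator's default postures give just two gravity levels on the vertical
  axis, so that axis's gain and offset can trade off against each other while
  the radial residual still reaches the noise floor. Per-axis parameter
  recovery is guaranteed only for epoch sets spanning six or more
  orientations (as the tests construct); on traces, the meaningful
  end-to-end figure is the post-calibration radial residual.
* GT3X/ActiLife binary parsing and proprietary count units are out of scope;
  the package reads plain tabular exports.
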