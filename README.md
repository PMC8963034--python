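# emgfuse

User-independent hand-gesture recognition from fused surface-EMG and IMU
recordings: signal conditioning, TKEO double-threshold activity detection,
time-domain feature extraction with feature-level sensor fusion, and three
subject-independent classification methods evaluated under subject-wise
cross-validation. Since no public recordings exist for this protocol, the
package ships a synthetic multi-subject cohort generator with planted ground
truth that reproduces the statistical structure the pipeline assumes.

## Pipeline

1. **synthetic** (`emgfuse.synthetic`) — seeded cohorts: 8-channel EMG at
   200 Hz + 3-axis accelerometer / 3-axis gyroscope at 50 Hz, 7 gestures x
   4 arm positions x 10 repetitions per subject (5 s holds, 3 s rests).
   Subject variability is modelled as channel gain jitter and circular
   electrode rotation; arm position sets the gravity direction in the
   accelerometer. Also provides exact planted bilinear style/content
   datasets for recovery tests.
2. **preprocess** (`emgfuse.preprocess`) — EMG: mean removal, 60 Hz notch,
   4th-order Butterworth high-pass at 20 Hz. IMU: 4th-order Butterworth
   band-pass 0.2–15 Hz, then cubic-spline upsampling from 50 to 200 Hz.
3. **onset** (`emgfuse.onset`) — Teager–Kaiser energy operator per channel,
   50 Hz low-pass, rectification, channel averaging, forward sliding RMS
   (W = 60), then a peak-referenced double threshold (onset = 20% of the
   mean of peaks above 10% of the global max; offset = 60% of the onset
   threshold). Multi-region trials are flagged ambiguous for manual or
   planted-truth resolution.
4. **features** (`emgfuse.features`) — 250 ms windows with 50% overlap;
   per EMG channel MAV, MAVS, WL, 4th-order Burg AR coefficients and ZC
   (64 features), per IMU axis MAV and WL (12 features), fused to 76 by
   concatenation.
5. **classifiers** —
   * `emgfuse.lssvm`: per-subject one-vs-all LS-SVM models; new subjects are
     calibrated with two repetitions per gesture and adapted by learning
     nonnegative per-class weights over prior decision functions via
     projected subgradient descent on the closed-form leave-one-out hinge
     loss.
   * `emgfuse.bilinear`: symmetric bilinear style/content factorization
     (style dim 2, content dim 3) fitted by alternating least squares;
     content vectors feed a small softmax MLP (50/20, dropout 20%, batch
     norm, Adam); new subjects contribute one repetition of one gesture to
     estimate their style vector.
   * `emgfuse.mlp`: classic MLP (300/200/100, logistic activations, linear
     output) trained as regression on Z-standardized integer labels with
     per-pattern SGD (lr 0.2); predictions are unscaled, rounded and clamped
     to 1..7.
6. **evaluation** (`emgfuse.evaluation`) — Z-normalization, ±1 scaling and
   PCA (SVD) retaining ≥ 95% variance, all fitted on training folds only;
   subject-wise k-fold cross-validation; accuracy, per-class precision /
   recall and confusion matrices.

## CLI

```bash
emgfuse generate --subjects 22 --seed 1 --out data/cohort
emgfuse detect data/cohort --out results/segments.json
emgfuse featurize data/cohort --out data/features --segmentation detect
emgfuse evaluate data/features --folds 5 --seed 1 --out results/
```

`emgfuse evaluate` writes per-subject accuracies, summary statistics,
confusion matrices (CSV) and a JSON summary. A YAML file mirroring
`CohortConfig` can be passed to `generate --config`.

## Notes

* All randomness flows from a single root seed through
  `numpy.random.SeedSequence`; cohorts, splits and network training are
  reproducible bit-for-bit on a fixed thread count.
* Cohorts are stored as one CSV per sensor stream per trial plus a JSON
  metadata file (subject, gesture, position, repetition, rates, planted
  onset/offset), so everything on disk is plain text.
* The heavy experiment tests run at reduced cohort sizes (fewer subjects,
  shorter holds, fewer repetitions) to stay inside CI budgets; the
  statistical assertions are unchanged.
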