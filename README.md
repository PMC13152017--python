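# kinescreen

Infant movement risk screening from 2D pose keypoint time series.

`kinescreen` turns per-frame COCO-17 keypoint detections (the output of any
standard pose estimator) into a clinical-style risk pipeline:

1. **preprocess** — best-detection selection, confidence masking (< 0.8),
   linear gap interpolation, 1-s rolling-median despike, 1-s rolling-mean
   smoothing; all windows in seconds so mixed frame rates (15/30/120 FPS)
   are handled uniformly.
2. **posenorm** — canonical body frame (mid-hip at origin, torso axis
   head-up, median torso length = 1) plus dataset QC: wingspan-to-body-length
   ratio, retention report, two-sample KS test.
3. **features** — the preregistered 38-feature kinematic vector
   (12 wrist + 12 ankle + 7 elbow + 7 knee): positions, velocities,
   accelerations, joint angles, Shannon entropy, and lagged left/right
   cross-correlation; whole-video or overlapping 2-s sliding windows.
4. **cohort** — exclusion accounting, subject-wise stratified
   Train/Val/Test (lock-box) splits, and SHA-256-frozen manifests.
5. **classify** — imbalance-aware binary classifier (balanced-accuracy
   objective, internal CV, class weights or oversampling, single refit
   model) with a pluggable backend; repeated stratified cross-validation.
6. **metrics** — from-scratch ROC/PR curves and AUCs, Youden's-J operating
   point, confusion matrices, permutation importance grouped by joint, and
   the learning-curve power-law fit (log n vs log(1 − AUC)).
7. **synthetic** — a labeled keypoint-cohort generator (band-limited limb
   oscillation, class-dependent amplitude/complexity/coupling, confidence
   dropouts, spikes, spurious detections) so the whole pipeline is testable
   without clinical data.
8. **pipeline / cli** — end-to-end orchestration with run logging and
   software-enforced lock-box discipline: the Test split cannot be scored
   without an explicit, logged `--unlock`.

## Quick start (all-synthetic)

```bash
kinescreen synth --n-subjects 100 --seed 1 --out data/
kinescreen extract --keypoints data/ --cohort data/cohort.csv --out features.csv
kinescreen split make --cohort data/cohort.csv --seed 1 --out manifest.json
kinescreen train --features features.csv --manifest manifest.json --out model.pkl
kinescreen evaluate --features features.csv --manifest manifest.json \
    --model model.pkl --split val --out report.json
# the Test lock box refuses to open without --unlock (and logs the unlock):
kinescreen evaluate ... --split test --unlock --out test_report.json
```

Or in one shot: `kinescreen run --synthetic 300 --seed 1 --out runs/demo`.

## File formats

All formats are plain text and versioned with `schema_version`:

- **Keypoints** — JSON (one object per frame, each with a list of candidate
  detections of 17 `[x, y, confidence]` triplets and an optional score) or
  flat CSV (one row per frame × detection, metadata in `#` header lines).
- **Feature table** — CSV: `subject_id,label` plus the 38 canonical feature
  columns in documented order (see `features.feature_dictionary()`).
- **Cohort** — CSV: `subject_id,label[,sex,age_weeks,race_ethnicity]`;
  labels `FM+`, `FM-`, `atypical`, `unknown` (atypical is kept but never
  trained on).
- **Split manifest** — canonical JSON with a SHA-256 content hash;
  `kinescreen split verify` refuses tampered manifests.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests with independent oracles
(brute-force sliding windows, Mann–Whitney pair counting, exhaustive
threshold sweeps), hypothesis property tests, and `tests/test_acceptance.py`
covering the end-to-end acceptance criteria (synthetic separability, null
calibration, scaling-law recovery, invariance suites, lock-box guard).
The full run takes roughly two minutes on one CPU.

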