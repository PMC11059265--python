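# imusway

Postural-sway biomarker pipeline for waist-worn IMU recordings. The package
implements, as tested reusable components:

* **synth_cohort** — a synthetic sway-cohort generator (subject table +
  per-trial accelerometer/gyroscope recordings at 64 Hz across four stance
  conditions EO/EC/RL/LL), with a configurable planted group effect whose
  feature-level signatures match the directions reported for MCI vs CN
  cohorts (higher sway velocity, path length, mean frequency and spectral
  entropy; lower excursion amplitude and sway area).
* **signal_prep** — trial CSV I/O, 8th-order zero-phase low-pass Butterworth
  filtering (5 Hz cutoff), sensor-to-anatomical axis mapping (x→ML, y→V,
  z→AP), gravity removal by per-channel demeaning, and the signal vector
  magnitude series.
* **sway_features** — the fixed 76-measure sway battery (43 time-domain +
  33 frequency-domain measures, Welch PSD with Hann window / 256-sample
  segments / 50% overlap, analysis band (0, 5] Hz).
* **feature_ranking** — hybrid filter (ANOVA F, mutual information) +
  wrapper (random-forest importance, linear-SVM weights) feature scoring
  over leave-one-subject-out folds, with top-15 counting, score fusion and
  cross-session combination.
* **model_eval** — LOSO classification (SVM, random forest, gradient
  boosting, majority voting) with confusion-matrix metrics, plus an
  MMSE-AUC baseline.
* **explain_stats** — Shapley attribution (exact coalition enumeration up
  to 12 features, seeded Monte-Carlo permutation sampling beyond),
  Shapley-vs-score ranking overlap, two-group demographics ANOVA (raw or
  summary mode) and Tukey boxplot group summaries.

## CLI

The `imusway` entry point chains the pipeline stages:

```sh
imusway simulate --config cohort.yaml --out raw --seed 7
imusway preprocess --in raw --out sway --fc 5 --order 8
imusway extract --in raw --out features.csv
imusway rank --features features.csv --subjects raw/subjects.csv \
    --session EO --top-k 15 --out scores.csv
imusway classify --features features.csv --subjects raw/subjects.csv \
    --session EO --model svm --mode nested --out metrics.csv
imusway explain --features features.csv --subjects raw/subjects.csv \
    --session EO --k 15 --out explain_out
imusway demographics --subjects raw/subjects.csv
```

`cohort.yaml` may set any `CohortSpec` field, e.g.:

```yaml
n_cn: 30
n_mci: 30
trials_per_subject: 2
sessions: [EO, EC, RL, LL]
trial_duration_s: 30.0
effect_scale: 1.0
```

Recording files are one CSV per trial
(`<subjectID>_<session>_<trial>.csv`, columns
`time_s,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z`, m/s² and deg/s); the subject
table is `subjects.csv` with
`subject_id,group,mmse,age,sex,height_cm,weight_kg,education_yr`.

## Notes

* Classifier evaluation offers a leakage-free `nested` mode (per-fold
  feature re-selection, the default) and a `paper` mode that uses one
  global top-15 list per session.
* Metrics can be computed per trial (default) or aggregated per subject by
  majority vote (`per_subject_vote`).
* Since no real recordings ship with the package, all statistical claims
  are exercised on the synthetic cohort generator, which is itself
  first-class, tested code (determinism, null calibration, monotone effect
  planting, stationarity).
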