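# fogait

Single-foot-IMU gait analysis for Parkinsonian gait: a causal rest/unrest/motion
gait-phase state machine, spatio-temporal feature extraction via quaternion
sensor fusion and strap-down integration, motion-phase-wise freezing-of-gait
(FoG) detection/prediction with SVM and AdaBoost under leave-one-patient-out
cross-validation, a spectral freezing-index baseline, and a synthetic gait
generator that provides ground truth so the whole pipeline is testable without
clinical data.

## Modules

| Module | Purpose |
| --- | --- |
| `fogait.data_io` | CSV/YAML/JSON I/O for recordings, annotations, parameters and feature tables; core domain types (`ImuSeries`, `AnnotatedEpisode`, `GpdParams`) |
| `fogait.orientation` | Complementary quaternion filter (gyro strap-down + gated gravity correction), global-frame transform, rest-offset estimation, jerk |
| `fogait.gait_segmentation` | The gait-phase state machine: debounced rest/unrest detection, motion-phase start (pitch peak or roll/acceleration correlation), end (jerk+velocity or pitch minimum), and Z-reactivation for step sequences without inter-step rest |
| `fogait.feature_extraction` | 10 features per motion phase (strap-down stride/velocity with zero-end-velocity drift correction, pitch extrema, turning, turn rates, duration); chi-square feature ranking; lagged design matrices (`C0`, `C210`, `C21`) |
| `fogait.fog_classification` | FoG labeling from expert episodes (OR/AND), rater agreement, SVM_10/SVM_5/AdaBoost training with shipped hyperparameter defaults, LOPO cross-validation, paired t-tests, best-foot selection, pre-akinesia fraction |
| `fogait.baseline_fi` | Sliding-window freezing index (3–8 Hz freeze band over the locomotor band) with per-patient thresholding and 6-axis majority voting |
| `fogait.synthetic_gait` | Analytic step/recording generator (normal, shuffling, festination, trembling, akinesia, turns) with ground-truth events, plus feature-level cohort simulation for classifier evaluation |

## CLI

```bash
# synthetic recording + ground truth + two simulated raters
fogait simulate --seed 1 --out demo/

# gait-phase segmentation (Table-style defaults; YAML overrides via --params)
fogait segment demo/recording.csv --out demo/phases.json

# per-motion-phase feature table, optionally labeled from annotations
fogait extract demo/recording.csv --annotations demo/annotations.csv --out demo/features.csv

# classifier training / leave-one-patient-out evaluation
fogait train --variant C210 --model SVM_10 --out demo/model.joblib
fogait evaluate --variant C210 --model SVM_10 --out demo/report.json

# freezing-index baseline
fogait baseline-fi demo/recording.csv --window 6 --threshold 1.0 --out demo/fi.json
```

Scenario files for `simulate` are YAML lists, e.g.

```yaml
- {mode: normal, n_steps: 5}
- {mode: festination, n_steps: 5}
- {mode: trembling, duration: 3.0}
```

## Conventions

- Sensor frame at rest: z up, y opposite the walking direction, x mediolateral.
  Foot pitch is the rotation about x, positive when the heel is above the toes.
- Recording CSV: one units header line, columns `t, ax, ay, az, gx, gy, gz`
  (seconds, m/s², rad/s; `deg/s` gyro headers are converted on read).
- Angles are radians internally; configuration files and parameter defaults use
  degrees.
- Annotations CSV: `start, end, subtype, rater` with half-open episode
  intervals `[start, end)` and subtypes
  `festination | shuffling | trembling | akinesia`.
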