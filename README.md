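# wristgait

Detecting bouts of walking in multiday wrist-accelerometer recordings of
daily living, and turning the detections into gait quantity and quality
measures.

Wrist-worn accelerometers are the most wearable of wearables, but the wrist
is a hostile place to detect gait: hand movements occur constantly without
walking, walking occupies only a small fraction of a day (heavy class
imbalance), and older adults or people with Parkinson's disease walk with
reduced amplitude and regularity. `wristgait` implements five detectors
spanning the methodological range used for this problem, the shared
preprocessing and labelling rules, an imbalance-aware evaluation suite, and
the downstream daily-living gait measures — all exercisable end to end on a
seeded synthetic cohort generator, so every stage is testable without any
recording hardware or data download.

The package is aimed at movement-science and digital-biomarker researchers
who want a transparent, dependency-light reference implementation of these
methods to benchmark on their own labelled data.

## The detectors

| name | kind | output |
|---|---|---|
| `maf` | one-class masked autoregressive flow (unsupervised) | window gait probability |
| `fb` | time/frequency feature thresholds | binary window decision |
| `arihmm` | sticky HDP autoregressive HMM segmentation | per-sample state → gait flag |
| `dcnn` | 1-D U-Net semantic segmentation (3 × 512 windows) | per-sample probability |
| `lstm` | residual bidirectional LSTM (6 s windows) | window probability |

The flow detector is the methodological core. A masked autoregressive flow
(MAF) stacks five MADE layers, each an autoregressive affine map

u_i = (x_i − μ_i(x_{<i})) · exp(−α_i(x_{<i})),

whose triangular Jacobian gives the exact density by change of variables:

log p(x) = log N(f⁻¹(x); 0, I) + Σ_layers Σ_i (−α_i).

Trained by maximum likelihood (ADAM, exponentially decaying learning rate
from 0.01, l2 regularization) on windows of one class only ("normal" = gait
by default; the non-gait direction is also supported), it scores unseen
windows by the anomaly score −log p(x); an empirical-CDF calibration maps
scores to gait probabilities so the global high-precision threshold of 0.9
applies uniformly across detectors.

All detectors share the conditioning chain: Euclidean norm → moving-STD
activity gate (3 s blocks, 0.1 m/s² threshold) → 6 s windows with 50 %
overlap → per-window DC removal → training-set normalization, with
subject-disjoint five-fold cross-validation (no subject appears in both
train and test folds). Evaluation reports accuracy, specificity,
sensitivity and precision (in percent), balanced accuracy, and ROC/PR
curves with trapezoid AUCs, aggregated as mean ± fold STD. Daily gait
quantity (walking minutes on wear days ≥ 8 h) and per-bout gait quality
(locomotor-band dominant frequency and its normalized amplitude, RMS,
stride regularity) are computed from the 0.9-thresholded predictions.

The neural detectors run on a small reverse-mode automatic-differentiation
engine over numpy arrays (`wristgait._autodiff`, `wristgait.nn`) written
for this package; training is seeded and reproducible.

## Worked example

Simulate a five-subject cohort, run the AR–HMM segmenter through
subject-disjoint five-fold cross-validation, and extract gait measures —
from Python:

```python
from wristgait.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(detector="arihmm", n_subjects=5, days=1,
                       sim={"duration_s": 1200.0},
                       detector_params={"sweeps": 60, "burn_in": 20},
                       min_wear_h=0.2, seed=1)
res = run_experiment(cfg)
print(res.summary())
print(res.quality["predicted"]["group"].round(3))
```

prints

```
experiment: detector=arihmm profile=hya seed=1
============================================================
                    mean    std
accuracy           93.91   4.81
specificity        99.98   0.02
sensitivity        43.68  44.74
precision          99.82   0.21
balanced_accuracy  71.83  22.36
roc_auc             0.98   0.02
pr_auc              0.89   0.09

                     mean     sd
dominant_frequency  1.500  0.250
amplitude_dominant  0.519  0.043
rms                 1.493  0.229
stride_regularity   0.952  0.019
```

Reading the numbers: at the high-precision 0.9 threshold the segmenter
almost never cries wolf (precision 99.8 %, specificity ~100 %) but misses
many gait samples (sensitivity 43.7 % with large spread across folds) — the
precision/recall trade-off that dominates wrist-based gait detection under
class imbalance. The continuous score is far more informative (ROC AUC
0.98, PR AUC 0.89). The recovered gait quality of the detected bouts
matches the generator: dominant frequency 1.5 Hz (the configured cadence),
stride regularity near 1 for nearly periodic synthetic gait.

The same pipeline is scriptable from the shell:

```bash
wristgait simulate --subjects 2 --days 1 --seed 3 --out runs/sim
wristgait run --detector fb --seed 1 --out runs/fb
wristgait compare --detectors fb,lstm --seed 1 --out runs/compare.csv
```

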