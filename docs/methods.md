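# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `wristgait`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute at
run time.

## Problem setting

Input is a tri-axial wrist acceleration series (m/s², 25–100 Hz), optionally
with a per-sample binary gait annotation derived from a reference sensor and
downsampled by nearest-neighbour interpolation (ties resolve to the earlier
sample). Gait bouts are maximal runs of gait-labelled samples; runs shorter
than 6 s are relabelled non-gait, because very short bouts can be neither
detected reliably nor characterized by quality measures. Intervals are
0-based half-open `[start, end)`. Day boundaries are wall-clock midnights
relative to the recording start time, which defaults to midnight.

## Shared preprocessing

* **Euclidean norm** per sample removes orientation dependence.
* **Activity gate**: non-overlapping 3 s blocks of the norm with standard
  deviation below 0.1 m/s² are flagged low-activity. The gated detectors
  (flow, AR–HMM) excise these samples before windowing; the supervised deep
  detectors consume ungated windows and learn to ignore rest themselves.
* **Windows**: 6 s with 50 % overlap (hop = L/2); the trailing partial
  window is discarded; each axis of each window is mean-centred, which also
  cancels the constant gravity component. Window count obeys
  `floor((N − L)/hop) + 1`.
* **Window labels**: strict majority — a window is gait iff more than half
  of its samples are gait-labelled.
* **Normalization**: per-feature mean/SD estimated on the training split
  only and applied unchanged to validation/test; zero-variance features are
  dropped with a warning.
* **Folds**: subjects are partitioned into k = 5 disjoint folds. When
  per-subject gait percentages are available, a greedy pass (largest
  percentage first, fold sizes capped) keeps fold gait percentages close to
  the global mean, so folds are comparably imbalanced.

## The one-class flow detector

A masked autoregressive flow with 5 MADE layers; each layer's shift and
log-scale networks have two hidden layers of 64 ReLU units, with
connectivity masks enforcing the autoregressive property and the dimension
ordering reversed between consecutive layers. The base density is standard
Gaussian; the log-density is exact by the change-of-variables formula. The
shift/log-scale output heads are zero-initialized, so an untrained model is
exactly the identity map — a property the unit tests exploit for
closed-form checks — and training starts from a well-conditioned point.

Training: maximum likelihood on windows of the designated normal class
(gait by default; non-gait supported), 90/10 train/validation split, ADAM
with exponential learning-rate decay (initial 0.01, rate 0.95/epoch), l2
weight decay (default 0.001; 0.01 suits the degraded cohort profiles),
batch 256, up to 100 epochs with early stopping on validation negative
log-likelihood (patience 10), global gradient-norm clipping at 5.

**Window features.** The flow sees log band-power vectors: the power
spectrum of each DC-removed, gated window is summed over the three axes and
pooled into 12 equal-width bands over [0, Nyquist], then log-transformed.
Band powers are invariant to the phase at which a window cuts the gait
cycle and insensitive to small cadence differences between subjects, so
windows of the same movement type form one cluster that a density model can
learn. Flattened raw windows (available via `features="flat"`) are a poor
density-estimation substrate here: two windows of identical walking differ
by an arbitrary cycle phase, the class difference is largely a scale
difference, and maximum-likelihood density models notoriously assign high
likelihood to low-complexity, low-amplitude inputs outside the training
class — with raw windows the anomaly ranking can invert outright.

**Scoring.** Anomaly score = −log p(x). Scores map to gait probabilities
through the empirical CDF (mid-rank ties) of the held-out validation
scores: for a gait-trained model, a score below every calibration score
maps to probability 1 and the calibration median to 0.5; the non-gait
direction uses the complement. Far out-of-distribution inputs can overflow
the affine scales; their log-density saturates at a large negative value
rather than propagating non-finite numbers.

Two evaluation protocols are provided: the one-class protocol (train on
90 % of the normal class pooled over the cohort, test on the held-out 10 %
plus all windows of the other class) and subject-disjoint cross-validation
(train the flow on the training folds' normal windows, score the held-out
subjects). The first measures density-estimation quality under the method's
own design; the second is the stricter deployment-style estimate and is
what the pipeline reports.

## Feature-based classifier

Per 6 s window, on the DC-removed norm: RMS, dominant frequency over
0.1 Hz–Nyquist (Hann periodogram), locomotor-band (0.5–3 Hz) peak
frequency, band-power ratio and peak prominence (peak over mean band
power). A window is gait iff RMS ≥ 1 m/s² (the activity gate, applied at
window level), the dominant frequency lies in-band, band ratio ≥ 0.4 and
prominence ≥ 3. The two latter cut-offs are this package's own defaults,
set once on hya-profile synthetic data; all four are configuration-exposed.
Output is a hard binary decision, so this detector appears in metric tables
but not in ROC/PR analyses. Raising any threshold can only shrink the
positive set (monotonicity, property-tested).

## AR–HMM segmenter

The gated, mean-centred norm is modelled as switching AR(p) regimes
(default p = 5 at 25 Hz) under a weak-limit sticky hierarchical-Dirichlet-
process HMM truncated at K_max = 20 states: top-level stick weights
β ~ Dir(γ/K, …), rows π_j ~ Dir(αβ + κe_j) with a self-transition mass
κ = 50 that favours temporally coherent segments (defaults α = γ = 4).
Blocked Gibbs sweeps alternate (i) conjugate Normal–Inverse-Gamma updates
of each regime's AR coefficients and innovation variance (coefficient prior
N(0, 10² I); variance prior scaled to the data), (ii) forward-filter
backward-sample of the state sequence, (iii) table-count (Chinese
restaurant) auxiliary updates with the sticky override correction for β and
π. Default 150 sweeps with 50 burn-in; the reported segmentation is the
sweep with the highest complete-data log joint after burn-in, which makes
the output a single reproducible point estimate rather than a posterior
summary. A convergence flag checks that the trailing log-joint window has
stabilized (relative spread ≤ 2 %).

Each state k induces the parametric spectral density
S_k(f) = σ²_k / (fs · |1 − Σ_m a_{k,m} e^{−i2πfm/fs}|²), a two-sided
density: the integral over [−Nyquist, Nyquist] approximates the process
variance. States are called gait when their trapezoid-integrated PSD over
0.5–3 Hz exceeds a threshold chosen to maximize balanced accuracy of the
state-level assignment against the training labels; the integrated band
power of the decoded state also serves as a continuous per-sample score
(for curves, calibrated through the training-score empirical CDF). New
recordings are decoded by Viterbi under the fitted parameters, which is
deterministic. Predictions are invariant to state relabelling
(property-tested).

## Deep detectors

Both run on the package's reverse-mode autodiff engine (float64; seeded
Glorot initialization; fixed batch order ⇒ bit-reproducible training).

**U-Net segmenter.** Input 3 × 512 windows (≈ 20.5 s at 25 Hz; batch 64),
the three axes as input channels. Four encoder levels (channels 16, 32, 64,
128 by default; kernels span 5 time steps; max-pool ×2 along time),
bottleneck with dropout 0.2, mirrored decoder with nearest-neighbour
upsampling and skip concatenation, 1×1 output convolution → per-time-step
sigmoid probability. Batch normalization after every convolution. Loss:
per-time-step binary cross-entropy (softplus form) with optional
positive-class weighting. Inputs are standardized per axis by training-set
statistics. Whole recordings are cut into 512-sample windows at 50 %
overlap plus one final right-aligned window; overlapping outputs merge by
per-sample averaging, so the prediction has exactly the recording's length.
Thresholding at 0.9 yields a subset of the 0.5-positives (nesting,
property-tested).

**Residual bidirectional LSTM.** 6 s windows; 2 stacked bidirectional
layers, 64 hidden units per direction (tests use smaller), forget-gate bias
1, dropout 0.2 between layers; identity skip connections across cell
outputs from the second layer on (the stacked width 2H matches, so the skip
is a plain addition). The window decision is a sigmoid readout of the
concatenated final states of both directions — the choice made where a
pooling rule had to be fixed. Per-axis input standardization from training
statistics; best-validation checkpointing.

## Evaluation

Confusion counts and the four percent metrics (accuracy, specificity,
sensitivity, precision) follow the standard definitions; zero-denominator
metrics are returned as NaN ("undefined") and excluded from fold means with
a warning, never imputed. Balanced accuracy = (Se + Sp)/2 is exported.
ROC curves keep every distinct threshold (no intermediate dropping); the
trapezoid ROC AUC therefore equals the Mann–Whitney all-pairs probability
with ties half-weighted, which the tests verify to 1e−10. PR curves are
integrated by trapezoid along the threshold-ordered path (recall 0 → 1,
anchored at the conventional (0, 1) endpoint); vertical precision drops at
repeated recall values contribute zero width. This is the achieved-point
trapezoid, not interpolated average precision. Positive decisions use
`prob > threshold` with the high-precision default 0.9.

Cross-detector comparisons are harmonized at sample level: window
probabilities spread back onto samples by averaging the covering windows;
gate-excised samples count as non-gait (probability 0). The feature-based
row carries no AUC entries.

## Gait quantity and quality

* **Daily walking minutes**: per calendar day, the sum of positive samples
  divided by 60·fs, restricted to wear days with ≥ 8 h of recording;
  predicted and reference minutes are compared by Pearson correlation.
* **Quality measures**, per predicted bout longer than 10 s (bouts
  reconstructed from the thresholded mask with the 6 s detection rule
  first): Welch PSD of the DC-removed norm (4 s Hann segments, 50 %
  overlap); dominant frequency = argmax in 0.5–3 Hz; amplitude = that
  peak's single-bin power divided by total power (unitless); RMS of the
  DC-removed norm; stride regularity = the dominant peak of the biased,
  zero-lag-normalized autocorrelation searched between one half and twice
  the dominant period. The biased estimator shrinks the value by a factor
  (1 − lag/N), ≈ 0.97 for a 20 s bout at 1.5 Hz — the price of a bounded,
  low-variance estimate; perfectly periodic bouts therefore score slightly
  below 1.
* **Aggregation**: per-day medians of bout values, then per-subject medians
  of daily values; group summaries as mean ± SD across subjects. Agreement
  between wrist-predicted and reference daily values: Pearson r per
  measure with Bonferroni correction (α/4).

The 6 s detection rule and the 10 s quality rule are deliberately two
distinct thresholds: a bout can be detectable yet too short for stable
spectral and autocorrelation estimates.

## Synthetic cohort generator

The generator emulates the statistical structure the detectors assume, not
arm biomechanics:

| parameter | default | rationale |
|---|---|---|
| fs | 25 Hz | consumer wrist-device rate |
| duration | 3600 s | desk-scale recording session |
| gait fraction | 0.10 | realistic daily-living rarity of walking |
| bout duration | log-normal, mean 19.5 s, SD 4.1 s, truncated ≥ 6 s | field-typical daily-living bout statistics |
| step frequency | 1.5 Hz (hya), subject jitter SD 0.15 Hz | locomotor-band dominant frequency of healthy adults |
| harmonics | weights 0.4, 0.2 at 2f, 3f | quasi-sinusoidal wrist gait signal |
| gait amplitude | 3.8 (hya) / 1.9 (oa) / 1.6 (pd) m/s² | produces bout RMS in the ranges typical of each cohort |
| regularity jitter | 0.05 / 0.15 / 0.20 | cycle-level phase+amplitude random walk; 0 = perfectly periodic |
| bursts | 40/h, amp 1.5 m/s², mean 10 s, low-pass noise | non-gait hand activity |
| sensor noise | 0.05 m/s² | rest periods fall below the 0.1 m/s² gate |
| tremor (pd) | 0.3 m/s² at 4–6 Hz | parkinsonian rest tremor band |

Gravity (9.80665 m/s²) lies along a random fixed axis. The gait component
is projected onto a direction whose alignment with gravity is drawn with
|cos| ∈ [0.4, 0.9]: forearm swing rotates the sensor through the gravity
field, so the acceleration norm is modulated at the step frequency — with
an orthogonal direction the norm would only carry the (quadratic,
frequency-doubled) residue, which is not how wrist signals behave. Bout
placement draws durations until the target gait time is reached and
scatters them over Dirichlet-distributed gaps; bouts ramp in/out over
0.5 s. Per-subject seeds derive from SHA-256 of (master seed, subject,
day), so any subject's data regenerate identically regardless of cohort
size or generation order, and a fixed seed reproduces recordings
bit-exactly.

What the generator does **not** emulate — postural transitions, non-gait
periodic activities (tooth-brushing, typing), sensor drift and non-wear,
broadly varying gait styles — bounds what passing tests show: they certify
the algorithmic machinery (density estimation, segmentation, training,
evaluation, measures) on data with the assumed structure, not clinical
performance on real cohorts. On this synthetic structure the detectors are
substantially stronger than they would be on real recordings, where the
non-gait class is far richer.

## Numerical and scale choices

Acceptance-style runs use desk-scale problem sizes chosen as the package's
own defaults for a laptop-class single CPU: five subjects with 20–60 min
recordings, flow training capped at 25 epochs, AR–HMM at 60–100 Gibbs
sweeps, deep detectors at ≤ 8 epochs with reduced widths (8 base channels /
32 hidden units), and a 10 000-sample two-regime switching-AR benchmark.
The supervised detectors are evaluated on a single 3/2 subject-disjoint
split in the acceptance script; the fast detectors run the full five-fold
protocol. Negative controls for the supervised detectors follow
permutation-test logic: labels are shuffled in the training pool and the
measured AUC is averaged over permutations of the held-out labels, whose
null distribution is centred on 0.5 regardless of what the shuffled-trained
network outputs.

Determinism: every stochastic stage receives a seed derived from the single
experiment seed via SHA-256 tags; re-running an experiment with the same
configuration reproduces the synthetic data checksum and all deterministic
outputs bit-exactly.

## Known limitations

* The flow's probability calibration is an empirical CDF of (at most a few
  hundred) validation scores; probabilities are rank-based, and the fixed
  0.9 threshold on them is a convention, not an optimized operating point.
* The AR–HMM point estimate discards posterior uncertainty; label
  switching across reruns with different seeds is expected and harmless.
* The AR–HMM is trained on concatenated recordings; the p samples at each
  junction are modelled as if contiguous.
* Deep-detector training on the numpy engine is CPU-bound; the defaults
  are sized for desk-scale experiments, not for multiday cohorts at 100 Hz.
* `wear_site` is carried through the data model, but no lower-back
  detection algorithms are implemented; reference labels are taken as
  given.
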