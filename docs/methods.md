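# Methods

## Data model and segmentation

The unit observation is one complete calendar day of wrist actigraphy: 1440
non-negative integer counts, one per minute, ordered 00:00 → 23:59. Records
are binned by the calendar date and wall-clock minute of their timestamp;
daylight-saving or timezone shifts are not modelled, since the day is
treated as a fixed 1440-slot grid. Days missing any minute are dropped, not
imputed, and each subject contributes the 7 earliest complete days.
Earliest-first is a convention chosen for determinism — any 7-day window
would serve, and nothing downstream depends on which week is chosen beyond
reproducibility. Duplicate timestamps are an error rather than being
averaged: they indicate a malformed export, and failing loudly beats
silently halving a day's counts.

Labels are per subject (0 = control, 1 = depressed) and are copied to all 7
of a subject's day-vectors.

## Splitting

The split is by observation (day), not by subject: 70/30 with the train
size ⌊0.7·N⌋, which maps 385 observations to 269/116. Stratified splitting
(per-class proportions preserved to within one row via largest-remainder
apportionment) is the default; unstratified is available. Day-level
splitting places days of the same subject on both sides, an optimistic-bias
caveat inherent to this protocol; a grouped (per-subject) split would
change the estimand and is deliberately not implemented here.

## ADASYN

Implemented exactly from the balance equations, with these documented edge
conventions:

* The synthetic total is G = (m_l − m_s)·β. A printed form with the
  operands reversed would be negative; the sign used here is the one that
  makes G "the number of synthetic examples to generate".
* Per-point budgets g_i = r̂_i·G are integerised by largest-remainder
  apportionment so they sum to G exactly; plain rounding does not.
* When every minority K-neighborhood is purely minority, Σr_i = 0 and the
  density r̂ is a 0/0; the budget is then spread uniformly (r̂_i = 1/m_s).
* The interpolation partner x_z is drawn uniformly from the minority
  members of x_i's K-neighborhood; if there are none, the globally nearest
  minority point is used, since the interpolation formula requires a
  minority partner.
* Defaults K = 5, β = 1, d_th = 1 (balance whenever any imbalance exists);
  all exposed and recorded in run manifests.

Neighbor queries use scikit-learn's `NearestNeighbors` (Euclidean, in the
full 1440-dimensional space); the ADASYN logic itself is authored here and
cross-checked in the tests against an exhaustive-distance reference.

With a stratified 269-row training portion (157 majority / 112 minority),
β = 1 yields 45 synthetics and a 157/157 balance. A published balanced
count of 156/145 from the same starting sizes is not reproducible from the
stated equations under any (β, d_th) with a deterministic split; the knobs
are exposed rather than tuned toward those counts.

## Normalization

Per-column z-score, population σ (ddof = 0, configurable), fitted after
balancing and on the training rows only, then reused on the test rows;
σ = 0 columns map to 0. Fitting on the pooled data (`scope="all"`) is
available to replicate the alternative reading, but train-only fitting is
the default because anything else leaks test statistics into training.
Stage order is balance → normalize.

## Classifier

Input 30×48×1: the day-vector reshaped row-major, 48 consecutive minutes
per row. The fill order is fixed; changing it changes every receptive
field. The published layer table is internally inconsistent — 3×3 kernels
with stride 1 and padding 1 cannot map 30×48 to 26×44 — but its feature-map
column is self-consistent under exactly one reconstruction, which is the
default here (`mode="reconstructed"`):

| stage | kernel | mode | output |
|---|---|---|---|
| conv1 | 5×5 | valid | 26×44×48 |
| pool1 | 3×3, stride 2 | valid, ceil | 13×22×48 |
| conv2 | 3×3 | valid | 11×20×48 |
| pool2 | 3×3, stride 2 | valid, ceil | 5×10×48 |
| conv3 | 3×3 | valid | 3×8×48 |
| pool3 | 3×3, stride 2 | valid, ceil | 1×4×48 |

then dense 192 → 900 → 300 → 100 → 2. A `literal` mode (every kernel 3×3,
padding 1, padded pools) is kept behind a flag because the true first
kernel is unknowable from the table alone. Dropout p = 0.5 after each pool
and after each of the first three dense ReLUs. The head is two sigmoid
units trained with binary cross-entropy against one-hot targets (as
printed, rather than a softmax); the hard label is the argmax and the
class-1 score is the ROC score. Optimizer Adam, learning rate 1e-3, batch
32, 14 epochs — optimizer and batch size are unstated upstream, so these
defaults are explicit, configurable and logged.

The network is written directly in NumPy in float64: convolution as an
im2col matrix product (cross-correlation), ceil-mode pooling via −inf edge
padding, inverted dropout. The backward pass is verified against central
finite differences in the test suite, and the convolution layer against a
deliberately naive double-sum convolution oracle (kernel flipped). Training
is bit-reproducible for a fixed seed and thread count.

The overfitting check compares final-epoch validation loss to training
loss: more than `tol` (0.05) below → underfit; up to `margin` (0.25) above
→ acceptable; beyond → overfit. The thresholds are reporting conventions,
not fitted quantities.

## Evaluation

Positive class is 1 (depressed). Accuracy, precision, recall ≡ sensitivity,
specificity and F1 = 2PR/(P+R) are computed from TP/TN/FP/FN; a printed
F1 form without the factor 2 is a typo — the published per-class numbers
(P = 0.69, R = 0.75 → F1 = 0.72) require the harmonic mean. Zero
denominators return 0 with a warning (strict mode raises). The report
gives per-class metrics with each class in turn as positive, macro
(unweighted) and weighted (support-weighted) averages, rendered at two
decimals with unrounded values retained.

The ROC sweeps thresholds over distinct scores with ties grouped into one
step, and AUC is the trapezoid rule over the resulting curve, which equals
the Mann–Whitney statistic P(s⁺ > s⁻) + ½P(tie); the garbled printed
increment definitions are replaced by the standard rule and the equality is
asserted to 1e-12 in tests.

Cross-validation partitions the *training* portion into k = 3 seeded folds
(test portion untouched); balancing and normalization are re-fitted inside
each fold so no fold sees statistics from its held-out part. Per-fold
held-out accuracy and BCE loss are reported with arithmetic means.

## Synthetic cohorts

The simulator exists so the pipeline is testable without any download. A
control day has expectation `baseline_mean · (1 + amplitude·cos(2π(h −
wake_phase)/24))` (defaults 240 counts/min, amplitude 0.4, peak 14:00)
while awake, and `sleep_mean` = 2 counts/min in the 23:00–07:00 sleep
window. Counts are negative binomial with shape `noise_dispersion` = 1.5
(variance μ + μ²/1.5), matching the zero-inflated overdispersion of real
actigraphy better than Poisson noise. Condition subjects get the awake mean
multiplied by `depression_activity_factor` (default 0.6) and each awake
20-minute bout zeroed with probability `depression_fragmentation`
(default 0.15) — a minimal emulation of the reduced, fragmented activity
visible in real depressed traces. Defaults are the study-cohort conditions:
32 control / 23 condition subjects, 7 days each.

What the simulator does **not** emulate: ultradian cycles, weekday
structure, inter-subject heterogeneity beyond count noise, severity
gradients, device artefacts. Consequently a passing end-to-end test shows
the pipeline is correct and sensitive to a planted effect of known size —
not that the accuracy on real cohorts will match. The default effect is
strongly separable by design, so held-out accuracy on synthetic data is
near 1.0, and exactly chance under the null (factor 1, no fragmentation),
which is the pair of behaviours the end-to-end tests pin down.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 55-subject pipeline (385
images, 14 epochs) for the end-to-end checks and smaller cohorts (9–16
subjects, 2–5 epochs) for orchestration and determinism checks — sizes
chosen to exercise every code path at the study's scale while keeping a
complete run in minutes on one CPU. All randomness flows from one master
seed split deterministically into per-stage seeds (simulate, split,
balance, train, cv) recorded in each manifest. Degenerate inputs are
defined rather than accidental: σ = 0 columns → 0; zero metric
denominators → 0 with a warning; single-class inputs are errors for
ADASYN, ROC and stratified splitting; k-NN ties and apportionment ties
break by stable index order.

## Known limitations

* Day-level splitting leaks subject identity across the split (above);
  results on real data should be read as day-classification, not
  subject-level screening performance.
* The reconstructed architecture is one consistent reading of an
  inconsistent published table; the literal mode is kept for comparison.
* The NumPy implementation is single-threaded BLAS-bound; it is sized for
  this model (≈300 images of 30×48), not for large-scale training.
* MADRS severity is not modelled anywhere; the label is binary group
  membership.
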