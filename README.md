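# actidep

Detection of depressive episodes from one week of wrist actigraphy with a
small two-dimensional convolutional classifier.

## The problem

Actigraphs are wrist-worn accelerometers that record gross motor activity as
one integer count per minute. Depressed subjects show globally reduced and
more fragmented motor activity than healthy controls, so a week of per-minute
counts carries diagnostic signal that can be read without clinical
interviews. This package implements, end to end, a pipeline that turns raw
per-subject actigraphy CSVs (the Depresjon layout: `control/*.csv`,
`condition/*.csv` with columns `timestamp,date,activity`) into a trained,
evaluated binary classifier, for researchers in digital phenotyping who want
a reproducible, dependency-light reference implementation.

## The method

1. **Day-vectors.** Each complete calendar day of a subject becomes a vector
   of its 1440 per-minute counts (00:00 → 23:59). The first 7 complete days
   per subject enter the observation matrix *A*; a cohort of 55 subjects
   (32 control, 23 condition) yields 385 rows, each labelled 0 (not
   depressed) or 1 (depressed) by its subject's group.
2. **Split.** A seeded 70/30 shuffle split: 269 training rows, 116 test
   rows (train size is ⌊0.7·N⌋).
3. **ADASYN balancing** of the training rows: with imbalance degree
   d = m_s/m_l below the threshold d_th, G = (m_l − m_s)·β synthetic
   minority rows are generated, allocated per minority point *x_i*
   proportionally to the majority share r_i = Δ_i/K of its K-neighborhood
   (normalised to r̂_i, integerised so Σg_i = G), each synthesised as
   s = x_i + (x_z − x_i)·λ with λ ~ U[0,1] and x_z a minority K-neighbor.
4. **z-normalization** per column, z = (x − μ)/σ, fitted on the balanced
   training rows only.
5. **2D-CNN.** Each day-vector is a 30×48 single-channel image (row-major,
   48 consecutive minutes per row). The classifier stacks three 48-filter
   convolution blocks (conv → ReLU → 3×3 max-pool, stride 2, ceil
   rounding → dropout 0.5), with feature maps
   26×44 → 13×22 → 11×20 → 5×10 → 3×8 → 1×4 (×48), then dense layers
   900 → 300 → 100 → 2 with a sigmoid head, trained with binary
   cross-entropy on one-hot targets (Adam, 14 epochs, batch 32). The
   network is implemented directly in NumPy with a finite-difference-
   verified backward pass.
6. **Evaluation.** Confusion-matrix metrics (accuracy, precision,
   recall ≡ sensitivity, specificity, F1 = 2PR/(P+R)), trapezoidal
   ROC/AUC (verified against the Mann–Whitney rank statistic), a per-class /
   macro / weighted classification report, an overfitting check comparing
   validation and training loss, and 3-fold cross-validation on the
   training portion.

A bundled simulator generates seed-stable synthetic cohorts in the same CSV
layout (circadian activity profile, near-zero nocturnal counts,
negative-binomial noise; condition subjects get a multiplicative daytime
reduction and extra zero-activity bouts), so everything is testable without
downloading data.

## Worked example

```sh
actidep run-all --seed 1 --out scratch/run --skip-cv
```

simulates the default 55-subject cohort, builds the 385×1440 matrix, splits
269/116, balances the training portion (157/112 → 157/157 with β = 1),
trains 14 epochs and prints the held-out report:

```
                 Precision  Recall  F1-Score  Support
Not Depressed         1.00    1.00      1.00       67
Depressed             1.00    1.00      1.00       49
Accuracy                                1.00      116
Macro avg             1.00    1.00      1.00      116
Weighted avg          1.00    1.00      1.00      116
accuracy 1.0000  auc 1.0000  sensitivity 1.00  specificity 1.00
```

The default simulated effect (activity factor 0.6 plus fragmentation 0.15)
is strongly separable, so the classifier is essentially perfect on synthetic
data; under a null simulation (factor 1.0, no fragmentation) the same
pipeline scores at chance. Real actigraphy is far noisier — see
`docs/methods.md` for what the simulator does and does not emulate.

The same stages are available individually (`simulate`, `prepare`,
`balance`, `train`, `evaluate`, `cv`), all driven by a YAML config plus
flag overrides, and as plain library calls (`actidep.pipeline.run_all`).
Every run writes a manifest with the config, derived per-stage seeds and
data hashes; identical configs reproduce identical manifests.

## Replication note (optional, needs the real data)

With the Depresjon dataset downloaded into `<root>/control` and
`<root>/condition`, `actidep run-all --data-root <root>` runs the identical
pipeline on the real cohort. Held-out accuracy on real data is stochastic
across seeds; a seed sweep is the appropriate protocol, and day-level
splitting places days of one subject on both sides of the split — a leakage
caveat discussed in `docs/methods.md`.
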