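# Methods

## The model

Given an expression profile (samples × variables, two sample groups), the
package ranks variables by a permutation importance that works with any base
classifier, not only with random forest's trees. Samples are first divided
into training and testing halves, stratified by class. The selection phase
then runs r resampling rounds (default r = 500). In round j:

1. a stratified 70% in-bag subsample of the *training* samples is drawn;
2. one base classifier (LDA, kNN, SVM or RF) is fitted on the in-bag samples
   over the **entire** variable space;
3. the remaining 30% out-of-bag (OOB) samples give the round's error rate
   Err_j;
4. for each variable i, the OOB values of column i are permuted **once** and
   the fitted model re-scored, giving Err0_j(i).

The importance of variable i is the accumulated excess error

    importance(i) = Σ_{j=1..r} ( Err0_j(i) − Err_j ) / r .

It is zero in expectation for a variable the classifier does not use (the
estimator is unbiased for uninformative variables and can be negative), and
positive for variables whose corruption damages classification. A feature —
any subset of variables, possibly individually insignificant ones — is then
selected (top-m by rank, or explicitly), an ensemble of r base classifiers of
the same kind is trained on the training samples restricted to that feature,
and the held-out testing half quantifies it: confusion matrix, per-class and
support-weighted precision/recall/F1, ROC/AUC, and a projection heatmap whose
samples are reordered by k-means clustering of the discrete classification
outputs.

Key design choices where the procedure admits more than one reading:

* **In-bag stratification.** The 70% in-bag draw is stratified per class by
  largest-remainder apportionment of round(0.7 · n_train) slots; a remainder
  tie is broken by the round's RNG rather than by class index, so no class
  systematically receives the extra in-bag sample across rounds (for
  margin-dominated learners on uninformative variables a fixed tie-break
  would bias every member toward the same class). An apportionment that would
  leave a class absent from the in-bag set is an error.
* **One model per round.** The model whose permuted-column error is measured
  is the round's full-space model; nothing is refit per variable.
* **Independent permutations.** Each variable gets a fresh permutation within
  the round; a single permutation is never reused across variables.
* **Per-round seeding.** Round j's RNG is derived from the master seed and j
  alone (`SeedSequence(seed, spawn_key=(stream, j))`), so serial and parallel
  execution are bit-identical and extending r does not replay earlier rounds
  differently. Ensemble members use a disjoint stream under the same master
  seed. Within a round the stream order is fixed: in-bag draw, classifier
  seed, then one permutation per variable in ascending order.
* **Ensemble aggregation.** Members are trained on independent stratified 70%
  subsamples (this is what makes r LDA members distinct; training them all on
  the full training set would make them clones). Prediction is an unweighted
  majority vote; the score is the class-1 vote fraction; a tied vote goes to
  class 0 (the lexicographically smaller original label). With r = 500
  hard-label members the vote fraction is effectively continuous and serves
  as the ROC score.

## Base classifiers

All four kinds satisfy one contract (fit on {0,1}-labelled data, hard-label
prediction) and are scikit-learn estimators underneath:

| kind | default hyperparameters | notes |
|------|------------------------|-------|
| LDA  | none | svd solver; tolerates near-singular within-class scatter, so degenerate resamples survive |
| kNN  | k = 5 | Euclidean distance on raw expression values, no scaling |
| SVM  | RBF kernel, cost C = 1 | deterministic |
| RF   | 100 trees per forest | the only seed-dependent kind |

LDA, kNN and SVM are deterministic regardless of the seed; RF is
deterministic given it. Prediction is hard-label only — the method needs no
probabilities, and ensemble scores come from vote fractions.

## The simulator

The generator emulates a two-group miRNA study in which no single variable
separates the groups but one variable pair does. Defaults: 250 positive and
250 negative samples in 40 dimensions; 38 null variables i.i.d.
Normal(m_i, 0.01²) in both classes with m_i ~ Uniform(10, 30) drawn once per
dataset; and variables 0–1 ("miRNA-alternative 1/2") bivariate normal with
class means (1, 1) vs (1.11, 0.89) and shared covariance
[[1, 0.999], [0.999, 1]]. The planted geometry: the informative contrast
x₁ − x₂ has within-class SD √(2 − 2·0.999) ≈ 0.045 against a class gap of
0.22 (Mahalanobis Δ² = 24.2, Bayes error Φ(−Δ/2) ≈ 0.70%), while each
marginal's gap of 0.11 is buried under a marginal SD of ~1 — so the pair is
2-D separable but 1-D chance-level. One seeded stream draws, in order, null
means, pair values (positives first, via the Cholesky factor), null values.

What the simulator does *not* emulate: count noise (it is Gaussian, not
negative-binomial), library-size or batch effects, heavy tails, missingness,
and realistic gene–gene correlation structure beyond the single planted pair.
Tests passing on it therefore certify the selection machinery — that an
individually-insignificant but jointly-informative pair is found and that
uninformative variables score ~0 — not robustness to real RNA-seq noise.

`theoretical_bayes_error` provides the closed-form 2-D optimum
Φ(−½·√(dᵀΣ⁻¹d)) used as the reference for the achievable error.

## Report metrics and rounding

Full-precision metrics follow the closed forms (precision of an empty
predicted column is defined as 0; a class without true samples is an error;
weighted = support-weighted, which for two classes makes weighted recall equal
accuracy). The printed 3-decimal table uses sequential rounding, the way such
report tables are conventionally produced: precision and recall are rounded
first, each F1 is the harmonic mean of the *rounded* precision and recall
(rounded again), and the weighted row is the rounded support-weighted mean of
the rounded per-class values. This differs from rounding the exact values by
one unit in the last place in some cells; JSON reports keep full precision
alongside the rounded table.

The ROC staircase groups tied scores (trapezoidal AUC equals
P(score⁺ > score⁻) + ½ P(score⁺ = score⁻), asserted against a brute-force
pairwise oracle in tests). The heatmap order runs k-means (10 restarts,
seeded) on the 1-D discrete projections, clusters sorted by ascending
centroid, samples within a cluster by original index; for binary predictions
and k = 2 this reduces to grouping by predicted class, which is also asserted.
If k exceeds the number of distinct projection values the clustering collapses
to distinct-value grouping.

## Numerical and I/O conventions

* Labels are canonicalized so the lexicographically smaller original label is
  class 0 (for the simulator: negative → 0, positive → 1).
* Train/test split: per-class test count = round(class count × test fraction).
* Numeric text output uses shortest round-tripping float representation, so
  write → read is bit-identical.
* Orientation of input tables must be stated (default variables-as-rows);
  auto-detection is refused as error-prone. Missing values are rejected, not
  imputed.
* All importance errors are exact multiples of 1/|OOB| and the accumulated
  importance is the exact mean of the per-round differences.

## Problem sizes used in the shipped checks

The test suite and the results script regenerate the study at its native
size: 250+250 samples, 40 variables, r = 500 rounds. Ensemble F1 values are
averaged over three independent dataset draws to damp the draw-to-draw
variance of a 250-sample test half; the importance selection rate uses 100
draws (tests) or 20 draws (results script); the closed-form error comparison
uses a 5 000+5 000-sample simulation so the binomial noise at n_test = 5 000
resolves a sub-percent error rate.

## Known limitations

* RF's reproduced pair F1 averages a few points below an LDA-quality result
  and varies by ±0.03 across dataset draws; with only 175-sample in-bag fits
  and axis-aligned splits against a diagonal decision boundary, its error is
  sensitive to forest hyperparameters, which are configurable but cannot be
  pinned down for external comparisons.
* kNN neighbor searches and SVM fits are O(n²)-ish per round; the
  implementation batches permutation scoring (one predict call per chunk of
  variables, identical results to per-variable scoring) but is not otherwise
  optimized for very wide matrices — expect r × p predict work.
* Sample-order invariance is guaranteed for LDA/SVM and (given deterministic
  neighbor tie-breaks) kNN, but not claimed for RF under reordering with the
  same seed.
* No normalization, batch correction or missing-data handling is provided;
  inputs are taken as-is.
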