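# Methods

## Problem and model

Given a set of drugs with known SMILES structures and a list of validated
interacting pairs, the task is to predict whether an arbitrary unordered drug
pair interacts. The package deliberately uses *only* structural information:
each drug `d` is encoded as a 1024-bit Morgan circular fingerprint of radius 2
(the ECFP4 convention), `F(d) = (f_1, …, f_1024)`, `f_i ∈ {0, 1}`. No targets,
side effects, or network context are required, which is what makes the method
applicable to any drug with a parseable structure.

A candidate interaction is the unordered pair `{d1, d2}`. Because
`{d1, d2} = {d2, d1}`, concatenating the two fingerprints would force an
arbitrary ordering into the feature vector; instead the two vectors are fused
componentwise by symmetric operators:

- addition: `V_A,i = f_i(d1) + f_i(d2)` (values 0/1/2)
- subtraction: `V_S,i = |f_i(d1) − f_i(d2)|` (values 0/1)
- Hadamard: `V_H,i = f_i(d1) · f_i(d2)` (values 0/1)

Any non-empty subset of the three operators may be used (seven combinations:
A, S, H, AS, AH, SH, ASH); chosen blocks are concatenated in the fixed order
addition → subtraction → hadamard so column meanings are stable across runs.
The order is immaterial to tree models; fixing it is purely for
reproducibility. Values stay as small integers; no scaling is applied.
Note the algebraic identity `V_A − V_S = 2·V_H`, which the tests use as a
cross-check: the three blocks are pairwise informative but jointly redundant
by one block.

The classifier is a random forest with 100 trees and otherwise default
hyperparameters (scikit-learn), seeded for reproducibility. A polynomial-kernel
SVM with `C = 1` (backend-default degree 3, recorded in model metadata) is
provided as a comparison backend; its probabilities come from the backend's
standard calibration and feed only the threshold sweep. Scalar metrics
threshold predicted probabilities at 0.5.

## Dataset construction

Positive samples are the validated pairs, canonicalised (lexicographic order
within the pair) and deduplicated; self-pairs and pairs referencing unknown or
unparseable drugs are dropped with logged counts, never fatally. Negative
samples are drawn uniformly at random among the drugs occurring in positives:
pick two distinct drugs, keep the pair if it is not a known positive, repeat
until there are as many distinct negatives as positives. Sampling is seeded,
drawn once for the whole dataset (not per fold), and guarded by an exact
capacity pre-check `C(n_drugs, 2) − |positives| ≥ |positives|`; when the
candidate space is more than half-consumed the sampler switches from rejection
sampling to exhaustive enumeration, so termination never depends on luck. The
drug universe of a dataset is always derived from the pairs actually present,
never a fixed count.

## Evaluation protocols

Two ten-fold cross-validation protocols (`K = 10` default):

**Entire CV** partitions the pooled samples into K near-equal random parts;
each sample is tested exactly once. No label stratification is applied — the
dataset is balanced by construction, so a random split is near-balanced in
expectation.

**Composition CV** partitions the *drugs* into K near-equal random parts.
Holding out drug part k routes every sample by how many of its two drugs are
held out: 0 → training set, 1 → ODIT (One Drug In Train) test set, 2 → NDIT
(No Drug In Train) test set. ODIT and NDIT are the one- and two-cold-start
regimes. Negative samples are routed by the same rule as positives — the only
leakage-free choice. Per fold the three strata are disjoint and exhaustive,
and no held-out drug ever occurs in a training pair; both properties are
asserted by brute force in the tests.

Fold predictions are pooled by default — all test-set probabilities
concatenated, then one confusion matrix and one ROC/PR curve per classifier —
matching the single-curve-per-classifier presentation convention. Per-fold
scalar metrics and their mean are also computed (`CVResult.per_fold_frame`),
because the two aggregations differ slightly: F1 of pooled counts is the
harmonic mean of pooled precision/recall, whereas a mean of per-fold F1 values
is not. The package's own reports always state pooled values.

## Metrics

From the confusion counts: accuracy, precision, recall,
`F1 = 2PR/(P+R) = 2TP/(2TP+FN+FP)`, and MCC. Zero-division policy: precision,
recall and F1 return 0 when their denominator is 0; MCC returns 0 when any
factor under its root is 0 — degenerate predictions yield a defined report
rather than NaN.

ROC and PR curves sweep thresholds over the distinct predicted scores plus a
`+inf` sentinel, with tied scores collapsed to one operating point. Areas are
trapezoidal. With this construction the trapezoidal AUROC equals the
Mann–Whitney pairwise-concordance probability (ties counted ½) exactly; the
tests assert agreement to 1e−12 against an exhaustive pairwise oracle and
against scikit-learn's `roc_auc_score`. The PR curve is anchored at recall 0
with the first attainable precision rather than an extrapolated 1.0 (toolkits
differ here; the choice is recorded in report metadata). AUPR is likewise
trapezoidal, which differs by design from scikit-learn's step-wise average
precision.

## Synthetic worlds

`fpddi.synthetic` generates fully self-contained inputs so the entire
pipeline, including the file readers, runs with no external data. Molecules
are seeded random concatenations of closed SMILES fragments (alkyl chains,
aromatic and aliphatic rings, halogens, common functional groups); every
fragment parses on its own and closes its own rings, so every concatenation
parses, and distinctness is enforced by canonical-form deduplication.

Interaction labels follow a latent fingerprint-dependent rule: a pair is
positive when the two molecules share more fingerprint bits than a threshold,
then each label is flipped with a small noise probability. Defaults, chosen
once: the threshold is the 70th percentile of the pair shared-bit-count
distribution, giving roughly 30% positive pairs — dense enough to learn from,
sparse enough that the negative sampler's capacity bound holds comfortably —
and the flip rate is 5%. An explicit threshold yielding under 10% or over 90%
positives triggers a warning and falls back to the percentile choice. All
randomness in a world flows from one seed.

Because the rule is a function of fingerprint overlap, the signal is by
construction recoverable from the fused features (the shared-bit count is
`Σ V_H,i`, and `V_H` is implied by `V_A`/`V_S` through the identity above), so
a passing learnability test shows the pipeline machinery works — it does not
show anything about real pharmacology. What the synthetic world does *not*
emulate: the heavy-tailed degree distribution of real interaction networks,
structural correlation between interaction partners beyond substructure
sharing, and class imbalance in the wild. Cold-start degradation on synthetic
worlds (NDIT ≤ ODIT ≤ entire-CV AUROC, checked across five world seeds at
noise 0) is therefore a qualitative, not quantitative, reproduction of the
behaviour expected on curated interaction data.

Default problem sizes: worlds of 60 drugs (≈1,770 candidate pairs, ≈500
positives) for end-to-end evaluations and 20–25 drugs for unit-level checks.
These sizes give stable pooled AUROCs under tenfold CV while keeping a full
suite run in about a minute.

## Numerical and design notes

- Pair canonical order is lexicographic on drug id; fingerprints are dense
  uint8 vectors; fused features are small integers (uint8).
- Drug-shuffling, sample-shuffling, negative-sampling and model seeds are
  independent and all recorded in run provenance files.
- Entire-CV fold sizes differ by at most one; drug parts in composition CV
  likewise.
- Composition folds with an empty ODIT or NDIT stratum simply contribute
  nothing to that stratum's pool; an entirely empty or single-class stratum is
  an error surfaced to the caller, not silently skipped.
- Cross-toolkit-version bit identity of fingerprints is out of contract: bit
  positions depend on the hashing of the installed toolkit version. The
  ethanol regression fixture pins the in-repo toolkit's behaviour only.
- Known limitations: no hard-negative mining (uniform sampling only may
  overstate separability), no per-fold negative resampling, no confidence
  intervals on AUROC, and the SVM backend's probability calibration follows
  the backend default rather than a tuned calibrator.
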