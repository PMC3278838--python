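# Methods

## Problem and model

`hexafib` classifies six-residue peptide windows (hexmers) as
amyloidogenic or not. The architecture has four stages: feature encoding,
two-stage feature optimization, a small neural-network classifier, and
confusion/ROC evaluation. Everything downstream of the raw sequence is
deterministic given a seed.

### Feature encoding

A hexmer is encoded by up to three blocks, concatenated in the fixed
order BPC, AC, ATOM:

* **BPC block.** One feature per selected amino-acid property: the
  arithmetic mean of the raw per-residue index values over the six
  positions. The aggregation rule (mean) is a design choice: any
  order-free summary would do, and order sensitivity is deliberately
  delegated to the AC block.
* **AC block.** Moreau-Broto autocorrelation
  `F_v = (1/(w−v)) Σ_{i≤w−v} p_i p_{i+v}` for lags v = 1…5 within the
  w = 6 window. Indices are standardized to mean 0, sd 1 over the
  20 residues before use, following the PROFEAT convention for
  autocorrelation descriptors; both the standardization and the 1/(w−v)
  lag normalization are switchable (`standardize_ac`, `lag_normalized`)
  since unnormalized variants circulate in the literature.
* **ATOM block.** Summed C/H/N/O/S counts using dehydrated in-chain
  residue formulas (free amino acid minus one water). No terminal water
  is added: a window is a fragment of a chain, not a free peptide. This
  block is permutation-invariant by construction, which the tests assert
  exhaustively, in contrast to the AC block whose whole point is to break
  that invariance.

Windows are cut at every offset (L − 5 windows for a clean length-L
sequence); windows containing non-standard residues (B, Z, X, U, O, J)
are skipped rather than imputed. Window origins are 0-based; positive
region annotations are half-open [start, end) intervals and a window is
positive iff fully contained in one — BED-like semantics, chosen because
they are unambiguous.

Min-max normalization maps each feature affinely from its training-set
[min, max] to [0, 1] (target range configurable). Parameters are fitted
on the training partition only and reused unchanged on validation and
test data, so out-of-range values may legitimately leave [0, 1];
degenerate (constant) features map to the range minimum. This prevents
information leaking from evaluation partitions into the scaling.

### Feature optimization

**Stage 1 (embedded pre-selection).** A linear-kernel SVM is fitted once
on all candidate per-property mean features; properties are ranked by
absolute weight and the top k kept (k = 186 canonically). Ties break by
column order so runs are reproducible.

**Stage 2 (memetic algorithm).** Individuals are property subsets of
fixed cardinality (default 40) carrying their own RBF-SVM
hyperparameters. Fitness is mean stratified 5-fold CV accuracy with a
seeded, per-run-fixed fold assignment. Per generation:

1. evaluate all unevaluated individuals;
2. keep the best half (stable tie-break by position);
3. recombine: a shuffled multiset pool of the parents' properties is
   drawn one property at a time, keeping first occurrences, until the
   offspring holds the full cardinality — properties common to many fit
   parents are inherited with higher probability;
4. mutate each offspring by swapping `N_M` members for uniformly chosen
   non-members, where `N_M = max(1, round(s·m·e^{−λ n_G/N_G}))` with
   λ = ln(s·m): the schedule starts at round(s·m) (8 for s = 40, m = 0.2)
   and decays exponentially to 1 at the final generation. (C, γ) are
   perturbed log-normally (σ = 0.1) so kernel parameters co-evolve;
5. local search: with F-scores
   `((x̄₊−x̄)² + (x̄₋−x̄)²) / (s²₊ + s²₋)` ranked over the pool, up to
   `length` (default 8) Add operations pull the best excluded features in
   and up to `length` Delete operations push the worst selected features
   out; the merged candidate is trimmed/filled by rank back to the fixed
   cardinality and replaces the offspring only on strictly better CV
   fitness;
6. replace the worst half with the improved offspring.

The best individual ever seen is returned (elitist; the recorded
best-fitness trace is non-decreasing by construction). Early stopping
after 15 generations without improvement by default, against a 100
generation budget. A zero within-class-variance feature with separated
means receives an infinite F-score (it is maximally discriminative); 0/0
returns 0.

The SVM hyperparameter handling — (C, γ) as genes, log-uniform in
[2⁻⁵, 2¹⁵] × [2⁻¹⁵, 2³], log-normal mutation — is this package's reading
of "evolutionary SVM" parameter determination; a grid search per subset
would multiply cost without changing the selection dynamics being tested.

### Prediction models

PM1–PM5 share one classifier and differ in feature blocks: 40 BPC / 5
ATOM / 65 BPC+AC / 45 BPC+ATOM / 70 all. The classifier is a one-hidden-
layer network (23 sigmoid hidden units, one sigmoid output, 1 = positive)
trained by full-batch gradient descent on the binary cross-entropy with a
geometrically decaying learning rate (0.1, ×0.9995/epoch, ≤ 2000 epochs),
weights initialized uniformly in [−0.5, 0.5] from the seed. Early
stopping keeps the weights of the best validation-loss epoch (patience
50). The implementation is plain numpy with explicit, JSON-serializable
weights. Data are split 60/20/20 train/validation/test, stratified,
seeded. The decision threshold is 0.5 with ties called positive, matching
the target coding.

### Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), BACC = (Sn+Sp)/2,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with the standard
0 convention when any marginal is empty; an empty class makes the
affected rate NaN rather than silently 0. ROC curves sweep the distinct
score values (ties collapsed), so the trapezoidal AUC equals the
Mann-Whitney concordance with ties counted ½ — asserted against an O(n²)
oracle in the tests. ROC space is split at (0.5, 0.5) into quadrants;
boundary points (a rate exactly 0.5) fall into the "lower" quadrant,
so quadrant II strictly requires Sn > 0.5 and Sp > 0.5.

## Synthetic data: what it emulates and what it does not

`generate_hexmers` draws residues i.i.d. per position from class-specific
frequency profiles: positives enriched in β-prone residues (V, I, F, Y,
L, T), negatives in aggregation-breakers (P, G, D, E, K, R) — an
enrichment pattern from the amyloid literature, fully configurable. The
`effect` parameter linearly interpolates both profiles toward uniform;
at effect 1 the supports are disjoint, at effect 0 the classes are
generatively identical. Default sizes (1232 positive / 1280 negative)
mirror the scale of curated hexmer corpora so runtime profiles are
comparable.

This captures compositional class structure only. Real amyloid data have
positional dependencies within windows, overlapping windows from shared
parent proteins (non-i.i.d. samples), label noise from assay
disagreement, and class signal that is far weaker and partly structural.
Passing tests therefore demonstrate that the pipeline machinery is
correct and can extract compositional signal when present — not that it
achieves any particular accuracy on experimental data.

`generate_planted_matrix` skips sequence space entirely: Gaussian
features with a ±shift/2 class separation in a planted column subset,
the direct test harness for the selection stage. `generate_indices`
yields standard-normal per-residue property tables (rejecting sd < 0.3)
standing in for property databases.

## Experiment sizes and numerical choices

* **Selection-recovery experiment** (tests and reproducibility script):
  pool 60, 10 planted columns, subset size 10, shift 1.0, noise sd 1.0,
  250 samples/class, population 10, 30 generations, 5 seeds. The shift
  gives per-feature d′ = 1 and full-subset d′ ≈ √10, i.e. a CV accuracy
  ceiling near 0.94: deliberately below 1.0, because once fitness
  saturates, strict-improvement acceptance stops rewarding extra planted
  features and recovery stalls. Success is ≥ 8/10 planted features
  recovered, compared against a 10,000-draw random-subset null
  (expected overlap under the null: 10·10/60 ≈ 1.7).
* **End-to-end experiment**: 1232/1280 hexmers, 60 synthetic indices,
  embedded pre-selection to 40 BPC properties (top 5 feeding the AC
  block), PM3-style training. At effect 1 the classes are disjoint in
  composition, so held-out Sn/Sp/AUC near 1.0 is the correct outcome and
  values ≥ 0.9 are asserted; at effect 0 the held-out AUC must sit in
  [0.45, 0.55].
* Floating-point contracts: AAindex round-trip to 1e-9 (writer emits 12
  significant digits); standardization to |mean| < 1e-12, |sd−1| < 1e-12;
  min-max inverse round-trip to 1e-9; descriptor hand-values to 1e-12.
* Population (ddof = 0) standard deviation for index standardization
  over the fixed 20-residue alphabet; unbiased (ddof = 1) variances in
  the F-score, which is the form whose brute-force oracle the tests pin.

## Known limitations

* The BPC aggregation (mean) and the exact exponential mutation-schedule
  and local-search merge forms are documented conventions among several
  defensible readings; all are behind switches or injectable functions.
* The ANN is full-batch gradient descent, adequate at these problem
  sizes; no momentum/conjugate-gradient acceleration is provided.
* Feature selection cost is dominated by SVM CV fits (O(pop ·
  generations) fits per run); wall-clock grows quickly beyond a few
  thousand samples.
* No handling of non-standard residues beyond skipping their windows;
  no window sizes other than those with lag < window are meaningfully
  supported (6 is canonical throughout).
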