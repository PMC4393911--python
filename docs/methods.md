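# Methods

This note records the models, conventions and design choices behind the
package, in the order a user meets them: morphometry, classifiers, the
BMSF selector, the SVM-RFE baseline, the evaluation protocol, the
one-vs-rest hierarchy, and the synthetic-data generator used by the test
suite and the acceptance script.

## Morphometry (`bmsf.morphometry`)

An SWC reconstruction is a rooted tree of nodes `(id, type, x, y, z,
radius, parent)`; every non-root node defines a compartment from its
parent's position to its own.  Coordinates and radii are taken as
micrometres (the NeuroMorpho convention); no unit conversion is applied.

Conventions, chosen where the metric catalog leaves room:

- **Compartment geometry.** Compartments are cylinders carrying the
  *child* node's radius (not frusta).  This is the dominant convention
  and keeps length/surface/volume closed-form: ℓ, 2πrℓ, πr²ℓ.
- **Soma and stems.** Soma nodes are `type == 1` (the root stands in for
  somaless files).  A stem is a neurite node whose parent is a soma
  node; the stem count `N_s` is the "number of trees".  Soma surface
  `SS` is the sphere 4πr² for single-node somas and the sum of
  soma-compartment lateral surfaces otherwise, since SWC soma encodings
  vary across labs.
- **Extents.** `NH`/`NW`/`ND` are the central-95% ranges (97.5th minus
  2.5th percentile) of node projections on the first/second/third PCA
  axes of the node cloud.
- **Branches.** A branch is a maximal compartment run between critical
  points (soma, bifurcation, tip).  Contraction `Co` is the
  Euclidean-to-path-length ratio per branch, averaged; `Bpl` is the mean
  per-branch path length (the catalog's phrasing is ambiguous between a
  per-branch and whole-cell reading; the mean is used).  Taper uses the
  diameter at the branch's proximal critical point (for stems, the first
  neurite node); `Ta2 = (d_init − d_final)/d_init` keeps its sign when a
  branch widens distally.
- **Bifurcations.**  Daughter diameters are those of the first
  compartment after the split.  At multifurcations the two
  largest-diameter daughters carry the diameter/angle statistics;
  partition asymmetry `Pa = |(n1 − n2)/(n1 + n2 − 2)|` counts tips in
  all subtrees (largest daughter vs the rest pooled) and is defined as 0
  at a symmetric terminal bifurcation (n1 = n2 = 1, where the formula is
  0/0).  The diameter-conservation exponent (`Pk`, and `RP`, which the
  catalog defines nearly identically — both are reported as the same
  fitted statistic) is the n ∈ [0, 5] minimising |d1ⁿ + d2ⁿ − dpⁿ| on a
  0.01 grid; `Pc`/`Pk2` fix the exponent at 1.5/2.  Angles are degrees
  in [0, 180] via arccos of normalized dot products clipped to [−1, 1];
  torque angles (between successive bifurcation planes) are folded to
  [0, 90] because plane orientation is sign-ambiguous.
- **Undefined metrics.**  A tree without bifurcations (or without
  terminal bifurcations) reports those metrics as 0 with a
  "not defined" flag on the profile rather than NaN, so batch tables
  stay numeric.

Out of the 43-name catalog, five (`Ty`, `Td`, `TS`, `He`, `FD`) are not
computed from SWC — they are either trivially categorical or require
helix/fractal machinery out of scope here.  Synthetic tables still carry
all 43 column names so selection code handles the full width.

## Classifiers (`bmsf.classifiers`)

The reference classifier is an RBF-kernel SVC with `C = 2^c`,
`gamma = 2^g` walked on the inclusive base-2 grid c ∈ [−5, 15],
g ∈ [3, −15], step 2 (the conventional libsvm coarse grid; the exponent
*ranges* are part of the protocol, the step is a package choice).  Grid
selection maximises stratified k-fold accuracy pooled over folds
(micro-average, well-defined under imbalance); ties break toward smaller
C, then smaller gamma, favouring smoother models.  CV accuracy of a
feature subset is reported as the best grid accuracy — the classical
libsvm tuning protocol.  Rows are put in canonical index order before
fold assignment so results are invariant to row permutation; a class
rarer than the fold count reduces the fold count (floor 2) with a logged
warning.  All model inputs are z-scored inside the pipeline, with
statistics learned on training folds only.

BPNN is adapted by a single-hidden-layer `MLPClassifier` with a fixed
seed, Naive Bayes by `GaussianNB`; exact parity with any external
implementation is a non-goal — they exist to show selected subsets
transfer across classifier families.

## BMSF (`bmsf.selection`)

See the README for the algorithm.  Choices the outline leaves open:

- **Surrogate.** Support vector regression with RBF kernel, matching the
  method's SVM framing.  `epsilon = 0.01` because the response
  (accuracy) lives in a narrow band near 1 — the libsvm default 0.1
  would swallow the signal.  C and gamma are tuned by 5-fold CV on the k
  meta-samples over the same exponent grid.  The surrogate is pluggable:
  anything with `predict` works, which the tests exploit by injecting
  analytic surrogates.
- **Forcing semantics.** Column j is forced to all-ones (Z₁) and
  all-zeros (Z₀); the margin is mean(Z₁) − mean(Z₀).
- **Per-round hyperparameters.** The classifier's (C, gamma) are
  grid-searched once per round on the full surviving feature set and
  frozen for all k row evaluations — a deliberate approximation; a
  nested grid per row (k × 110 grids per round) would dominate the
  runtime for no obvious statistical benefit.
- **Fixed folds within a round.** The CV fold assignment is computed
  once per round and reused for every row, so row accuracies differ only
  through feature content.
- **Degenerate rows and rounds.** A row with no active features scores
  at the majority-class proportion (keeping columns balanced); a
  spread-less accuracy vector yields a flagged constant surrogate, which
  stops the elimination loop.
- **Elimination rule.** Keep margin > 0; a margin of exactly 0 carries
  no evidence of contribution and is dropped.  If a round would drop
  everything, the single best-margin feature is retained.  Rounds use
  fresh deterministically derived seeds (design matrix regenerated each
  round, which decorrelates rounds) until a round deletes nothing,
  `min_features` (default 1) is reached, or `max_rounds` (default 20,
  a safeguard never hit in practice) runs out.
- **Stochasticity.** The margin of a feature whose true contribution is
  nil has the sign of a CV-accuracy fluctuation, so single noise
  features occasionally survive — a property of the margin>0 rule, not
  of the implementation.  Different seeds can legitimately return
  different (equally predictive) subsets.

## SVM-RFE (`bmsf.rfe`)

Guyon's original formulation: linear-kernel SVM (the published protocol
does not name its RFE kernel; linear is the one whose weights the
criterion is defined on), per-feature criterion = sum of squared weights
across one-vs-one machines, one feature eliminated per step (m is small),
retraining after each removal, z-scoring inside because weight
magnitudes are scale-sensitive.  The subset size is a required user
parameter — the method itself has no stopping rule.

## Evaluation (`bmsf.evaluation`)

Each replication splits every class 2:1 into train/test with independent
per-class shuffles derived from `(seed, replication)`; selection runs on
training rows only (asserted by a spy-selector test).  Per-class train
counts use an exact-global-2:1 **largest-remainder** allocation computed
in rational arithmetic: each class contributes ⌊n_c·2/3⌋ and the
remaining train slots (up to round(N·2/3)) go to the largest fractional
remainders, ties broken by class name.  Pure per-class rounding cannot
reproduce the published corpus split — two classes with identical
fractional parts (391 and 142 total) are printed rounded in opposite
directions — whereas this allocation reproduces every published count,
including the 3908/1954 totals.  A singleton class goes entirely to
train with a warning.

Binary metrics follow the standard formulas; MCC is defined as 0 when a
denominator factor vanishes, recall as 0 when the positive class is
absent.  Summaries are mean ± sample SD (n−1) over replications.

## Hierarchy (`bmsf.hierarchy`)

Classes are ordered by descending sample count (ties by name); level i
poses "i-th class vs all smaller classes", giving c−1 binary problems
whose last level opposes the two rarest classes.  Splits are stratified
on the original class labels (each type keeps its own 2:1 ratio) and
then binarized.  Levels are trained and evaluated independently — no
routing of test samples through the cascade.  Each level records its
accuracy/MCC/recall and the private feature subset per replication.

## Synthetic data (`bmsf.synthetic`)

`generate_feature_table` draws class-conditional Gaussian features:
informative features get per-class mean shifts (default: 3-SD one-hot
marks, each informative feature marking one non-baseline class, so each
one is strictly necessary); redundant features are 0.8·source + N(0,
0.5²); everything else is standard normal.  Class counts use
largest-remainder apportionment; the default proportions mirror the
7-type corpus imbalance (81.1% down to 0.3%) at n = 586 (a tenth of the
corpus, the smallest size at which the rarest class is non-empty).  What
this emulates: imbalance, redundancy, and noise.  What it does not:
real morphometric dependence structure, heavy tails, measurement error
correlated across metrics — so passing tests show the machinery and the
selector's statistical behavior under the planted model, not performance
on real reconstructions.

`generate_toy_swc` grows rooted trees by recursive branching (branch
probability, Gaussian segment lengths, per-branch radius taper,
direction jitter) and emits valid SWC; with branch probability 1 and
depth d it produces exact full binary trees, which gives the topology
metrics closed-form oracles.

### Reference study sizes

Chosen once as the package's benchmark conditions (`bmsf.benchmarks`):

- **Planted recovery:** n = 300, m = 40 (5 informative with 3-SD
  one-hot shifts over six classes at proportions 0.30/0.20/0.15/0.13/
  0.12/0.10, 5 redundant, 30 noise), BMSF at k = 50, ten-fold CV, five
  seeds.  Six moderately imbalanced classes are used instead of the
  7-type corpus mix because at n = 300 the corpus proportions leave the
  rarest class with a single sample, which cannot be stratified at all.
- **Hierarchy:** n = 350, seven classes (0.30/0.18/0.14/0.12/0.10/
  0.09/0.07), every class carrying its own 4-SD one-hot signature (a
  one-vs-rest level is only well-posed when its positive class has a
  signature of its own — a purely "unmarked" class is recognisable only
  by the absence of every other class's marks, which a per-level
  parsimonious selector rightly refuses to keep), one replication per
  level, BMSF per level at k = 50.  n = 350 keeps ≥ 11 test samples in
  the smallest positive class, so one misclassified neuron cannot drag
  a level's recall below 0.9 on its own.

## Known limitations

- Morphometric values are not bit-compatible with any external metric
  software; conventions above are self-consistent and unit-tested
  against hand-computed trees instead.
- The SVC grid accuracy used for subset scoring is the tuning optimum,
  an optimistic estimate of generalization; it is used consistently for
  all subsets, so comparisons remain fair.
- `Pk`/`RP` are reported as the same fitted-exponent statistic (the
  catalog's two definitions are not distinguishable from their
  descriptions).
- The hierarchy evaluates each level in isolation; it is not a deployed
  cascade classifier.
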