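# Methods

This note documents the models implemented in `aisclf`, the choices made
where the underlying algorithm descriptions are qualitative, and what the
synthetic cohort does and does not establish.

## Problem setting

The package targets binary recurrence-risk classification on small,
heavily imbalanced clinical cohorts: on the order of 600 patient records
with ~6% positives (recurrent cases) and ~20 mixed-type predictors
(continuous measurements, binary exposures, ordinal stage/grade codes,
nominal clinical codes). Two difficulties dominate: (i) the minority
class is nearly invisible to accuracy-driven learners, and (ii) several
of the methods compared are distance-based clusterers, which need all
variables on a common scale.

All distance-based computation therefore happens on the min–max
normalized unit cube `[0, 1]^d`. Nominal codes are stored as non-negative
integers and enter distances as ordinary reals (the same convention the
clustering methods implicitly use on coded registry variables); this is a
deliberate simplification, and the data model records column kinds so
Relief can apply the categorically correct 0/1 mismatch diff.

## The immune classifier

Training samples are *antigens*. Per class `c`:

1. **Seeding.** k-means (`n_best = 5` centroids, k-means++ init) on class
   `c`'s antigens produces the initial *antibody* vectors. Classes with
   fewer distinct points than `n_best` get one antibody per distinct
   point.
2. **Affinity.** `aff(a, x) = 1 / (1 + ||a − x||_2)`, bounded in (0, 1].
   An antibody's fitness is its mean affinity over its class's antigens.
   The functional form is our reconstruction: it is bounded, symmetric
   and strictly decreasing in distance, which makes the clone-count and
   mutation rules below well-posed.
3. **Clonal expansion.** Each antibody produces
   `max(1, round(clonal_rate × aff))` mutated clones per round
   (`clonal_rate = 10`; rounding half away from zero): better recognizers
   clone more.
4. **Mutation.** Each clone perturbs every coordinate by
   `Normal(0, σ²)`, `σ = mutation_scale × (1 − aff)` with
   `mutation_scale = 0.2`, clipped to the unit cube: better recognizers
   mutate less. A mutant replaces its parent slot only on strict affinity
   improvement, so per-slot affinity is monotone non-decreasing — with
   `mutation_scale = 0` the procedure reduces exactly to the per-class
   k-means seeds.
5. **Convergence.** Rounds stop when the largest memory-cell
   displacement falls below `convergence_tol = 1e-4` (or after
   `max_iterations = 50`). The surviving antibodies are archived as
   *memory cells* (MC).

**Hormone field.** Each class's concentration at a query `x` is the sum
of Gaussian kernels centred on that class's memory cells with bandwidth
`radius_of_influence = 0.1` (on the unit cube); concentrations are
normalized across classes into a probability vector. A continuous kernel
mixture was chosen over a discretized grid because a grid is hopeless in
11–20 dimensions. Where all kernels underflow to zero the field is
defined as uniform.

**Decision rule.** Decision A is the class of the nearest memory cell;
decision B the hormone argmax. Agreement decides immediately. A conflict
inside the *burring area* — the top two hormone probabilities within
`burring_epsilon = 0.1` of each other *and* the nearest memory cell
within `burring_radius = 0.1` of the query — is resolved by the nearest
memory cell; any other conflict by the strongest hormone. The returned
score is the hormone probability of the chosen class.

A consequence of this architecture worth stating explicitly: because
every class receives the same number of memory cells regardless of its
sample count, the classifier's decision geometry is *insensitive to
class imbalance*. Bootstrap balancing of the training data therefore
neither helps nor systematically harms it (duplicated minority rows add
no information to the per-class k-means seeding or the affinity means),
in contrast to the four comparison learners, which all gain sensitivity
dramatically from balancing. The benchmark makes this directly
measurable.

## Comparison learners

* **BPNN** — fixed `N-15-2` topology, sigmoid activations, MSE loss
  against one-hot targets (1,0)/(0,1), full-batch gradient descent.
  Defaults: learning rate 0.1, 1,000 epochs, uniform(−0.5, 0.5) init.
  The hidden width and two-unit output coding are part of the method
  definition; the training hyperparameters are ours.
* **RBF-SVM** — soft-margin SVM with labels coded ±1; the dual
  optimization is delegated to sklearn's solver, but the model object
  exposes the support vectors, dual coefficients `α_i d_i` and bias `b`,
  and `decision_svm` recomputes
  `f(x) = Σ_i α_i d_i exp(−γ‖x − x_i‖²) + b` by explicit summation so
  the decision function is verifiable. Defaults `C = 1`, `γ = 1/d`.
* **FCM** — fuzzy c-means, fuzzifier `m = 2` (field standard),
  memberships `u_ij ∝ (1/d_ij²)^{1/(m−1)}` renormalized per row, stop
  when codebooks move less than `tol = 1e-5`. A sample coincident with a
  codebook takes membership 1 there. The full membership history is
  retained so the row-sum invariant is auditable at every iteration.
* **AK (ant k-means)** — per iteration every sample is assigned to a
  cluster with probability proportional to its pheromone row `τ_i·`,
  centroids are recomputed from the sampled assignment, pheromone toward
  every centroid is deposited as `1/(1 + distance)` and the whole trail
  evaporates at rate `ρ = 0.1`; the lowest in-group-distance solution
  over `max_iter = 50` iterations is retained (a monotone best-so-far
  trace). With `ρ = 1` the trail has no memory and assignment reduces to
  a pure distance rule. The published description is qualitative; the
  deposit form, the farthest-point centroid initialization (needed so
  the positive feedback has distinct attractors to amplify) and the
  empty-cluster re-seeding (farthest point from its nearest centroid)
  are ours.
* Both clusterers are scored as classifiers via majority-vote cluster →
  class mapping (ties to the smaller class index), which for two
  clusters provably maximizes accuracy over all mappings.

## Bootstrap balancing and evaluation protocol

`bootstrap_balance` appends minority rows resampled uniformly with
replacement until class counts are equal — plain resampling, no
interpolation. By default balancing is applied *inside* each training
fold (`balance_scope: fold`), so duplicated rows never straddle the
train/test boundary; `balance_scope: global` balances the whole table
before splitting, reproducing the historical protocol at the cost of
duplicate leakage across folds.

Evaluation pools confusion counts over held-out folds and computes the
five clinical rates once (micro-averaging); per-fold macro averages are
kept alongside, with undefined values (zero denominators) skipped and
counted rather than coerced. Sensitivity is undefined iff `TP + FN = 0`,
and analogously for each ratio; undefined renders as `NaN` in text
reports. ROC curves come from a full threshold sweep with trapezoidal
AUC, which equals the Mann–Whitney `U/(n₊n₋)` identity (tested).

Default CV is `k = 10` stratified folds; the acceptance script and the
heavier end-to-end tests use `k = 5`, which halves the fit count while
leaving every pooled metric estimated from all 599 held-out predictions.

## Feature selection

**SFS-AIS** is a wrapper: starting from all features, each round refits
and cross-validates the immune classifier with every single remaining
feature left out, removes the feature whose *exclusion* maximizes the
recognition rate (CV accuracy with fold-scoped balancing; ties remove
the larger index), and stops at the target size (default 11). Although
the method family is named "sequential forward selection", the published
procedure eliminates features from the full set ("leave-one-out …
eliminate the selected feature"), so elimination is the default reading;
a genuinely forward-growing variant is available via
`direction="forward"`. Inside the wrapper the classifier runs with
`max_iterations = 15` and 3-fold CV — the subset *ranking* stabilizes
long before full convergence, and the wrapper performs hundreds of fits.

**Relief** visits every sample, finds its nearest hit and nearest miss
(distance = summed per-feature diffs), and scores each feature by
`diff(miss) − diff(hit)`; diff is the absolute difference on the unit
scale for continuous/ordinal features and a 0/1 mismatch indicator for
nominal/binary codes, following the classic algorithm.

**Information gain** is `H(y) − Σ_v p(v) H(y | f = v)` in bits, with
continuous features discretized into 10 equal-frequency bins.

## The synthetic cohort

The generator emulates the statistical skeleton of a gynecologic-
oncology registry cohort that cannot be redistributed: 599 records,
38:561 class imbalance, age ~ Normal(52.73, 11.82²) years, and 19
further mixed-type variables on clinically plausible scales (tumor size
in cm, radiotherapy doses in cGy, binary exposures, ordinal stage/grade,
nominal histology-like codes). Only the age distribution and the class
sizes are published values; all other marginals are invented and
documented in `synthetic_cohort.py`.

The discriminative signal is planted on the analogues of histology
(feature 2, nominal) and chemotherapy (feature 10, binary):
continuous informative features get a class-conditional mean shift of
`effect_size` SDs; coded ones get class-conditional category
distributions at total-variation distance `min(0.3 × effect_size, 0.9)`.
The default `effect_size = 1.5` (TV 0.45) models a strong prognostic
factor — detectable from 38 minority cases (z ≈ 5 for the binary
feature) without being deterministic. Features are sampled
independently; real registry data has correlation structure
(stage–grade, dose–fractions) that the generator deliberately omits, so
passing tests demonstrate *planted-signal recovery under imbalance and
mixed types*, not performance on real clinical data, and the published
per-cohort headline accuracies are not reproducible here.

`generate_blobs` provides isotropic unit-SD Gaussian clusters at a
chosen centroid separation (regular-simplex placement when the dimension
allows, a circle in 2-D) as ground-truthed fixtures for the clusterers.

## Numerical and degenerate-case choices

* Min–max parameters fitted on training data clip unseen samples into
  `[0, 1]`; constant columns map to 0 and invert back to their constant.
* Rows with any unparseable/blank cell are flagged at load and removed
  by an explicit cleaning step (no imputation); cleaning preserves row
  order.
* FCM's membership singularity at `d = 0` (squared distance < 1e-12)
  assigns full membership to the coincident codebook.
* k-fold plans are stratified when labels are available; all plans are
  validated to partition the index set with fold sizes within one.
* All stochastic procedures take explicit integer seeds and are
  bit-reproducible; nothing reads global RNG state.

## Known limitations

* Treating nominal codes as reals in Euclidean distances is crude; a
  one-hot path exists in the data model's typing but the distance-based
  methods run on the coded representation by default.
* The immune classifier's affinity/clone/mutation forms are a
  reconstruction of a qualitative description; other bounded affinity
  functions would satisfy the same invariants.
* Because the immune classifier is per-class balanced by construction,
  bootstrap balancing does not improve it (see above) — the improvement
  claim holds for the four learners whose objectives are dominated by
  the majority class.
* The wrapper's recognition rate on an imbalanced test fold is dominated
  by the majority class; with very weak planted signals the eliminated
  features are close to exchangeable and the selected subset becomes
  seed-dependent.
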