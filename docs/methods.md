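# Methods

## Problem and model

A random-forest classifier cannot split on a nominal predictor directly;
its `k` levels must first be given an order. `leakyforest` implements the
two ordering families used by mainstream forest software and exposes the
one design axis those packages hide: *when* the ordering is fitted relative
to bagging.

Let the training data be `(x_i, y_i), i = 1..n`, with `x_i` a level of a
categorical predictor and `y_i` one of `C` classes.

**Encodings.**

* `integer_alpha` — levels ranked lexicographically by their string label.
  Target-agnostic: the ranks are a function of the level set alone.
* `target_twoclass` (`C = 2`) — levels ranked ascending by the within-level
  proportion of the second class. Threshold search over this order attains
  the exhaustive optimum over all `2^(k−1) − 1` level bipartitions for the
  Gini criterion, which is why it is used at all; the equivalence is
  verified in the test suite against a brute-force bipartition oracle.
* `target_pca` (`C ≥ 2`) — for level `l` with `n_l` observations let `p_l`
  be its class-proportion vector and `w_l = n_l/n`. With
  `p̄ = Σ_l w_l p_l`, form the weighted covariance
  `Σ = Σ_l w_l (p_l − p̄)(p_l − p̄)ᵀ` and rank levels ascending by the
  projection `(p_l − p̄)·v` where `v` is the leading eigenvector of `Σ`
  (symmetric eigendecomposition of the `C × C` matrix, not an SVD of the
  profile matrix).

Encoded values are the consecutive ranks `1..k_observed`, not raw
projection scores: a CART threshold split depends only on the induced
order, so the two are outcome-equivalent and ranks are numerically cleaner.

Determinism rules: all ties (equal proportions, equal projections, a
numerically zero covariance) fall back to lexicographic order on the level
label; `v`'s sign is fixed by making its first nonzero coordinate positive.
Since flipping `v` merely reverses the ranks, and threshold splits are
invariant under order reversal, the sign convention cannot affect any
downstream quantity (tested).

**Encoding timing.** `before_bagging` fits one encoding per variable on the
full training set; all trees share it. For the target-based methods this is
the leaky construction: rows that are out-of-bag for a tree contributed
their *targets* to the level order that tree uses, so the tree has indirect
access to its own test labels. `after_bagging` draws each tree's bootstrap
first and fits that tree's encodings on its in-bag rows only (with
bootstrap multiplicity — a row drawn twice counts twice, which is what a
per-bootstrap refit sees). This is the repair: OOB rows never touch the
encoding they are evaluated under.

**Forest.** Standard CART classification trees under bagging: `n` bootstrap
draws per tree, Gini impurity `G = 1 − Σ_c p_c²`, thresholds at midpoints
between consecutive distinct encoded values, `mtry` candidate variables
drawn uniformly without replacement per node (default `⌈√p⌉`; with one
predictor necessarily 1), nodes split while impure and an accepted split
exists, leaves predict their majority class. A split must strictly decrease
impurity (gain > 1e-12) to be accepted; split ties break to the lower
variable index then the smaller threshold; leaf-count and vote ties break
to the first class in `class_order`. Under the null these tie rules are
independent of the data-generating process and add no bias.

## Error and importance measures

* **OOB error** — per training row, majority vote over the trees for which
  the row is out of bag; rows never OOB (probability `(1 − e^{-1})^{T}`-ish,
  negligible for hundreds of trees) are dropped from the denominator.
* **Test error** — misclassification of forest majority votes on withheld
  rows.
* **MDI** — per variable, the mean over trees of
  `Σ_nodes n_node × ΔG(node)` over nodes splitting on the variable,
  computed on in-bag samples. Node-*sample* weighting (not node fraction)
  is the convention of the reference R implementation (ranger); the score
  therefore grows with sample size, and the per-tree identity
  `Σ_vars MDI / n_inbag = G(root) − Σ_leaves f_leaf G(leaf)` (Gini
  conservation) is enforced in the tests to 1e-9.
* **MDA** — per tree, error on its OOB rows with one variable's column
  permuted (one permutation per tree × variable) minus the unpermuted
  error; averaged over trees; unscaled (no SD normalisation), the ranger
  default.
* **AIR** — each tree grown for AIR carries a permuted *shadow* copy of
  every variable, created by permuting the variable across training rows
  and then applying the bootstrap multiset (so duplicated draws share one
  shadow value, exactly like the real column). Shadows compete as split
  candidates: `mtry` candidates are drawn from the `2p` real-plus-shadow
  pool. `AIR_i` is the MDI-style node-sample-weighted sum at nodes split on
  variable `i` minus the sum at nodes split on its shadow. For an
  uninformative variable real and shadow are exchangeable, making AIR
  exactly unbiased under the null — the property that motivated the measure.
  Two earlier candidate designs (shadow evaluated passively at the nodes
  where the real variable split, with the permutation drawn either within
  the bootstrap multiset or across training rows) were measured and
  rejected: they carry structural null biases of about +0.10 and −0.18
  respectively at n = 50, k = 100, because passive evaluation cannot keep
  the real and shadow columns exchangeable once ancestor splits condition
  the node. Because shadows alter tree growth, AIR is computed on its own
  forest and never mixed into the error/MDA/MDI numbers.
* **Holdout / Independent Holdout** — rows are split into two random
  (unstratified 50/50) folds; a forest is trained on each fold and every
  one of its trees is scored by permutation on the *entire* opposite fold;
  the two forests' per-variable scores are averaged. `Holdout` fits the
  level encodings once on the whole dataset before the fold split — which
  leaks target information across folds for target-based encodings —
  while `IndependentHoldout` fits them within each training fold only and
  pushes the opposite fold through that map. The holdout construction fixes
  its own encoding scope, so it is computed identically whatever
  `encoding_timing` the main forest used.

**Absent levels.** Levels met at prediction/evaluation time but unseen at
encoding-fit time are routine in the after-bagging and per-fold modes (a
bootstrap or fold misses levels). Default policy `majority_child`: the
encoded value is a NaN sentinel that split routing sends to the child with
more in-bag samples (ties route left); sentinels are excluded from
threshold enumeration. `strict` raises instead and exists for debugging.

## Null simulation

`generate_null_dataset` draws `p` predictors i.i.d. uniform over `k` levels
and a response i.i.d. uniform over 3 classes — no relationship by
construction — and splits 80/20 by simple random sampling, unstratified
(tiny test sets can therefore be class-imbalanced, which is visible as
extra spread at n = 20). Under this design the true misclassification rate
is exactly 2/3 and every honest importance has mean 0, so any systematic
departure measured by `run_experiment` is estimator bias. The full design
(config defaults) is n ∈ {20, 50, 100, 150, 200, 400},
k ∈ {1, 5, 10, 35, 50, 100, 150, 200}, p = 1, 99 replicates of 500-tree
forests; `SimulationConfig.reduced()` (n ∈ {50, 100}, k ∈ {5, 50, 200},
20 replicates, 200 trees) gives the same qualitative surface in minutes and
is the scale the packaged tests run at. k = 1 cells are kept: no split is
possible, trees are majority-vote stumps, errors stay defined and every
importance is exactly 0.

What the generator does *not* emulate: class imbalance, dependent or
informative predictors, mixed categorical/numeric designs, missing values.
Passing tests therefore demonstrate the leakage mechanism and its repairs
under exchangeable noise; they do not quantify the bias on structured real
data, where it will additionally interact with genuine signal.

## Randomness and reproducibility

Seeds are hierarchical: master seed → cell (n, k, p, encoding, timing) →
replicate → tree, all derived through `numpy` `SeedSequence` from small
nonnegative integers, so any single replicate or tree can be regenerated in
isolation and a rerun with the same master seed is bit-identical (tested).
Tree growth is depth-first, left child first, so per-node `mtry` draws
consume the stream in a fixed order; when `mtry = p` the draw is skipped
entirely. The run manifest written next to every CSV output records config,
seed and package version — enough to reproduce any output exactly.

## Known limitations

* Classification only; no regression or survival forests, no boosting.
* One-hot and dissimilarity-based (PCO/CA-style) encodings are out of
  scope, as is per-node re-encoding.
* Trees are stored as explicit Python objects for transparency; the
  implementation is sized for the simulation scales above (seconds per
  500-tree forest at n in the hundreds), not for large-scale production
  fitting.
* MDI/AIR are reported on ranger's samples × impurity scale and are not
  comparable across datasets of different size without dividing by the
  bootstrap size.
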