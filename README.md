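# leakyforest

Random-forest classification with *explicit* control over how categorical
predictors are ordinally encoded — target-agnostic vs target-based, fitted
before vs after bagging — plus out-of-bag (OOB) diagnostics and five
variable-importance measures (MDI, MDA, AIR, Holdout, Independent Holdout).

The package is for machine-learning practitioners and biostatisticians who
evaluate forests on OOB samples. Its point is a subtle failure mode: when
levels of a nominal predictor are **target-encoded** (ordered using the
response) and the encoding is fitted on the full training set **before
bagging**, every OOB row's target has already informed the level ordering.
The OOB sample then stops behaving like independent test data: OOB error is
biased downward and OOB-based importances upward, even for a predictor that
carries no signal whatsoever. `leakyforest` makes the leak measurable and
offers the two repairs — encode per bootstrap sample (after bagging), or use
encodings fitted independently per fold (Independent Holdout importance).

## The machinery

* **Encodings.** A predictor with levels `l = 1..k` is mapped to ranks
  `1..k`. Target-agnostic: alphabetical order. Target-based, two classes:
  ascending within-level proportion of the second class (threshold search on
  this order is equivalent to exhaustive search over all `2^(k−1) − 1` level
  bipartitions under Gini). Target-based, multiclass: per level compute the
  class-probability vector `p_l` and weight `w_l = n_l/n`, form the weighted
  covariance `Σ = Σ_l w_l (p_l − p̄)(p_l − p̄)ᵀ` with `p̄ = Σ_l w_l p_l`, and
  order levels by projection onto the leading eigenvector of `Σ`.
* **Forest.** Bagged CART trees, Gini splitting
  (`ΔG = G(parent) − Σ_child (n_child/n) G(child)`), `mtry` candidate
  variables per node, grown to purity; each tree records its bootstrap
  multiset, OOB set, per-node split statistics, and the encodings it used.
* **Measures.** OOB error (majority vote over trees holding a row OOB);
  independent test error; MDI (node-sample-weighted impurity sums); MDA
  (OOB permutation importance); AIR (impurity sum minus the sum earned by a
  competing permuted shadow copy); Holdout and Independent Holdout
  (permutation importance across two cross-validation folds, with encodings
  fitted on the whole data or per fold respectively).
* **Null simulation.** Levels uniform over `k`, three equiprobable classes,
  no predictor-response relationship, 80/20 train/test split — so the true
  misclassification rate is exactly 2/3 and every honest importance is 0.

## Worked example

```sh
python examples/oob_vs_test_error.py
```

```
null data: n=50, k=100 levels, 3 classes; chance error = 0.667

integer, before bagging      OOB error 0.675   test error 0.500
target PCA, before bagging   OOB error 0.250   test error 0.500
target PCA, after bagging    OOB error 0.700   test error 0.500
```

The data are pure noise, so any error estimate should hover near 0.667 (the
small test set here, 10 rows, is noisy — 0.500 is within its Monte-Carlo
spread). With the alphabetical encoding the OOB error does exactly that.
With the target-PCA encoding fitted before bagging the OOB error collapses
to 0.250 — the forest appears to classify noise — while the honest test
error is unchanged. Refitting the same target encoding per bootstrap sample
(after bagging) restores the OOB estimate. The other examples print the rank
maps of the three encodings (`encoding_orderings.py`), the five importance
measures on the same null data (`importance_null.py`), and a reduced sweep
of the bias as a function of the number of levels (`leakage_sweep.py`).

The same functionality is scriptable from a shell:

```sh
leakyforest fit --input data.csv --response y --encoding target_pca --timing after --out run/
leakyforest importance --input data.csv --methods MDA,IndependentHoldout --out run/
leakyforest simulate --out sim/          # reduced grid; --full for 99×500
```

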