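"""Out-of-bag error and five variable-importance measures.

The measures compared here differ in *which* held-out data they consult and
therefore in how exposed they are to target leakage from encodings fitted
before bagging:

* **MDI** (mean decrease in impurity / Gini importance) — in-bag only: the
  mean over trees of the node-sample-weighted Gini decreases at nodes that
  split on the variable.
* **MDA** (mean decrease in accuracy / permutation importance) — per tree,
  the error on the OOB rows with the variable's column permuted minus the
  error on the intact OOB rows, averaged over trees. Unscaled.
* **AIR** (actual impurity reduction) — the variable's MDI-style impurity sum
  minus the impurity sum earned by a per-tree permuted "shadow" copy of the
  variable that competes with it as a split candidate; requires a forest
  grown with ``air_shadows``. Real and shadow copies are exchangeable for an
  uninformative variable, so the difference is unbiased under a null.
* **Holdout** — permutation importance computed on a second cross-validation
  fold: the data is split 50/50, a forest is trained on each fold, each tree
  is evaluated on the entire opposite fold, and the two forests' scores are
  averaged. Encodings are fitted once on the *whole* dataset, so target-based
  encodings leak across folds.
* **Independent Holdout** — the same construction but with encodings fitted
  separately within each fold, so no target information crosses folds. Under
  a null (no predictor-response relationship) this is the only OOB/holdout
  measure that stays unbiased regardless of encoding method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .forest import Forest, ForestParams, fit_forest, predict

__all__ = [
    "ImportanceResult",
    "oob_error",
    "test_error",
    "mdi_importance",
    "mda_importance",
    "air_importance",
    "holdout_importance",
]


@dataclass(frozen=True)
class ImportanceResult:
    """Per-variable scores for one importance method.

    MDI scores are nonnegative by construction; the permutation-based scores
    (MDA, AIR, Holdout, IndependentHoldout) may be negative.
    """

    method: str
    values: Mapping[str, float]
    n_trees_used: int
    rng_seed: int | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.values), name=self.method)

    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))


def _as_rng(rng) -> tuple[np.random.Generator, int | None]:
    if hasattr(rng, "permutation"):  # a Generator, or anything duck-typed like one
        return rng, None
    seed = int(rng)
    return np.random.default_rng(seed), seed


def oob_error(forest: Forest) -> float:
    """Misclassification rate of the OOB majority votes.

    Rows that were in-bag for every tree carry no OOB prediction and are
    excluded from the denominator.
    """
    from .forest import oob_predict

    preds = oob_predict(forest)
    y = forest.train[forest.response].astype(str).to_numpy()
    has = np.array([p is not None for p in preds])
    if not has.any():
        raise ValueError("no training row has an OOB prediction")
    return float(np.mean(preds[has] != y[has]))


def test_error(forest: Forest, test: pd.DataFrame) -> float:
    """Misclassification rate on an independent test set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    preds = predict(forest, test)
    y = test[forest.response].astype(str).to_numpy()
    return float(np.mean(preds != y))


def mdi_importance(forest: Forest) -> ImportanceResult:
    """Gini importance: per variable, the mean over trees of
    Σ (node samples) × impurity_decrease at nodes splitting on it.

    Weighting is by in-bag node sample count (node_fraction × bootstrap
    size), the convention of ranger's impurity importance; the score is
    therefore on a samples-×-impurity scale and grows with sample size.
    """
    p = len(forest.feature_names)
    total = np.zeros(p)
    for tree in forest.trees:
        nb = tree.in_bag.size
        for rec in tree.splits:
            if not rec.is_shadow:
                total[rec.variable_index] += nb * rec.node_fraction * rec.impurity_decrease
    vals = total / len(forest.trees)
    return ImportanceResult(
        method="MDI",
        values=dict(zip(forest.feature_names, vals.tolist())),
        n_trees_used=len(forest.trees),
    )


def mda_importance(forest: Forest, rng) -> ImportanceResult:
    """Permutation importance on the OOB samples (unscaled).

    One permutation is drawn per (tree, variable), over that tree's OOB rows.
    Trees with an empty OOB set are skipped with a warning.
    """
    rng, seed = _as_rng(rng)
    y = forest.y_codes()
    p = len(forest.feature_names)
    total = np.zeros(p)
    used = 0
    for tree in forest.trees:
        if tree.oob.size == 0:
            warnings.warn(f"tree {tree.tree_id} has an empty OOB set; skipped")
            continue
        X = forest.tree_train_matrix(tree)[tree.oob]
        yo = y[tree.oob]
        err0 = float(np.mean(tree.predict_codes(X) != yo))
        for j in range(p):
            perm = rng.permutation(tree.oob.size)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            errp = float(np.mean(tree.predict_codes(Xp) != yo))
            total[j] += errp - err0
        used += 1
    if used == 0:
        raise ValueError("every tree had an empty OOB set")
    vals = total / used
    return ImportanceResult(
        method="MDA",
        values=dict(zip(forest.feature_names, vals.tolist())),
        n_trees_used=used,
        rng_seed=seed,
    )


def air_importance(forest: Forest) -> ImportanceResult:
    """Actual impurity reduction: real minus shadow impurity sums.

    The forest must have been grown with ``air_shadows=True``, in which case
    each tree carries a permuted shadow copy of every variable competing as a
    split candidate. Per variable, AIR is the mean over trees of
    Σ (node samples) × impurity_decrease at nodes split on the real variable
    minus the same sum at nodes split on its shadow copy (node-count
    weighting, as in :func:`mdi_importance`).
    """
    if not forest.params.air_shadows:
        raise ValueError(
            "forest was grown without shadow records; refit with air_shadows=True"
        )
    p = len(forest.feature_names)
    total = np.zeros(p)
    for tree in forest.trees:
        nb = tree.in_bag.size
        for rec in tree.splits:
            sign = -1.0 if rec.is_shadow else 1.0
            total[rec.variable_index] += sign * nb * rec.node_fraction * rec.impurity_decrease
    vals = total / len(forest.trees)
    return ImportanceResult(
        method="AIR",
        values=dict(zip(forest.feature_names, vals.tolist())),
        n_trees_used=len(forest.trees),
    )


def _fold_permutation_importance(
    forest: Forest, eval_frame: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Mean over trees of (permuted − original) error, the whole opposite
    fold serving as every tree's evaluation set."""
    lut = {c: i for i, c in enumerate(forest.class_order)}
    y = np.array([lut.get(v) for v in eval_frame[forest.response].astype(str)], dtype=object)
    # labels unseen by this fold's forest can never be predicted; they count
    # as errors either way and are kept in the denominator
    y = np.array([v if v is not None else -1 for v in y], dtype=np.intp)
    p = len(forest.feature_names)
    total = np.zeros(p)
    shared_X = None
    if forest.shared_encodings is not None:
        shared_X = forest.encode_frame(eval_frame)
    for tree in forest.trees:
        X = shared_X if shared_X is not None else forest.encode_frame(eval_frame, tree=tree)
        err0 = float(np.mean(tree.predict_codes(X) != y))
        for j in range(p):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            total[j] += float(np.mean(tree.predict_codes(Xp) != y)) - err0
    return total / len(forest.trees)


def holdout_importance(
    data: pd.DataFrame,
    params: ForestParams,
    rng,
    *,
    encode_per_fold: bool,
    response: str = "y",
    absent_policy: str = "majority_child",
) -> ImportanceResult:
    """Holdout (``encode_per_fold=False``) or Independent Holdout
    (``encode_per_fold=True``) permutation importance.

    The rows are split into two random halves. With ``encode_per_fold=False``
    the level encodings are fitted once on the entire dataset before the
    split — the construction that leaks target information between folds for
    target-based encodings. With ``encode_per_fold=True`` each fold's forest
    fits encodings on its own fold only and the opposite fold is pushed
    through that map (absent levels per policy). Each fold's forest is scored
    by permutation on the opposite fold and the two scores averaged.
    """
    rng, seed = _as_rng(rng)
    if len(data) < 4:
        raise ValueError("need at least 4 rows to form two folds")
    n = len(data)
    perm = rng.permutation(n)
    folds = (data.iloc[perm[: n // 2]], data.iloc[perm[n // 2:]])
    for f in folds:
        if f[response].nunique() < 2:
            raise ValueError("a holdout fold contains a single response class")

    from .forest import _fit_encodings  # shared fitting helper

    features = tuple(c for c in data.columns if c != response)
    pre = None
    if not encode_per_fold:
        y_all = data[response].astype(str).to_numpy()
        class_order = tuple(sorted(set(y_all.tolist())))
        pre = _fit_encodings(
            params.encoding_method, data, features, y_all,
            class_order, "full_train", absent_policy,
        )

    scores = []
    trees_used = 0
    for i, (train_fold, eval_fold) in enumerate([(0, 1), (1, 0)]):
        fold_seed = int(rng.integers(2**31))
        fold_params = replace(params, seed=fold_seed, air_shadows=False)
        if pre is not None:
            fold_enc = pre
        else:
            yf = folds[train_fold][response].astype(str).to_numpy()
            fold_enc = _fit_encodings(
                params.encoding_method, folds[train_fold], features,
                yf, tuple(sorted(set(yf.tolist()))), f"fold:{i}", absent_policy,
            )
        forest = fit_forest(
            folds[train_fold], fold_params, response=response,
            absent_policy=absent_policy, encodings=fold_enc,
        )
        scores.append(_fold_permutation_importance(forest, folds[eval_fold], rng))
        trees_used += len(forest.trees)
    vals = np.mean(scores, axis=0)
    return ImportanceResult(
        method="IndependentHoldout" if encode_per_fold else "Holdout",
        values=dict(zip(features, vals.tolist())),
        n_trees_used=trees_used,
        rng_seed=seed,
    )
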