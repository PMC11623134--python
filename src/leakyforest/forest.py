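"""Bagged CART classification trees over ordinally encoded categorical data.

The forest here is deliberately transparent rather than fast: every tree
records its bootstrap multiset (``in_bag``), the complementary out-of-bag
(OOB) index set, per-node split statistics (Gini impurity decrease and node
fraction), and — crucially — *which* level encodings it used and where they
were fitted. That bookkeeping is what allows the out-of-bag error and the
permutation/impurity importance measures in :mod:`leakyforest.importance`
to be computed exactly, and allows the two encoding timings to be compared:

* ``before_bagging`` — one encoding per variable is fitted on the full
  training set and shared by every tree. For target-based encodings this
  leaks target information from rows that later fall out-of-bag.
* ``after_bagging`` — each tree draws its bootstrap first and fits its own
  encodings on the in-bag rows only (with bootstrap multiplicity); OOB rows
  are encoded through that per-tree map, with levels absent from the
  bootstrap handled by the encoding's absent-level policy.

Splits are standard CART: Gini impurity, thresholds at midpoints between
consecutive distinct encoded values, ``mtry`` candidate variables drawn
uniformly without replacement at each node, grown to purity (no depth limit,
``min_node_size`` 1 — classification defaults of the ranger package).
Determinism is a contract: tree ``t`` uses an independent generator derived
from ``(seed, t)``, so identical data, parameters and seed reproduce the
forest node-for-node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .encoders import (
    LevelEncoding,
    fit_integer_encoding,
    fit_target_encoding_multiclass,
    fit_target_encoding_twoclass,
)

__all__ = [
    "ForestParams",
    "SplitRecord",
    "Tree",
    "Forest",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "fit_forest",
    "predict",
    "oob_predict",
]

_ENCODING_METHODS = ("integer_alpha", "target_twoclass", "target_pca")
_TIMINGS = ("before_bagging", "after_bagging")

# Minimum accepted impurity decrease; splits with (numerically) zero gain
# terminate the node instead.
_MIN_GAIN = 1e-12


@dataclass(frozen=True)
class ForestParams:
    """Forest hyper-parameters.

    ``mtry`` (number of candidate variables per node) defaults to ⌈√p⌉,
    resolved at fit time; with a single predictor it is necessarily 1.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 1
    seed: int = 0
    encoding_method: str = "integer_alpha"
    encoding_timing: str = "before_bagging"
    air_shadows: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not (0 <= int(self.seed) < 2**31):
            raise ValueError("seed must lie in [0, 2^31)")
        if self.encoding_method not in _ENCODING_METHODS:
            raise ValueError(f"unknown encoding_method {self.encoding_method!r}")
        if self.encoding_timing not in _TIMINGS:
            raise ValueError(f"unknown encoding_timing {self.encoding_timing!r}")

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(p))
        if m > p:
            raise ValueError(f"mtry={m} exceeds number of predictors p={p}")
        return m


@dataclass(frozen=True)
class SplitRecord:
    """One internal node's split, on the encoded scale.

    ``impurity_decrease`` is Gini(parent) minus the child-weighted Gini of the
    two children (not scaled by the node fraction); ``node_fraction`` is the
    share of the tree's in-bag sample sitting at the node. Their product is
    the node's contribution to MDI. In a forest grown with ``air_shadows``,
    nodes may split on a permuted shadow copy of a variable; such records
    carry ``is_shadow=True`` with ``variable_index`` naming the underlying
    real variable.
    """

    node_id: int
    variable_index: int
    threshold: float
    impurity_decrease: float
    node_fraction: float
    is_shadow: bool = False


class _Node:
    __slots__ = (
        "node_id", "var", "threshold", "left", "right",
        "n_left", "n_right", "counts", "pred",
    )

    def __init__(self) -> None:
        self.var = -1          # -1 marks a leaf
        self.left = None
        self.right = None


@dataclass
class Tree:
    root: _Node
    in_bag: np.ndarray                     # bootstrap row indices, with multiplicity
    oob: np.ndarray                        # sorted row indices absent from in_bag
    encodings: dict[str, LevelEncoding]    # per-variable; shared obj refs before bagging
    splits: list[SplitRecord]
    tree_id: int = 0
    # training-row permutations defining this tree's shadow copies (air_shadows)
    shadow_perms: np.ndarray | None = None

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Class codes for an encoded matrix; NaN routes to the larger child."""
        out = np.empty(X.shape[0], dtype=np.intp)
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.var < 0:
                out[idx] = node.pred
                continue
            x = X[idx, node.var]
            go_left = x <= node.threshold
            nan = np.isnan(x)
            if nan.any():
                go_left[nan] = node.n_left >= node.n_right
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out


@dataclass
class Forest:
    trees: list[Tree]
    params: ForestParams
    class_order: tuple[str, ...]
    feature_names: tuple[str, ...]
    response: str
    train: pd.DataFrame = field(repr=False)
    shared_encodings: dict[str, LevelEncoding] | None = None
    _train_encoded: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def y_codes(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_order)}
        return np.array([lut[v] for v in self.train[self.response]], dtype=np.intp)

    def encode_frame(self, frame: pd.DataFrame, tree: Tree | None = None) -> np.ndarray:
        """Encode a data frame with the forest's (or one tree's) level maps."""
        enc = self.shared_encodings if tree is None else tree.encodings
        if enc is None:
            enc = self.trees[0].encodings
        missing = [f for f in self.feature_names if f not in frame.columns]
        if missing:
            raise KeyError(f"data lacks forest variables: {missing}")
        cols = [enc[f].apply(frame[f].to_numpy()) for f in self.feature_names]
        return np.column_stack(cols)

    def tree_train_matrix(self, tree: Tree) -> np.ndarray:
        """Full training set encoded the way `tree` sees it.

        For forests grown with ``air_shadows`` the tree's shadow columns are
        appended, so routing through shadow-split nodes stays exact for
        training (hence OOB) rows.
        """
        if self.params.encoding_timing == "before_bagging":
            base = self._train_encoded
        else:
            base = self.encode_frame(self.train, tree=tree)
        if tree.shadow_perms is None:
            return base
        p = base.shape[1]
        ext = np.empty((base.shape[0], 2 * p))
        ext[:, :p] = base
        for j in range(p):
            ext[:, p + j] = base[tree.shadow_perms[j], j]
        return ext


def gini_impurity(class_counts: Sequence[int]) -> float:
    """``1 − Σ_c (n_c/n)²`` for a node's class counts; errors on an empty node."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty node has no Gini impurity")
    p = counts / n
    return float(1.0 - np.dot(p, p))


def _best_threshold(
    x: np.ndarray, y: np.ndarray, n_classes: int, parent_gini: float
) -> tuple[float, float, int, int] | None:
    """Best midpoint threshold on one column.

    Returns ``(decrease, threshold, n_left, n_right)`` or None when fewer than
    two distinct finite values exist. NaN entries (absent-level sentinels) are
    excluded from threshold enumeration and joined to the larger child.
    """
    nan_mask = np.isnan(x)
    if nan_mask.any():
        return _best_threshold_with_nan(x, y, n_classes, parent_gini, nan_mask)
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    cut = np.flatnonzero(xs[1:] != xs[:-1]) + 1      # candidate left-block sizes
    if cut.size == 0:
        return None
    tot = np.bincount(ys, minlength=n_classes).astype(float)
    cumL = np.empty((cut.size, n_classes))
    for c in range(n_classes):
        cumL[:, c] = np.cumsum(ys == c)[cut - 1]
    nL = cut.astype(float)
    nR = n - nL
    sumL = np.einsum("ij,ij->i", cumL, cumL)
    R = tot[None, :] - cumL
    sumR = np.einsum("ij,ij->i", R, R)
    dec = parent_gini - 1.0 + (sumL / nL + sumR / nR) / n
    i = int(np.argmax(dec))                           # first max -> smallest threshold
    if dec[i] <= _MIN_GAIN:
        return None
    thr = 0.5 * (xs[cut[i] - 1] + xs[cut[i]])
    return float(dec[i]), float(thr), int(cut[i]), int(n - cut[i])


def _best_threshold_with_nan(x, y, n_classes, parent_gini, nan_mask):
    # Slow path: sentinel rows attach to whichever child has more finite
    # samples (ties: left). Only reachable when training data itself carries
    # absent-level sentinels, which the fitting paths never produce.
    fin = ~nan_mask
    xf, yf = x[fin], y[fin]
    y_nan = y[nan_mask]
    vals = np.unique(xf)
    if vals.size < 2:
        return None
    n = x.shape[0]
    best = None
    for a, b in zip(vals[:-1], vals[1:]):
        thr = 0.5 * (a + b)
        left = xf <= thr
        cl = np.bincount(yf[left], minlength=n_classes).astype(float)
        cr = np.bincount(yf[~left], minlength=n_classes).astype(float)
        if cl.sum() >= cr.sum():
            cl += np.bincount(y_nan, minlength=n_classes)
        else:
            cr += np.bincount(y_nan, minlength=n_classes)
        nL, nR = cl.sum(), cr.sum()
        dec = parent_gini - (nL / n) * gini_impurity(cl) - (nR / n) * gini_impurity(cr)
        if best is None or dec > best[0]:
            best = (float(dec), float(thr), int(nL), int(nR))
    if best is None or best[0] <= _MIN_GAIN:
        return None
    return best


def best_split(
    encoded_columns: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[int],
    *,
    n_classes: int | None = None,
    node_id: int = 0,
    node_fraction: float = 1.0,
) -> SplitRecord | None:
    """Best Gini split at a node over the candidate variables.

    Ties in impurity decrease break to the lower variable index, then the
    smaller threshold (the within-variable scan already favours the smaller
    threshold). Returns None for pure or unsplittable nodes.
    """
    X = np.asarray(encoded_columns, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if len(candidates) == 0:
        raise ValueError("candidates must be nonempty")
    C = n_classes if n_classes is not None else int(y.max()) + 1
    counts = np.bincount(y, minlength=C)
    parent = gini_impurity(counts)
    if parent <= 0.0:
        return None
    best = None
    for j in sorted(candidates):
        res = _best_threshold(X[:, j], y, C, parent)
        if res is None:
            continue
        if best is None or res[0] > best[1][0]:
            best = (j, res)
    if best is None:
        return None
    j, (dec, thr, _, _) = best
    return SplitRecord(
        node_id=node_id,
        variable_index=j,
        threshold=thr,
        impurity_decrease=dec,
        node_fraction=node_fraction,
    )


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
    *,
    in_bag: np.ndarray | None = None,
    n_classes: int | None = None,
    encodings: dict[str, LevelEncoding] | None = None,
    tree_id: int = 0,
) -> Tree:
    """Grow one CART tree on the bootstrap rows ``in_bag`` of encoded ``X``.

    Recursion is depth-first, left child first, so the per-node ``mtry`` draws
    consume the generator in a fixed order (the determinism contract). When
    ``params.air_shadows`` is set, a permuted shadow copy of every variable
    (one training-row permutation per variable, drawn up front from ``rng``)
    joins the pool of split candidates: ``mtry`` candidates are then drawn
    from the ``2p`` real-plus-shadow columns, and nodes that split on a
    shadow are recorded with ``is_shadow=True``. Real and shadow copies are
    exchangeable when the variable carries no information, which is what
    makes the actual-impurity-reduction difference unbiased under a null.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    n_total, p = X.shape
    if in_bag is None:
        in_bag = np.arange(n_total)
    in_bag = np.asarray(in_bag, dtype=np.intp)
    if in_bag.size == 0:
        raise ValueError("empty in_bag sample")
    C = n_classes if n_classes is not None else int(y.max()) + 1
    mtry = params.resolve_mtry(p)

    Xb = X[in_bag]
    yb = y[in_bag]
    nb = in_bag.size

    Xgrow = Xb
    n_vars = p
    shadow_perms = None
    if params.air_shadows:
        # Shadow columns: permute each variable across the *training rows*,
        # then apply the bootstrap multiset. Rows drawn several times keep one
        # shadow value per draw, mirroring how bootstrap duplication couples
        # the real column to the response; under a null this makes each
        # shadow exchangeable with its real counterpart.
        shadow_perms = np.empty((p, n_total), dtype=np.intp)
        shadow_b = np.empty_like(Xb)
        for j in range(p):
            shadow_perms[j] = rng.permutation(n_total)
            shadow_b[:, j] = X[shadow_perms[j], j][in_bag]
        Xgrow = np.hstack([Xb, shadow_b])
        n_vars = 2 * p

    oob = np.setdiff1d(np.arange(n_total), in_bag, assume_unique=False)
    tree = Tree(
        root=_Node(), in_bag=in_bag, oob=oob,
        encodings=encodings or {}, splits=[], tree_id=tree_id,
        shadow_perms=shadow_perms,
    )

    next_id = 0
    # stack holds (node, row positions within the bootstrap sample)
    stack: list[tuple[_Node, np.ndarray]] = [(tree.root, np.arange(nb))]
    while stack:
        node, idx = stack.pop()
        node.node_id = next_id
        next_id += 1
        counts = np.bincount(yb[idx], minlength=C)
        node.counts = counts
        node.pred = int(np.argmax(counts))
        parent = gini_impurity(counts)
        if parent <= 0.0 or idx.size < max(2, params.min_node_size):
            continue
        if mtry < n_vars:
            cand = np.sort(rng.choice(n_vars, size=mtry, replace=False))
        else:
            cand = np.arange(n_vars)
        best = None
        for j in cand:
            res = _best_threshold(Xgrow[idx, j], yb[idx], C, parent)
            if res is not None and (best is None or res[0] > best[1][0]):
                best = (int(j), res)
        if best is None:
            continue
        j, (dec, thr, nL, nR) = best
        node.var = j
        node.threshold = thr
        node.n_left, node.n_right = nL, nR
        tree.splits.append(
            SplitRecord(
                node_id=node.node_id,
                variable_index=j % p,
                threshold=thr,
                impurity_decrease=dec,
                node_fraction=idx.size / nb,
                is_shadow=j >= p,
            )
        )
        go_left = Xgrow[idx, j] <= thr
        node.left, node.right = _Node(), _Node()
        stack.append((node.right, idx[~go_left]))
        stack.append((node.left, idx[go_left]))     # popped first: left-first order
    return tree


def _fit_encodings(
    method: str,
    frame: pd.DataFrame,
    features: Sequence[str],
    y: Sequence[str],
    class_order: tuple[str, ...],
    fit_scope: str,
    absent_policy: str,
) -> dict[str, LevelEncoding]:
    out = {}
    for f in features:
        x = frame[f].to_numpy()
        if method == "integer_alpha":
            out[f] = fit_integer_encoding(
                x, fit_scope=fit_scope, absent_policy=absent_policy
            )
        elif method == "target_twoclass":
            out[f] = fit_target_encoding_twoclass(
                x, y, class_order=class_order,
                fit_scope=fit_scope, absent_policy=absent_policy,
            )
        else:
            out[f] = fit_target_encoding_multiclass(
                x, y, class_order=class_order,
                fit_scope=fit_scope, absent_policy=absent_policy,
            )
    return out


def fit_forest(
    train: pd.DataFrame,
    params: ForestParams,
    *,
    response: str = "y",
    absent_policy: str = "majority_child",
    encodings: dict[str, LevelEncoding] | None = None,
) -> Forest:
    """Fit a bagged forest with the requested encoding method and timing.

    ``before_bagging``: encodings are fitted once on the full training set —
    for target-based methods every training row's target, including rows that
    will later be out-of-bag for a given tree, informs the level order (the
    leaky construction). ``after_bagging``: each tree's bootstrap is drawn
    first and its encodings are fitted on the in-bag rows only.

    ``encodings``, if given, are pre-fitted maps applied to every tree
    regardless of timing (used by the holdout importance constructions).
    """
    if response not in train.columns:
        raise KeyError(f"response column {response!r} not in data")
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    y_labels = train[response].astype(str).to_numpy()
    class_order = tuple(sorted(set(y_labels.tolist())))
    if len(class_order) < 2:
        raise ValueError("training data has a single response class")
    lut = {c: i for i, c in enumerate(class_order)}
    y = np.array([lut[v] for v in y_labels], dtype=np.intp)
    features = tuple(c for c in train.columns if c != response)
    if not features:
        raise ValueError("no predictor columns")
    n = len(train)
    p = len(features)
    params.resolve_mtry(p)  # validate early

    shared = encodings
    before = params.encoding_timing == "before_bagging" or shared is not None
    if shared is None and before:
        shared = _fit_encodings(
            params.encoding_method, train, features, y_labels,
            class_order, "full_train", absent_policy,
        )
    X_full = None
    if before:
        cols = [shared[f].apply(train[f].to_numpy()) for f in features]
        X_full = np.column_stack(cols)

    trees = []
    for t in range(params.n_trees):
        rng = np.random.default_rng([params.seed, t])
        in_bag = rng.integers(0, n, size=n)
        if before:
            tree = grow_tree(
                X_full, y, params, rng, in_bag=in_bag,
                n_classes=len(class_order), encodings=shared, tree_id=t,
            )
        else:
            tree_enc = _fit_encodings(
                params.encoding_method, train.iloc[in_bag], features,
                y_labels[in_bag], class_order, f"bootstrap:{t}", absent_policy,
            )
            cols = [tree_enc[f].apply(train[f].to_numpy()) for f in features]
            Xt = np.column_stack(cols)
            tree = grow_tree(
                Xt, y, params, rng, in_bag=in_bag,
                n_classes=len(class_order), encodings=tree_enc, tree_id=t,
            )
        trees.append(tree)

    return Forest(
        trees=trees,
        params=params,
        class_order=class_order,
        feature_names=features,
        response=response,
        train=train,
        shared_encodings=shared if before else None,
        _train_encoded=X_full,
    )


def predict(forest: Forest, newdata: pd.DataFrame) -> np.ndarray:
    """Majority-vote class labels; vote ties go to the first class in order."""
    n = len(newdata)
    votes = np.zeros((n, forest.n_classes), dtype=np.int64)
    shared_X = None
    if forest.shared_encodings is not None:
        shared_X = forest.encode_frame(newdata)
    for tree in forest.trees:
        X = shared_X if shared_X is not None else forest.encode_frame(newdata, tree=tree)
        if tree.shadow_perms is not None:
            # shadow values are undefined off the training set; NaN columns
            # route through shadow-split nodes to the larger child
            pad = np.full((n, X.shape[1]), np.nan)
            X = np.hstack([X, pad])
        codes = tree.predict_codes(X)
        votes[np.arange(n), codes] += 1
    pred = votes.argmax(axis=1)  # argmax takes the first max: class_order tie rule
    return np.array([forest.class_order[c] for c in pred], dtype=object)


def oob_predict(forest: Forest) -> np.ndarray:
    """Per-training-row OOB majority vote; None where no tree left the row out."""
    n = len(forest.train)
    votes = np.zeros((n, forest.n_classes), dtype=np.int64)
    for tree in forest.trees:
        if tree.oob.size == 0:
            continue
        X = forest.tree_train_matrix(tree)
        codes = tree.predict_codes(X[tree.oob])
        votes[tree.oob, codes] += 1
    has_vote = votes.sum(axis=1) > 0
    pred_codes = votes.argmax(axis=1)
    out = np.empty(n, dtype=object)
    out[:] = None
    out[has_vote] = [forest.class_order[c] for c in pred_codes[has_vote]]
    return out
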