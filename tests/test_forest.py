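import numpy as np
import pandas as pd
import pytest

from leakyforest import (
    ForestParams,
    best_split,
    fit_forest,
    gini_impurity,
    grow_tree,
    oob_predict,
    predict,
)

from _oracles import best_split_exhaustive


def _tree_structure(tree):
    return [
        (r.variable_index, r.is_shadow, round(r.threshold, 12), round(r.impurity_decrease, 12))
        for r in tree.splits
    ]


def _walk_leaves(node, frac=1.0):
    if node.var < 0:
        yield node, frac
        return
    total = node.counts.sum()
    yield from _walk_leaves(node.left, frac * node.n_left / total)
    yield from _walk_leaves(node.right, frac * node.n_right / total)


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected",
        [((0, 5, 0), 0.0), ((1, 1, 1), 2 / 3), ((2, 1, 1), 0.625)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected, abs=1e-15)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestBestSplit:
    def test_perfect_binary_separation(self):
        rec = best_split(np.array([[1.0], [1.0], [2.0], [2.0]]),
                         np.array([0, 0, 1, 1]), [0], n_classes=2)
        assert rec.threshold == pytest.approx(1.5)
        assert rec.impurity_decrease == pytest.approx(0.5)

    def test_pure_node_returns_none(self):
        rec = best_split(np.array([[1.0], [2.0], [3.0]]),
                         np.array([0, 0, 0]), [0], n_classes=2)
        assert rec is None

    def test_constant_column_returns_none(self):
        rec = best_split(np.ones((4, 1)), np.array([0, 1, 0, 1]), [0], n_classes=2)
        assert rec is None

    def test_matches_brute_force_enumeration(self):
        """On random small nodes the chosen split equals the argmax over an
        independent enumeration of every (variable, threshold) pair."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            p = int(rng.integers(1, 4))
            C = int(rng.integers(2, 4))
            X = rng.integers(1, 5, size=(n, p)).astype(float)
            y = rng.integers(0, C, size=n).astype(np.intp)
            rec = best_split(X, y, list(range(p)), n_classes=C)
            want = best_split_exhaustive(X, y, C)
            counts = np.bincount(y, minlength=C)
            if gini_impurity(counts) == 0 or want is None or want[0] <= 1e-12:
                assert rec is None
                continue
            dec, j, thr = want
            assert rec.impurity_decrease == pytest.approx(dec, abs=1e-12)
            # exact-arithmetic ties may resolve either way in floats: accept
            # any pair whose brute-force decrease matches the optimum
            from _oracles import best_threshold_decrease

            chosen = best_threshold_decrease(
                np.where(X[:, rec.variable_index] <= rec.threshold, 0.0, 1.0), y, C
            )
            assert chosen[0] == pytest.approx(dec, abs=1e-12)

    def test_root_split_matches_sklearn_stump(self):
        """Independent cross-check: on numeric data with a unique best split,
        a depth-1 scikit-learn tree finds the same (feature, threshold)."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(13)
        for _ in range(20):
            X = rng.integers(1, 10, size=(30, 3)).astype(float)
            y = (X[:, 1] > 5).astype(np.intp)   # variable 1 is informative
            rec = best_split(X, y, [0, 1, 2], n_classes=2)
            stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
            assert rec.variable_index == stump.tree_.feature[0]
            assert rec.threshold == pytest.approx(stump.tree_.threshold[0])

    def test_sentinel_rows_join_larger_child(self):
        # 4 finite rows split cleanly; the NaN row joins the larger (left) child
        X = np.array([[1.0], [1.0], [1.0], [2.0], [np.nan]])
        y = np.array([0, 0, 0, 1, 1], dtype=np.intp)
        rec = best_split(X, y, [0], n_classes=2)
        assert rec.threshold == pytest.approx(1.5)
        # left child {0,0,0,+nan row 1}: gini drops less than a clean split
        assert 0 < rec.impurity_decrease < 0.5


class TestGrowTree:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 6, size=(40, 2)).astype(float)
        y = rng.integers(0, 3, size=40).astype(np.intp)
        params = ForestParams(n_trees=1, seed=1)
        t1 = grow_tree(X, y, params, np.random.default_rng(11), n_classes=3)
        t2 = grow_tree(X, y, params, np.random.default_rng(11), n_classes=3)
        assert _tree_structure(t1) == _tree_structure(t2)

    def test_perfect_separator_gives_depth_one_tree(self):
        X = np.array([[1.0, 3.0], [1.0, 1.0], [2.0, 3.0], [2.0, 1.0]])
        y = np.array([0, 0, 1, 1], dtype=np.intp)
        params = ForestParams(n_trees=1, mtry=2)
        tree = grow_tree(X, y, params, np.random.default_rng(0), n_classes=2)
        assert len(tree.splits) == 1
        assert tree.splits[0].variable_index == 0
        for leaf, _ in _walk_leaves(tree.root):
            assert gini_impurity(leaf.counts) == 0.0

    def test_empty_in_bag_rejected(self):
        with pytest.raises(ValueError, match="in_bag"):
            grow_tree(np.ones((3, 1)), np.zeros(3, dtype=np.intp),
                      ForestParams(n_trees=1), np.random.default_rng(0),
                      in_bag=np.array([], dtype=np.intp))

    def test_leaf_tie_predicts_first_class(self):
        X = np.ones((2, 1))
        y = np.array([0, 1], dtype=np.intp)
        tree = grow_tree(X, y, ForestParams(n_trees=1), np.random.default_rng(0),
                         n_classes=2)
        assert tree.root.var == -1 and tree.root.pred == 0

    def test_oob_fraction_matches_binomial_expectation(self):
        """Mean OOB fraction over trees ≈ (1 − 1/n)^n (≈ 0.366 for n=100);
        the in-bag thus holds about two-thirds of the rows."""
        n = 100
        rng = np.random.default_rng(5)
        fracs = []
        for t in range(300):
            trng = np.random.default_rng([17, t])
            in_bag = trng.integers(0, n, size=n)
            fracs.append(1 - np.unique(in_bag).size / n)
        expected = (1 - 1 / n) ** n
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)

    def test_gini_conservation_per_tree(self):
        """Root impurity minus leaf-weighted impurity equals the sum of
        node_fraction × impurity_decrease over internal nodes, to 1e-9."""
        rng = np.random.default_rng(21)
        X = rng.integers(1, 8, size=(60, 2)).astype(float)
        y = rng.integers(0, 3, size=60).astype(np.intp)
        for t in range(5):
            trng = np.random.default_rng([5, t])
            in_bag = trng.integers(0, 60, size=60)
            tree = grow_tree(X, y, ForestParams(n_trees=1, mtry=2), trng,
                             in_bag=in_bag, n_classes=3)
            root_gini = gini_impurity(tree.root.counts)
            leaf_term = sum(
                frac * gini_impurity(leaf.counts)
                for leaf, frac in _walk_leaves(tree.root)
            )
            split_term = sum(r.node_fraction * r.impurity_decrease for r in tree.splits)
            assert root_gini - leaf_term == pytest.approx(split_term, abs=1e-9)

    def test_monotone_encoding_invariance(self):
        """A strictly increasing transform of one column yields an identical
        tree (same split variables, same per-node decreases, same routing)."""
        rng = np.random.default_rng(9)
        X = rng.integers(1, 7, size=(50, 2)).astype(float)
        y = rng.integers(0, 3, size=50).astype(np.intp)
        X2 = X.copy()
        X2[:, 0] = X[:, 0] ** 2 + 3.0   # strictly increasing on positive ranks
        p = ForestParams(n_trees=1, mtry=1, seed=0)
        t1 = grow_tree(X, y, p, np.random.default_rng(42), n_classes=3)
        t2 = grow_tree(X2, y, p, np.random.default_rng(42), n_classes=3)
        assert [(r.variable_index, round(r.impurity_decrease, 12)) for r in t1.splits] == \
               [(r.variable_index, round(r.impurity_decrease, 12)) for r in t2.splits]
        assert t1.predict_codes(X).tolist() == t2.predict_codes(X2).tolist()


class TestFitForest:
    def test_integer_encoding_timing_equivalence(self, null_train):
        """Alphabetical encoding is data-independent, so before- and
        after-bagging forests coincide when every bootstrap sees all levels."""
        train, _ = null_train
        # k=3 levels over 48 rows: every bootstrap contains all levels
        train = train.assign(x1=np.array(["a", "b", "c"])[np.arange(len(train)) % 3])
        fb = fit_forest(train, ForestParams(n_trees=20, seed=3,
                                            encoding_timing="before_bagging"))
        fa = fit_forest(train, ForestParams(n_trees=20, seed=3,
                                            encoding_timing="after_bagging"))
        for tb, ta in zip(fb.trees, fa.trees):
            assert _tree_structure(tb) == _tree_structure(ta)
        assert predict(fb, train).tolist() == predict(fa, train).tolist()

    def test_before_bagging_shares_one_encoding(self, null_train, small_params):
        train, _ = null_train
        params = ForestParams(n_trees=5, seed=1, encoding_method="target_pca")
        forest = fit_forest(train, params)
        encs = {id(t.encodings["x1"]) for t in forest.trees}
        assert len(encs) == 1
        assert forest.trees[0].encodings["x1"].fit_scope == "full_train"

    def test_after_bagging_has_per_tree_encodings(self, null_train):
        train, _ = null_train
        params = ForestParams(n_trees=5, seed=1, encoding_method="target_pca",
                              encoding_timing="after_bagging")
        forest = fit_forest(train, params)
        scopes = [t.encodings["x1"].fit_scope for t in forest.trees]
        assert scopes == [f"bootstrap:{t}" for t in range(5)]
        assert len({id(t.encodings["x1"]) for t in forest.trees}) == 5

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"x1": ["a", "b", "a"], "y": ["c1", "c1", "c1"]})
        with pytest.raises(ValueError, match="single"):
            fit_forest(frame, ForestParams(n_trees=2))

    def test_determinism_bit_identical(self, null_train, small_params):
        train, test = null_train
        f1 = fit_forest(train, small_params)
        f2 = fit_forest(train, small_params)
        assert predict(f1, test).tolist() == predict(f2, test).tolist()
        for t1, t2 in zip(f1.trees, f2.trees):
            assert _tree_structure(t1) == _tree_structure(t2)
            assert t1.in_bag.tolist() == t2.in_bag.tolist()

    def test_bootstrap_inclusion_probability(self, null_train):
        """Per-row in-bag inclusion over many trees approaches
        1 − (1 − 1/n)^n within 3 Monte-Carlo SEs."""
        train, _ = null_train
        n = len(train)
        forest = fit_forest(train, ForestParams(n_trees=400, seed=2))
        incl = np.zeros(n)
        for tree in forest.trees:
            assert tree.in_bag.size == n
            assert np.intersect1d(tree.oob, np.unique(tree.in_bag)).size == 0
            incl[np.unique(tree.in_bag)] += 1
        p_hat = incl.mean() / 400
        p_exp = 1 - (1 - 1 / n) ** n
        se = np.sqrt(p_exp * (1 - p_exp) / (400 * n))
        assert abs(p_hat - p_exp) < 3 * se + 0.01

    def test_rank_reversal_leaves_forest_invariant(self, null_train):
        """Flipping the leading-eigenvector sign reverses the level ranks;
        thresholds mirror but structure, predictions and OOB error do not
        change (monotone-transform invariance)."""
        from leakyforest import LevelEncoding, oob_error

        train, test = null_train
        params = ForestParams(n_trees=15, seed=4, encoding_method="target_pca")
        f1 = fit_forest(train, params)
        enc = f1.shared_encodings["x1"]
        k = enc.k_observed
        rev = {lev: k + 1 - r for lev, r in enc.ranks.items()}
        reversed_enc = LevelEncoding("target_pca", rev, enc.fit_scope,
                                     enc.absent_policy, enc.class_order)
        f2 = fit_forest(train, params, encodings={"x1": reversed_enc})
        assert predict(f1, test).tolist() == predict(f2, test).tolist()
        assert oob_error(f1) == pytest.approx(oob_error(f2), abs=1e-12)


class TestPrediction:
    def test_stump_forest_predicts_majority(self):
        # k=1: no split possible; every tree is a majority-vote stump
        frame = pd.DataFrame({"x1": ["a"] * 10,
                              "y": ["c1"] * 6 + ["c2"] * 4})
        forest = fit_forest(frame, ForestParams(n_trees=3, seed=0))
        assert predict(forest, frame).tolist() == ["c1"] * 10

    def test_unknown_variable_rejected(self, null_train, small_params):
        train, _ = null_train
        forest = fit_forest(train, small_params)
        with pytest.raises(KeyError, match="x1"):
            predict(forest, pd.DataFrame({"z": ["a"], "y": ["c1"]}))

    def test_single_tree_oob_predictions(self, null_train):
        train, _ = null_train
        forest = fit_forest(train, ForestParams(n_trees=1, seed=6))
        tree = forest.trees[0]
        preds = oob_predict(forest)
        in_bag_only = np.setdiff1d(np.arange(len(train)), tree.oob)
        assert all(preds[i] is None for i in in_bag_only)
        X = forest.tree_train_matrix(tree)
        codes = tree.predict_codes(X[tree.oob])
        for i, c in zip(tree.oob, codes):
            assert preds[i] == forest.class_order[c]

    def test_absent_level_routing_does_not_crash(self, null_train):
        train, _ = null_train
        forest = fit_forest(train, ForestParams(n_trees=10, seed=8))
        new = pd.DataFrame({"x1": ["zzz_absent"] * 4, "y": ["c1"] * 4})
        labels = predict(forest, new)
        assert set(labels) <= set(forest.class_order)

    def test_strict_policy_propagates(self, null_train):
        train, _ = null_train
        forest = fit_forest(train, ForestParams(n_trees=5, seed=8),
                            absent_policy="strict")
        new = pd.DataFrame({"x1": ["zzz_absent"], "y": ["c1"]})
        with pytest.raises(KeyError, match="zzz_absent"):
            predict(forest, new)
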