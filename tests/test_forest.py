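import numpy as np
import pytest

from pkqspr.forest import (
    ForestModel,
    balanced_bootstrap,
    fit_balanced_forest,
    fit_tree,
    oob_predictions,
    selection_frequency_importance,
)
from pkqspr.validation import hand_till_auc


def brute_force_best_split(Xcol, y, n_classes):
    """Exhaustive Gini search over all midpoint thresholds (oracle)."""
    xs = np.unique(Xcol)
    best = None
    n = len(y)
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = 0.5 * (lo + hi)
        left = y[Xcol <= thr]
        right = y[Xcol > thr]
        g = 0.0
        for part in (left, right):
            freq = np.bincount(part, minlength=n_classes) / len(part)
            g += len(part) / n * (1 - np.sum(freq**2))
        if best is None or g < best[1] - 1e-12:
            best = (thr, g)
    return best


class TestBalancedBootstrap:
    def test_imbalanced_sizes_equalized(self):
        labels = np.repeat([1, 2, 3], [105, 96, 181])
        bag = balanced_bootstrap(labels, seed=0)
        assert len(bag) == 288
        classes, counts = np.unique(labels[bag], return_counts=True)
        assert counts.tolist() == [96, 96, 96]

    def test_balanced_input(self):
        labels = np.repeat(["a", "b", "c"], 10)
        bag = balanced_bootstrap(labels, seed=1)
        _, counts = np.unique(labels[bag], return_counts=True)
        assert counts.tolist() == [10, 10, 10]

    def test_seed_determinism(self):
        labels = np.repeat([0, 1], [20, 30])
        assert np.array_equal(balanced_bootstrap(labels, 7), balanced_bootstrap(labels, 7))
        assert not np.array_equal(balanced_bootstrap(labels, 7), balanced_bootstrap(labels, 8))

    def test_invariant_holds_for_every_tree(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=10, seed=0)
        k = min(np.bincount(y)[1:])
        for tree in forest.trees:
            _, counts = np.unique(y[tree.in_bag], return_counts=True)
            assert np.all(counts == k)


class TestFitTree:
    def test_perfectly_separable_single_descriptor(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        tree = fit_tree(X, y, np.arange(6), mtry=1, seed=0, min_leaf=2)
        assert not tree.root.is_leaf
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert np.array_equal(tree.predict(X), y)

    def test_mtry_floor_sqrt(self):
        assert int(np.floor(np.sqrt(140))) == 11
        X = np.random.default_rng(0).normal(size=(30, 140))
        y = np.random.default_rng(1).integers(0, 2, 30)
        forest = fit_balanced_forest(X, y, n_trees=1, seed=0)
        # every realized split drew exactly 11 candidates
        for eligible, _ in forest.trees[0].candidate_log:
            assert len(eligible) == 11

    @pytest.mark.parametrize("seed", range(5))
    def test_gini_split_matches_exhaustive_search(self, seed):
        """On small instances the chosen split equals brute-force optimum."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        X = rng.normal(size=(n, 1))
        y = rng.integers(0, 3, n)
        if len(np.unique(y)) < 2:
            y[0] = (y[0] + 1) % 3
        tree = fit_tree(X, y, np.arange(n), mtry=1, seed=0, min_leaf=n)  # root only
        oracle = brute_force_best_split(X[:, 0], y, 3)
        if tree.root.is_leaf:
            assert oracle is None or len(np.unique(y)) < 2
        else:
            assert tree.root.threshold == pytest.approx(oracle[0])

    def test_degenerate_constant_column_becomes_leaf(self):
        X = np.ones((10, 1))
        y = np.array([0] * 5 + [1] * 5)
        tree = fit_tree(X, y, np.arange(10), mtry=1, seed=0)
        assert tree.root.is_leaf


class TestForest:
    def test_separable_oob_accuracy(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=10, seed=0)
        oob = oob_predictions(forest, X, y)
        assert oob["accuracy"] > 0.9

    def test_many_trees_drive_oob_error_down(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=50, seed=0)
        oob = oob_predictions(forest, X, y)
        assert oob["accuracy"] > 0.97

    def test_label_shuffle_auc_near_half(self, separable_3class):
        X, y = separable_3class
        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(10):
            ys = rng.permutation(y)
            forest = fit_balanced_forest(X, ys, n_trees=10, seed=rep)
            oob = oob_predictions(forest, X, ys)
            cov = oob["covered"]
            aucs.append(hand_till_auc(ys[cov], oob["proba"][cov], forest.classes))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_prediction_invariant_to_tree_order(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=5, seed=0)
        reordered = ForestModel(
            trees=list(reversed(forest.trees)),
            classes=forest.classes,
            tree_seeds=forest.tree_seeds,
            n_train=forest.n_train,
            variable_names=forest.variable_names,
        )
        assert np.array_equal(forest.predict(X), reordered.predict(X))
        assert np.allclose(forest.predict_proba(X), reordered.predict_proba(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_balanced_forest(np.zeros((5, 2)), np.ones(5), seed=0)

    def test_json_roundtrip(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=3, seed=0)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "f.json")
            forest.to_json(p)
            back = ForestModel.from_json(p)
        assert np.array_equal(forest.predict(X), back.predict(X))
        assert np.allclose(forest.predict_proba(X), back.predict_proba(X))


class TestOOB:
    def test_single_tree_oob_is_complement_of_bag(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=1, seed=3)
        oob = oob_predictions(forest, X, y)
        in_bag = np.unique(forest.trees[0].in_bag)
        assert np.array_equal(np.where(oob["covered"])[0], np.setdiff1d(np.arange(len(y)), in_bag))

    def test_in_bag_accuracy_at_least_oob(self):
        rng = np.random.default_rng(1)
        n = 300
        y = np.repeat([1, 2, 3], 100)
        X = rng.normal(size=(n, 5))
        X[:, 0] += y * 1.0  # noisy overlap
        forest = fit_balanced_forest(X, y, n_trees=10, seed=0)
        oob = oob_predictions(forest, X, y)
        in_bag_acc = np.mean(forest.predict(X) == y)
        assert in_bag_acc >= oob["accuracy"]

    def test_never_oob_compound_flagged(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=1, seed=0)
        never_oob = np.unique(forest.trees[0].in_bag)
        oob = oob_predictions(forest, X, y)
        assert not oob["covered"][never_oob].any()
        assert np.isnan(oob["proba"][never_oob]).all()


class TestImportance:
    @pytest.mark.parametrize("chances,selections,expected", [(12, 1, 8.3), (4, 1, 25.0)])
    def test_percent_selection_frequency_arithmetic(self, chances, selections, expected):
        """Frequency = 100 x selections / chances, to one decimal."""
        freq = 100.0 * selections / chances
        assert round(freq, 1) == expected

    def test_importance_table_consistency(self, separable_3class):
        X, y = separable_3class
        forest = fit_balanced_forest(X, y, n_trees=10, seed=0)
        imp = selection_frequency_importance(forest)
        assessed = imp[imp["number_of_chances"] > 0]
        assert (assessed["percent_selection_frequency"] >= 0).all()
        assert (assessed["percent_selection_frequency"] <= 100).all()
        total_splits = sum(len(t.candidate_log) for t in forest.trees)
        assert imp["selections"].sum() == total_splits
        # the informative descriptor (column 0) dominates
        assert imp.iloc[0]["descriptor"] == "x0"

    def test_never_candidate_reported_not_assessed(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        forest = fit_balanced_forest(X, y, n_trees=1, seed=2, mtry=1)
        imp = selection_frequency_importance(forest)
        no_chance = imp[imp["number_of_chances"] == 0]
        assert no_chance["percent_selection_frequency"].isna().all()
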