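import numpy as np
import pandas as pd
import pytest

from primbox import (
    CARTClassifier,
    CARTRegressor,
    TreeSettings,
    extract_subgroups,
    grow_tree,
    prune_tree,
)
from primbox.tree import _weakest_link_path

from conftest import random_table


def brute_force_root_split(X, y, min_leaf=1):
    """Independent oracle: enumerate every (variable, midpoint threshold)
    and return the best RSS decrease with plain Python."""
    y = np.asarray(y, dtype=float)
    n = len(y)

    def rss(v):
        return float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0

    best = None
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        for t in sorted(set(x))[:-1]:
            uppers = sorted(set(x[x > t]))
            threshold = (t + uppers[0]) / 2
            left = y[x <= threshold]
            right = y[x > threshold]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            dec = rss(y) - rss(left) - rss(right)
            if best is None or dec > best[0] + 1e-12:
                best = (dec, name, threshold)
    return best


def count_internal(node):
    return 0 if node.is_leaf else (1 + count_internal(node.left)
                                   + count_internal(node.right))


class TestGrow:
    def test_constant_outcome_gives_root_leaf(self, rng):
        X, _ = random_table(rng, 50, 2)
        tree = grow_tree(X, np.ones(50))
        assert tree.is_leaf and tree.n == 50

    def test_perfect_step_function_recovered(self):
        x = np.concatenate([np.linspace(-1, -0.1, 10),
                            np.linspace(0.1, 1, 10)])
        X = pd.DataFrame({"x1": x})
        y = (x >= 0).astype(float)
        tree = grow_tree(X, y, TreeSettings(min_split=2, min_leaf=1,
                                            complexity_penalty=0.0))
        assert not tree.is_leaf
        assert tree.split_var == "x1"
        assert tree.split_threshold == pytest.approx(0.0)
        assert tree.left.is_leaf and tree.right.is_leaf
        assert tree.left.value == 0.0 and tree.right.value == 1.0

    @pytest.mark.parametrize("seed", range(15))
    def test_root_split_matches_brute_force(self, seed):
        gen = np.random.default_rng(seed)
        X, y = random_table(gen, 40, 3)
        y = y + 1.5 * (X["x1"] > 0)  # ensure a split clears the cp gate
        settings = TreeSettings(max_depth=1, min_split=2, min_leaf=5,
                                complexity_penalty=0.0)
        tree = grow_tree(X, y)
        tree = grow_tree(X, y, settings)
        dec, name, threshold = brute_force_root_split(X, y, min_leaf=5)
        assert tree.split_var == name
        assert tree.split_threshold == pytest.approx(threshold)

    def test_root_split_agrees_with_sklearn(self, rng):
        from sklearn.tree import DecisionTreeRegressor
        for seed in range(10):
            gen = np.random.default_rng(seed + 100)
            X, y = random_table(gen, 60, 3)
            y = y + (X["x2"] > 0.2) * 1.0
            ours = grow_tree(X, y, TreeSettings(max_depth=1, min_split=2,
                                                min_leaf=5,
                                                complexity_penalty=0.0))
            sk = DecisionTreeRegressor(max_depth=1,
                                       min_samples_leaf=5).fit(X, y)
            assert ours.split_var == X.columns[sk.tree_.feature[0]]
            # sklearn casts X to float32 internally; thresholds drift ~1e-7
            assert ours.split_threshold == pytest.approx(
                sk.tree_.threshold[0], abs=1e-5)

    def test_every_split_decreases_impurity(self, rng):
        X, y = random_table(rng, 200, 4)
        y = y + 2.0 * (X["x1"] > 0) * (X["x2"] > 0)
        tree = grow_tree(X, y, TreeSettings(complexity_penalty=0.001,
                                            min_split=10, min_leaf=3))

        def check(node):
            if node.is_leaf:
                return
            assert node.impurity - node.left.impurity \
                - node.right.impurity >= 0
            assert node.left.n + node.right.n == node.n
            assert node.left.depth == node.depth + 1
            check(node.left)
            check(node.right)

        check(tree)

    def test_leaves_partition_the_sample(self, rng):
        X, y = random_table(rng, 150, 3)
        y = y + (X["x1"] > 0.3)
        tree = grow_tree(X, y, TreeSettings(complexity_penalty=0.005))
        assert sum(leaf.n for leaf in tree.leaves()) == 150

    def test_classification_gini_pure_split(self):
        X = pd.DataFrame({"x1": np.r_[np.zeros(15), np.ones(15)]})
        y = np.array(["no"] * 15 + ["yes"] * 15)
        model = CARTClassifier(max_depth=2, min_split=2, min_leaf=1,
                               complexity_penalty=0.0).fit(X, y)
        assert not model.tree_.is_leaf
        assert list(model.predict(X)) == list(y)

    def test_categorical_split_separates_levels(self, rng):
        X = pd.DataFrame({"g": rng.choice(["a", "b", "c"], 120)})
        y = np.where(X["g"] == "b", 3.0, 0.0) + rng.normal(0, 0.1, 120)
        tree = grow_tree(X, y, TreeSettings(min_split=10, min_leaf=5))
        assert not tree.is_leaf
        side = tree.split_levels
        assert ({"b"} == set(side)) or (set("ac") == set(side))


class TestPruning:
    def test_path_is_nested_with_increasing_alpha(self, rng):
        X, y = random_table(rng, 200, 3)
        y = y + (X["x1"] > 0) + 0.5 * (X["x2"] > 0.5)
        tree = grow_tree(X, y, TreeSettings(complexity_penalty=0.001))
        path = _weakest_link_path(tree, tree.impurity)
        alphas = [a for a, _ in path]
        sizes = [t.n_leaves() for _, t in path]
        assert alphas == sorted(alphas)
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 1  # ends at the root leaf

    def test_pure_noise_usually_prunes_to_root(self):
        hits = 0
        for seed in range(15):
            gen = np.random.default_rng(seed)
            X, y = random_table(gen, 250, 6)
            model = CARTRegressor(prune_rule="min_cv",
                                  random_state=seed).fit(X, y)
            hits += model.tree_.is_leaf
        assert hits >= 12  # large majority of null fits collapse

    def test_root_leaf_unchanged_by_pruning(self, rng):
        X, _ = random_table(rng, 60, 2)
        tree = grow_tree(X, np.ones(60))
        pruned = prune_tree(tree, X, np.ones(60),
                            TreeSettings(prune_rule="min_cv", seed=0))
        assert pruned.is_leaf

    def test_strong_signal_survives_pruning(self):
        for seed in range(10):
            gen = np.random.default_rng(seed)
            X = pd.DataFrame(gen.uniform(-1, 1, size=(400, 4)),
                             columns=[f"x{j}" for j in range(1, 5)])
            y = gen.normal(3.0 * ((np.abs(X.x1) < 0.5)
                                  & (np.abs(X.x2) < 0.5)), 1.0)
            model = CARTRegressor(prune_rule="min_cv",
                                  random_state=seed).fit(X, y)
            assert count_internal(model.tree_) >= 2
            used = set()

            def vars_used(node):
                if not node.is_leaf:
                    used.add(node.split_var)
                    vars_used(node.left)
                    vars_used(node.right)
            vars_used(model.tree_)
            assert {"x1", "x2"} <= used

    def test_one_se_never_larger_than_min_cv(self, rng):
        X, y = random_table(rng, 300, 4)
        y = y + 1.5 * (X["x1"] > 0)
        a = CARTRegressor(prune_rule="min_cv", random_state=1).fit(X, y)
        b = CARTRegressor(prune_rule="one_se", random_state=1).fit(X, y)
        assert count_internal(b.tree_) <= count_internal(a.tree_)

    def test_fold_count_validation(self, rng):
        X, y = random_table(rng, 5, 2)
        with pytest.raises(ValueError):
            CARTRegressor(prune_rule="min_cv", n_cv_folds=10).fit(X, y)


class TestSubgroupExtraction:
    def test_root_leaf_yields_no_subgroup(self, rng):
        X, _ = random_table(rng, 40, 2)
        model = CARTRegressor().fit(X, np.ones(40))
        assert model.subgroups(1) == []

    def test_conjoined_rules_of_top_leaf(self):
        # two-variable staircase: top leaf = high x1 AND high x2
        gen = np.random.default_rng(3)
        X = pd.DataFrame({"glucose": gen.uniform(50, 250, 500),
                          "mass": gen.uniform(15, 50, 500)})
        y = ((X.glucose > 158) & (X.mass > 30)).astype(float)
        model = CARTRegressor(max_depth=3, min_split=10, min_leaf=5,
                              complexity_penalty=0.001).fit(X, y)
        boxes = model.subgroups(1)
        assert len(boxes) == 1
        rules = boxes[0].rules
        assert set(rules) == {"glucose", "mass"}
        assert rules["glucose"].lower == pytest.approx(158, abs=5)
        assert rules["mass"].lower == pytest.approx(30, abs=2)
        mask = boxes[0].membership(X)
        assert y[mask].mean() > 0.95

    def test_top_two_leaves_by_mean(self, rng):
        X = pd.DataFrame({"x1": rng.uniform(0, 4, 400)})
        y = np.floor(X.x1.to_numpy())  # 4 distinct plateaus
        model = CARTRegressor(max_depth=2, min_split=4, min_leaf=2,
                              complexity_penalty=0.0).fit(X, y)
        boxes = model.subgroups(2)
        assert len(boxes) == 2
        means = sorted(y[b.membership(X)].mean() for b in boxes)
        assert means == pytest.approx([2.0, 3.0], abs=0.2)

    def test_k_validation(self, rng):
        X, y = random_table(rng, 30, 2)
        model = CARTRegressor().fit(X, y)
        with pytest.raises(ValueError):
            extract_subgroups(model.tree_, 0, cols=model._cols)

    def test_max_depth_one_equals_best_stump(self, rng):
        X, y = random_table(rng, 50, 3)
        y = y + (X["x3"] > 0.1) * 2.0
        stump = grow_tree(X, y, TreeSettings(max_depth=1, min_split=2,
                                             min_leaf=7,
                                             complexity_penalty=0.0))
        dec, name, threshold = brute_force_root_split(X, y, min_leaf=7)
        assert stump.split_var == name
        assert stump.split_threshold == pytest.approx(threshold)
        assert stump.left.depth == 1 and stump.left.is_leaf
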