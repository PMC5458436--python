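"""A minimal CART: binary recursive partitioning with cost-complexity pruning.

Regression trees minimize the within-node residual sum of squares (RSS),
classification trees the Gini impurity (scaled by node size), both summed
over child nodes.  A node is split only while it has at least ``min_split``
observations, its depth is below ``max_depth``, both children would keep
``min_leaf`` observations, and the impurity decrease exceeds
``complexity_penalty`` times the root impurity.  Continuous split points are
midpoints between adjacent sorted distinct values; categorical splits scan
level subsets after ordering levels by mean outcome (regression) or by the
first-class proportion (classification), which is exact for RSS and binary
Gini.  Rows whose split variable is missing follow the larger child.

Pruning builds the nested weakest-link cost-complexity sequence and selects
a subtree by k-fold cross-validation, either at the error minimum or by the
one-standard-error rule.  A pruned tree may collapse to the root leaf —
the "no subgroup predicted" outcome.

The comparator exists to benchmark PRIM against recursive partitioning in
the Monte-Carlo study; subgroups are read off a fitted tree as the boxes of
its highest-mean leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from ._data import CATEGORICAL, CONTINUOUS, ColumnSet
from .box import Box, CategoricalRule, ContinuousRule
from .peeling import _as_frame

__all__ = [
    "TreeSettings",
    "TreeNode",
    "CARTRegressor",
    "CARTClassifier",
    "grow_tree",
    "prune_tree",
    "extract_subgroups",
]


@dataclass(frozen=True)
class TreeSettings:
    """Growth and pruning controls (defaults mirror common CART practice)."""

    max_depth: int = 30
    min_split: int = 20
    min_leaf: int = 7
    complexity_penalty: float = 0.01
    n_cv_folds: int = 10
    prune_rule: str = "none"  # {"none", "min_cv", "one_se"}
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.prune_rule not in ("none", "min_cv", "one_se"):
            raise ValueError(f"unknown prune_rule: {self.prune_rule!r}")


@dataclass
class TreeNode:
    """A node of a binary tree; a leaf has neither split nor children."""

    n: int
    value: object  # mean (regression) or class-proportion array
    impurity: float  # RSS, or n * Gini
    depth: int
    split_var: Optional[str] = None
    split_threshold: Optional[float] = None  # continuous split
    split_levels: Optional[frozenset] = None  # categorical: levels going left
    missing_left: bool = True  # majority routing for missing split values
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def n_leaves(self) -> int:
        return len(self.leaves())

    def subtree_impurity(self) -> float:
        return sum(leaf.impurity for leaf in self.leaves())

    def copy(self) -> "TreeNode":
        node = TreeNode(self.n, self.value, self.impurity, self.depth,
                        self.split_var, self.split_threshold,
                        self.split_levels, self.missing_left)
        if not self.is_leaf:
            node.left = self.left.copy()
            node.right = self.right.copy()
        return node

    def to_json(self) -> dict:
        out = {
            "n": self.n,
            "value": self.value if np.isscalar(self.value)
            else list(np.asarray(self.value, dtype=float)),
            "impurity": self.impurity,
            "depth": self.depth,
        }
        if not self.is_leaf:
            out["split"] = {
                "variable": self.split_var,
                "threshold": self.split_threshold,
                "levels": None if self.split_levels is None
                else sorted(self.split_levels, key=str),
                "missing_left": self.missing_left,
            }
            out["left"] = self.left.to_json()
            out["right"] = self.right.to_json()
        return out

    def format(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf n={self.n} value={_fmt_value(self.value)}\n"
        if self.split_threshold is not None:
            cond = f"{self.split_var} <= {self.split_threshold:.6g}"
        else:
            lv = ", ".join(map(str, sorted(self.split_levels, key=str)))
            cond = f"{self.split_var} in {{{lv}}}"
        return (f"{pad}node n={self.n} value={_fmt_value(self.value)} "
                f"split [{cond}]\n"
                + self.left.format(indent + 1) + self.right.format(indent + 1))


def _fmt_value(v):
    if np.isscalar(v):
        return f"{v:.6g}"
    return "[" + ", ".join(f"{x:.3g}" for x in np.asarray(v)) + "]"


# ---------------------------------------------------------------------------
# impurity helpers
# ---------------------------------------------------------------------------

def _node_stats_regression(y):
    n = y.size
    mean = float(y.mean())
    rss = float(((y - mean) ** 2).sum())
    return mean, rss


def _node_stats_classification(y_codes, n_classes):
    n = y_codes.size
    counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    props = counts / n
    gini_n = float(n - (counts ** 2).sum() / n)  # n * Gini index
    return props, gini_n


def _best_split_numeric(x, y_or_codes, min_leaf, task, n_classes):
    """Best threshold split on one numeric column (non-missing rows).

    Returns (decrease, threshold, left_mask_nonmiss) or None.  The decrease
    is relative to the impurity of the non-missing rows.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    if n < 2 * min_leaf or xs[0] == xs[-1]:
        return None
    valid = np.flatnonzero(xs[:-1] < xs[1:]) + 1  # split before position i
    valid = valid[(valid >= min_leaf) & (valid <= n - min_leaf)]
    if valid.size == 0:
        return None
    if task == "regression":
        ys = y_or_codes[order]
        csum = np.cumsum(ys)
        total = csum[-1]
        n_l = valid
        s_l = csum[valid - 1]
        # RSS decrease = S_l^2/n_l + S_r^2/n_r - S^2/n
        dec = s_l ** 2 / n_l + (total - s_l) ** 2 / (n - n_l) - total ** 2 / n
    else:
        codes = y_or_codes[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), codes] = 1.0
        ccum = np.cumsum(onehot, axis=0)
        totals = ccum[-1]
        n_l = valid.astype(float)
        c_l = ccum[valid - 1]
        c_r = totals - c_l
        imp_parent = n - (totals ** 2).sum() / n
        imp_l = n_l - (c_l ** 2).sum(axis=1) / n_l
        imp_r = (n - n_l) - (c_r ** 2).sum(axis=1) / (n - n_l)
        dec = imp_parent - imp_l - imp_r
    k = int(np.argmax(dec))
    i = valid[k]
    threshold = (xs[i - 1] + xs[i]) / 2.0
    return float(dec[k]), float(threshold), None


def _best_split_categorical(codes, y_or_codes, min_leaf, task, n_classes,
                            categories):
    """Best level-subset split on one categorical column (non-missing rows).

    Levels are ordered by outcome mean / first-class proportion and scanned
    like an ordered variable; exact for RSS and binary Gini.
    """
    present = np.unique(codes)
    if present.size < 2:
        return None
    if task == "regression":
        key = np.array([y_or_codes[codes == c].mean() for c in present])
    else:
        key = np.array([(y_or_codes[codes == c] == 0).mean() for c in present])
    level_order = present[np.argsort(key, kind="stable")]
    rank = np.empty(int(codes.max()) + 1, dtype=int)
    rank[level_order] = np.arange(level_order.size)
    x_ord = rank[codes].astype(float)
    res = _best_split_numeric(x_ord, y_or_codes, min_leaf, task, n_classes)
    if res is None:
        return None
    dec, threshold, _ = res
    left_levels = frozenset(categories[c] for c in
                            level_order[: int(math.floor(threshold)) + 1])
    return dec, left_levels


def _grow(cols: ColumnSet, rows: np.ndarray, y, task: str, n_classes: int,
          settings: TreeSettings, depth: int, root_impurity: float) -> TreeNode:
    if task == "regression":
        value, impurity = _node_stats_regression(y[rows])
    else:
        value, impurity = _node_stats_classification(y[rows], n_classes)
    node = TreeNode(n=rows.size, value=value, impurity=impurity, depth=depth)
    if (rows.size < settings.min_split or depth >= settings.max_depth
            or impurity <= 0):
        return node

    best = None  # (decrease, j, threshold, left_levels)
    for j in range(len(cols.names)):
        arr = cols.arrays[j][rows]
        if cols.kinds[j] == CONTINUOUS:
            nm = ~np.isnan(arr)
            if nm.sum() < 2 * settings.min_leaf:
                continue
            res = _best_split_numeric(arr[nm], y[rows][nm], settings.min_leaf,
                                      task, n_classes)
            if res is None:
                continue
            dec, threshold, _ = res
            cand = (dec, j, threshold, None)
        else:
            nm = arr != -1
            if nm.sum() < 2 * settings.min_leaf:
                continue
            res = _best_split_categorical(arr[nm], y[rows][nm],
                                          settings.min_leaf, task, n_classes,
                                          cols.categories[j])
            if res is None:
                continue
            dec, left_levels = res
            cand = (dec, j, None, left_levels)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        return node
    dec, j, threshold, left_levels = best
    if dec <= settings.complexity_penalty * root_impurity + 1e-12:
        return node

    arr = cols.arrays[j][rows]
    if threshold is not None:
        missing = np.isnan(arr)
        go_left = arr <= threshold
    else:
        missing = arr == -1
        cats = cols.categories[j]
        allowed = np.fromiter((c in left_levels for c in cats), dtype=bool,
                              count=len(cats))
        go_left = np.zeros(arr.size, dtype=bool)
        go_left[~missing] = allowed[arr[~missing]]
    n_left_nm = int(go_left[~missing].sum())
    n_right_nm = int((~missing).sum()) - n_left_nm
    missing_left = n_left_nm >= n_right_nm
    go_left = np.where(missing, missing_left, go_left)
    left_rows = rows[go_left]
    right_rows = rows[~go_left]
    if left_rows.size < settings.min_leaf or right_rows.size < settings.min_leaf:
        return node
    node.split_var = cols.names[j]
    node.split_threshold = threshold
    node.split_levels = left_levels
    node.missing_left = missing_left
    node.left = _grow(cols, left_rows, y, task, n_classes, settings,
                      depth + 1, root_impurity)
    node.right = _grow(cols, right_rows, y, task, n_classes, settings,
                       depth + 1, root_impurity)
    return node


def _route(node: TreeNode, cols: ColumnSet, rows: np.ndarray):
    """Yield (leaf, rows) pairs routing observations down the tree."""
    if node.is_leaf or rows.size == 0:
        yield node, rows
        return
    j = cols.names.index(node.split_var)
    arr = cols.arrays[j][rows]
    if node.split_threshold is not None:
        missing = np.isnan(arr)
        go_left = arr <= node.split_threshold
    else:
        missing = arr == -1
        cats = cols.categories[j]
        allowed = np.fromiter((c in node.split_levels for c in cats),
                              dtype=bool, count=len(cats))
        go_left = np.zeros(arr.size, dtype=bool)
        go_left[~missing] = allowed[arr[~missing]]
    go_left = np.where(missing, node.missing_left, go_left)
    yield from _route(node.left, cols, rows[go_left])
    yield from _route(node.right, cols, rows[~go_left])


def _predict(node: TreeNode, cols: ColumnSet, task: str) -> np.ndarray:
    rows = np.arange(cols.n)
    if task == "regression":
        out = np.empty(cols.n, dtype=float)
        for leaf, leaf_rows in _route(node, cols, rows):
            out[leaf_rows] = leaf.value
    else:
        out = np.empty(cols.n, dtype=int)
        for leaf, leaf_rows in _route(node, cols, rows):
            out[leaf_rows] = int(np.argmax(leaf.value))
    return out


# ---------------------------------------------------------------------------
# cost-complexity pruning
# ---------------------------------------------------------------------------

def _weakest_link_path(tree: TreeNode, root_impurity: float):
    """Nested subtree sequence: [(normalized alpha, subtree), ...].

    The first entry is the full tree at alpha 0; alphas increase and the
    last subtree is the root leaf.  Alphas are normalized by the root
    impurity (the cp scale), so they are comparable across trees.
    """
    scale = root_impurity if root_impurity > 0 else 1.0
    path = [(0.0, tree.copy())]
    current = tree.copy()
    while not current.is_leaf:
        # find the internal node with the weakest link
        best_g, best_node = None, None
        stack = [current]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            g = (node.impurity - node.subtree_impurity()) / (node.n_leaves() - 1)
            if best_g is None or g < best_g:
                best_g, best_node = g, node
            stack.extend([node.left, node.right])
        # collapse every node with link weight <= best_g (ties collapse together)
        def collapse(node):
            if node.is_leaf:
                return
            collapse(node.left)
            collapse(node.right)
            if not node.is_leaf:
                g = (node.impurity - node.subtree_impurity()) / (node.n_leaves() - 1)
                if g <= best_g + 1e-12:
                    node.left = node.right = None
                    node.split_var = None
                    node.split_threshold = None
                    node.split_levels = None
        collapse(current)
        path.append((best_g / scale, current.copy()))
    return path


def _prune_at(tree: TreeNode, alpha: float, root_impurity: float) -> TreeNode:
    """Smallest subtree optimal at normalized complexity ``alpha``."""
    path = _weakest_link_path(tree, root_impurity)
    chosen = path[0][1]
    for a, sub in path:
        if a <= alpha + 1e-12:
            chosen = sub
        else:
            break
    return chosen


def _cv_error(cols, y, task, n_classes, settings, cps, rng):
    """Cross-validated prediction error for each candidate cp."""
    n = cols.n
    folds = np.empty(n, dtype=int)
    if task == "classification":
        # stratified assignment per class
        for c in range(n_classes):
            rows = np.flatnonzero(y == c)
            rng.shuffle(rows)
            folds[rows] = np.arange(rows.size) % settings.n_cv_folds
    else:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % settings.n_cv_folds
    per_obs = np.zeros((len(cps), n))
    for fold in range(settings.n_cv_folds):
        test = folds == fold
        train_rows = np.flatnonzero(~test)
        test_rows = np.flatnonzero(test)
        sub = cols.take(train_rows)
        y_tr = y[train_rows]
        if task == "regression":
            _, root_imp = _node_stats_regression(y_tr)
        else:
            _, root_imp = _node_stats_classification(y_tr, n_classes)
        ftree = _grow(sub, np.arange(sub.n), y_tr, task, n_classes, settings,
                      0, root_imp)
        test_cols = cols.take(test_rows)
        path = _weakest_link_path(ftree, root_imp)
        path_alphas = [a for a, _ in path]
        pred_cache: dict[int, np.ndarray] = {}
        for ci, cp in enumerate(cps):
            pi = 0
            for k, a in enumerate(path_alphas):
                if a <= cp + 1e-12:
                    pi = k
                else:
                    break
            if pi not in pred_cache:
                pred_cache[pi] = _predict(path[pi][1], test_cols, task)
            pred = pred_cache[pi]
            if task == "regression":
                per_obs[ci, test_rows] = (y[test_rows] - pred) ** 2
            else:
                per_obs[ci, test_rows] = (y[test_rows] != pred).astype(float)
    err = per_obs.mean(axis=1)
    se = per_obs.std(axis=1, ddof=1) / math.sqrt(n)
    return err, se


def _prune_cv(tree: TreeNode, cols: ColumnSet, y, task: str, n_classes: int,
              settings: TreeSettings) -> TreeNode:
    if settings.n_cv_folds > cols.n:
        raise ValueError("n_cv_folds exceeds the number of observations")
    if tree.is_leaf:
        return tree.copy()
    root_imp = tree.impurity
    path = _weakest_link_path(tree, root_imp)
    alphas = [a for a, _ in path]
    # representative cps: geometric means of consecutive path alphas,
    # floored at the growing penalty (subtrees below it are never candidates)
    cps = []
    for a, b in zip(alphas, alphas[1:]):
        lo = max(a, 1e-10)
        hi = max(b, 1e-10)
        cps.append(max(math.sqrt(lo * hi), settings.complexity_penalty))
    # the root-leaf candidate: an unbounded penalty, so every fold tree
    # collapses fully and the no-split option competes on equal terms
    cps.append(math.inf)
    cps = sorted(set(cps))
    rng = np.random.default_rng(settings.seed)
    err, se = _cv_error(cols, y, task, n_classes, settings, cps, rng)
    # exact CV-error ties resolve to the larger cp (the smaller subtree)
    k_min = int(np.flatnonzero(err == err.min()).max())
    if settings.prune_rule == "one_se":
        limit = err[k_min] + se[k_min]
        candidates = [k for k in range(len(cps)) if err[k] <= limit]
        k_min = max(candidates)  # larger cp = smaller subtree
    return _prune_at(tree, cps[k_min], root_imp)


# ---------------------------------------------------------------------------
# subgroup extraction
# ---------------------------------------------------------------------------

def _leaf_boxes(node: TreeNode, cols: ColumnSet, rules: dict):
    if node.is_leaf:
        yield node, Box({k: v for k, v in rules.items()})
        return
    j = cols.names.index(node.split_var)
    name = node.split_var
    old = rules.get(name)
    if node.split_threshold is not None:
        lo = old.lower if old else -math.inf
        hi = old.upper if old else math.inf
        im = old.include_missing if old else False
        left_rule = ContinuousRule(lo, min(hi, node.split_threshold),
                                   node.missing_left and im if old else node.missing_left)
        right_rule = ContinuousRule(max(lo, node.split_threshold), hi,
                                    (not node.missing_left) and im if old else not node.missing_left)
    else:
        cats = set(cols.categories[j])
        allowed = set(old.levels) if old is not None and \
            isinstance(old, CategoricalRule) else cats
        left_levels = allowed & set(node.split_levels)
        right_levels = allowed - set(node.split_levels)
        im = old.include_missing if old else True
        left_rule = CategoricalRule(frozenset(left_levels) or frozenset(),
                                    node.missing_left and im) \
            if left_levels or (node.missing_left and im) else None
        right_rule = CategoricalRule(frozenset(right_levels) or frozenset(),
                                     (not node.missing_left) and im) \
            if right_levels or ((not node.missing_left) and im) else None
    for rule, child in ((left_rule, node.left), (right_rule, node.right)):
        new_rules = dict(rules)
        if rule is not None:
            new_rules[name] = rule
        yield from _leaf_boxes(child, cols, new_rules)


def extract_subgroups(tree: TreeNode, k: int, cols: ColumnSet | None = None,
                      feature_names=None) -> list[Box]:
    """Boxes of the k highest-mean leaves; [] when the tree is a root leaf.

    For classification trees, leaves are ranked by the proportion of the
    last class (the "positive" class for 0/1 outcomes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tree.is_leaf:
        return []
    if cols is None:
        # build a minimal ColumnSet shim carrying only names/kinds
        names = list(feature_names)
        cols = ColumnSet(names, [CONTINUOUS] * len(names),
                         [np.zeros(0)] * len(names), [None] * len(names))
    pairs = list(_leaf_boxes(tree, cols, {}))
    def leaf_key(leaf):
        v = leaf.value
        return float(v) if np.isscalar(v) else float(np.asarray(v)[-1])
    pairs.sort(key=lambda p: leaf_key(p[0]), reverse=True)
    return [box for _, box in pairs[:k]]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseCART(BaseEstimator):
    _task = "regression"

    def __init__(self, max_depth=30, min_split=20, min_leaf=7,
                 complexity_penalty=0.01, n_cv_folds=10, prune_rule="none",
                 random_state=None):
        self.max_depth = max_depth
        self.min_split = min_split
        self.min_leaf = min_leaf
        self.complexity_penalty = complexity_penalty
        self.n_cv_folds = n_cv_folds
        self.prune_rule = prune_rule
        self.random_state = random_state

    def _settings(self) -> TreeSettings:
        return TreeSettings(max_depth=self.max_depth, min_split=self.min_split,
                            min_leaf=self.min_leaf,
                            complexity_penalty=self.complexity_penalty,
                            n_cv_folds=self.n_cv_folds,
                            prune_rule=self.prune_rule,
                            seed=self.random_state)

    def fit(self, X, y):
        X = _as_frame(X)
        settings = self._settings()
        cols = ColumnSet.from_frame(X)
        if self._task == "regression":
            y = np.asarray(y, dtype=float).ravel()
            n_classes = 0
            _, root_imp = _node_stats_regression(y)
            y_int = y
        else:
            y = np.asarray(y).ravel()
            self.classes_, y_int = np.unique(y, return_inverse=True)
            n_classes = len(self.classes_)
            _, root_imp = _node_stats_classification(y_int, n_classes)
        if len(X) == 0:
            raise ValueError("empty training data")
        tree = _grow(cols, np.arange(cols.n), y_int, self._task, n_classes,
                     settings, 0, root_imp)
        if settings.prune_rule != "none":
            tree = _prune_cv(tree, cols, y_int, self._task, n_classes,
                             settings)
        self.tree_ = tree
        self._cols = cols
        self._n_classes = n_classes
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _predict_raw(self, X):
        if not hasattr(self, "tree_"):
            raise AttributeError("estimator is not fitted yet")
        X = _as_frame(X)
        cols = ColumnSet.from_frame(
            X, column_types={n: k for n, k in zip(self._cols.names,
                                                  self._cols.kinds)})
        # align categorical codes with the training categories
        for j, kind in enumerate(cols.kinds):
            if kind == CATEGORICAL:
                train_cats = self._cols.categories[j]
                remap = {lv: i for i, lv in enumerate(train_cats)}
                new = np.full(cols.n, -1, dtype=np.int64)
                codes = cols.arrays[j]
                cats = cols.categories[j]
                for c, lv in enumerate(cats):
                    if lv in remap:
                        new[codes == c] = remap[lv]
                cols.arrays[j] = new
                cols.categories[j] = train_cats
        return _predict(self.tree_, cols, self._task)

    def subgroups(self, k: int = 1) -> list[Box]:
        """Boxes of the k highest-mean (or positive-class) leaves."""
        return extract_subgroups(self.tree_, k, cols=self._cols)


class CARTRegressor(_BaseCART, RegressorMixin):
    """Regression tree (RSS impurity) with optional CV cost-complexity pruning."""

    _task = "regression"

    def predict(self, X):
        return self._predict_raw(X)


class CARTClassifier(_BaseCART, ClassifierMixin):
    """Classification tree (Gini impurity) with optional CV pruning."""

    _task = "classification"

    def predict(self, X):
        return self.classes_[self._predict_raw(X)]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def grow_tree(X, y, settings: TreeSettings = TreeSettings(),
              task: str = "regression") -> TreeNode:
    """Grow a tree and return its root node."""
    X = _as_frame(X)
    cols = ColumnSet.from_frame(X)
    if task == "regression":
        y = np.asarray(y, dtype=float).ravel()
        _, root_imp = _node_stats_regression(y)
        n_classes = 0
        y_int = y
    elif task == "classification":
        _, y_int = np.unique(np.asarray(y).ravel(), return_inverse=True)
        n_classes = int(y_int.max()) + 1
        _, root_imp = _node_stats_classification(y_int, n_classes)
    else:
        raise ValueError(f"unknown task: {task!r}")
    return _grow(cols, np.arange(cols.n), y_int, task, n_classes, settings,
                 0, root_imp)


def prune_tree(tree: TreeNode, X, y,
               settings: TreeSettings = TreeSettings(prune_rule="min_cv"),
               task: str = "regression") -> TreeNode:
    """Cross-validated cost-complexity pruning of a grown tree."""
    X = _as_frame(X)
    cols = ColumnSet.from_frame(X)
    if task == "regression":
        y_int = np.asarray(y, dtype=float).ravel()
        n_classes = 0
    else:
        _, y_int = np.unique(np.asarray(y).ravel(), return_inverse=True)
        n_classes = int(y_int.max()) + 1
    return _prune_cv(tree, cols, y_int, task, n_classes, settings)
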