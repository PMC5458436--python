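"""Internal column-oriented view of a data table for the search inner loops.

Continuous columns are float arrays with NaN for missing; categorical columns
are integer code arrays (-1 = missing) plus the level list.  Built once per
fit from a pandas DataFrame and indexed with numpy throughout peeling,
pasting and tree growing.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .box import Box, CategoricalRule, ContinuousRule

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class ColumnSet:
    def __init__(self, names, kinds, arrays, categories):
        self.names = list(names)
        self.kinds = list(kinds)
        self.arrays = list(arrays)
        self.categories = list(categories)
        self.n = len(arrays[0]) if arrays else 0

    @classmethod
    def from_frame(cls, X: pd.DataFrame, column_types: dict | None = None) -> "ColumnSet":
        names, kinds, arrays, categories = [], [], [], []
        column_types = column_types or {}
        for name in X.columns:
            col = X[name]
            declared = column_types.get(name)
            is_cont = (
                declared == CONTINUOUS
                if declared
                else pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype)
            )
            names.append(str(name))
            if is_cont:
                kinds.append(CONTINUOUS)
                arrays.append(pd.to_numeric(col, errors="raise").to_numpy(dtype=float))
                categories.append(None)
            else:
                kinds.append(CATEGORICAL)
                cat = pd.Categorical(col)
                arrays.append(cat.codes.astype(np.int64))  # -1 == missing
                categories.append(list(cat.categories))
        return cls(names, kinds, arrays, categories)

    def take(self, idx: np.ndarray) -> "ColumnSet":
        """Row subset / resample (used for covering and bootstrap runs)."""
        return ColumnSet(
            self.names,
            self.kinds,
            [a[idx] for a in self.arrays],
            self.categories,
        )

    def rule_mask(self, rules: dict, skip: str | None = None) -> np.ndarray:
        """Membership mask of a rule map on this column set."""
        mask = np.ones(self.n, dtype=bool)
        for name, rule in rules.items():
            if name == skip:
                continue
            j = self.names.index(name)
            arr = self.arrays[j]
            if isinstance(rule, ContinuousRule):
                missing = np.isnan(arr)
                ok = (arr >= rule.lower) & (arr <= rule.upper)
            else:
                missing = arr == -1
                cats = self.categories[j]
                allowed = np.fromiter(
                    (c in rule.levels for c in cats), dtype=bool, count=len(cats)
                )
                ok = np.zeros(self.n, dtype=bool)
                valid = ~missing
                ok[valid] = allowed[arr[valid]]
            mask &= np.where(missing, rule.include_missing, ok)
        return mask


def box_from_rules(rules: dict) -> Box:
    """Snapshot a mutable rule map into an immutable Box."""
    return Box(dict(rules))


def tighten_continuous(rules: dict, name: str, lower=None, upper=None,
                       include_missing=None) -> None:
    old = rules.get(name)
    lo = old.lower if old else -math.inf
    hi = old.upper if old else math.inf
    im = old.include_missing if old else True
    if lower is not None:
        lo = lower
    if upper is not None:
        hi = upper
    if include_missing is not None:
        im = include_missing
    rules[name] = ContinuousRule(lo, hi, im)


def set_categorical(rules: dict, name: str, levels, include_missing: bool) -> None:
    rules[name] = CategoricalRule(frozenset(levels), include_missing)
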