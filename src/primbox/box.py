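"""Boxes (axis-aligned rule sets) and decision lists.

A box is PRIM's representation of a subgroup: a conjunction of per-variable
rules — a closed interval ``[lower, upper]`` for a continuous variable, a set
of allowed levels for a categorical one.  Each rule also records whether
missing values of that variable belong to the box (missing values are treated
as one extra category, so the algorithm can peel or paste them as a block).
A variable without a rule imposes no restriction; the initial box of a
peeling run therefore has an empty rule map and contains every observation.

An ordered sequence of boxes together with a default value for the uncovered
remainder acts as a decision list: a new observation is predicted by the box
target of the first box in the list that contains it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousRule",
    "CategoricalRule",
    "Box",
    "DecisionList",
    "box_contains",
    "box_support",
    "decision_list_predict",
]


@dataclass(frozen=True)
class ContinuousRule:
    """Closed interval rule lower <= x <= upper (bounds may be infinite)."""

    lower: float = -math.inf
    upper: float = math.inf
    include_missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", float(self.lower))
        object.__setattr__(self, "upper", float(self.upper))
        if not self.lower <= self.upper:
            raise ValueError(f"lower bound {self.lower} exceeds upper bound {self.upper}")

    def to_json(self) -> dict:
        return {
            "type": "continuous",
            "lower": None if self.lower == -math.inf else self.lower,
            "upper": None if self.upper == math.inf else self.upper,
            "include_missing": self.include_missing,
        }


@dataclass(frozen=True)
class CategoricalRule:
    """Level-subset rule: x must be one of ``levels`` (or missing if allowed)."""

    levels: frozenset = field(default_factory=frozenset)
    include_missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", frozenset(self.levels))
        if not self.levels and not self.include_missing:
            raise ValueError("categorical rule must allow at least one level or missing")

    def to_json(self) -> dict:
        return {
            "type": "categorical",
            "levels": sorted(self.levels, key=str),
            "include_missing": self.include_missing,
        }


Rule = Union[ContinuousRule, CategoricalRule]


class Box:
    """A conjunction of per-variable rules; variables without rules are free."""

    def __init__(self, rules: dict[str, Rule] | None = None) -> None:
        self.rules: dict[str, Rule] = dict(rules) if rules else {}

    def __eq__(self, other) -> bool:
        return isinstance(other, Box) and self.rules == other.rules

    def __repr__(self) -> str:
        if not self.rules:
            return "Box(<all data>)"
        parts = []
        for name, rule in self.rules.items():
            if isinstance(rule, ContinuousRule):
                parts.append(f"{rule.lower:.4g} <= {name} <= {rule.upper:.4g}")
                if rule.include_missing:
                    parts[-1] += " (or missing)"
            else:
                lv = ", ".join(map(str, sorted(rule.levels, key=str)))
                parts.append(f"{name} in {{{lv}}}")
                if rule.include_missing:
                    parts[-1] += " (or missing)"
        return "Box(" + "; ".join(parts) + ")"

    # -- membership ---------------------------------------------------------

    def contains(self, row) -> bool:
        """True iff the observation satisfies every rule of the box."""
        for name, rule in self.rules.items():
            try:
                value = row[name]
            except (KeyError, IndexError) as exc:
                raise KeyError(f"ruled variable {name!r} absent from the row") from exc
            missing = value is None or (isinstance(value, float) and math.isnan(value))
            if missing:
                if not rule.include_missing:
                    return False
                continue
            if isinstance(rule, ContinuousRule):
                if not (rule.lower <= float(value) <= rule.upper):
                    return False
            else:
                if value not in rule.levels:
                    return False
        return True

    def membership(self, X: pd.DataFrame) -> np.ndarray:
        """Vectorized membership mask over a data table."""
        mask = np.ones(len(X), dtype=bool)
        for name, rule in self.rules.items():
            if name not in X.columns:
                raise KeyError(f"ruled variable {name!r} absent from the data")
            col = X[name]
            missing = col.isna().to_numpy()
            if isinstance(rule, ContinuousRule):
                vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                ok = (vals >= rule.lower) & (vals <= rule.upper)
            else:
                ok = col.isin(list(rule.levels)).to_numpy()
            ok = np.where(missing, rule.include_missing, ok)
            mask &= ok
        return mask

    def support(self, X: pd.DataFrame) -> float:
        """Fraction of the observations of ``X`` contained in the box."""
        if len(X) == 0:
            raise ValueError("support is undefined on an empty data table")
        return float(self.membership(X).mean())

    # -- (de)serialization --------------------------------------------------

    def to_json(self) -> dict:
        return {name: rule.to_json() for name, rule in self.rules.items()}

    @classmethod
    def from_json(cls, obj: dict) -> "Box":
        rules: dict[str, Rule] = {}
        for name, spec in obj.items():
            if spec["type"] == "continuous":
                rules[name] = ContinuousRule(
                    lower=-math.inf if spec["lower"] is None else float(spec["lower"]),
                    upper=math.inf if spec["upper"] is None else float(spec["upper"]),
                    include_missing=bool(spec.get("include_missing", False)),
                )
            else:
                rules[name] = CategoricalRule(
                    levels=frozenset(spec["levels"]),
                    include_missing=bool(spec.get("include_missing", False)),
                )
        return cls(rules)

    def dumps(self) -> str:
        return json.dumps(self.to_json(), sort_keys=True)


class DecisionList:
    """Ordered boxes with their training targets plus a default value.

    Prediction for an observation is the box target of the first box in the
    list containing it; observations outside all boxes get ``default_value``.
    """

    def __init__(self, boxes, default_value: float) -> None:
        # boxes: sequence of (Box, target, support)
        self.boxes = [(b, float(t), float(s)) for b, t, s in boxes]
        for _, _, s in self.boxes:
            if not 0 < s <= 1:
                raise ValueError("box supports must lie in (0, 1]")
        self.default_value = float(default_value)

    def __len__(self) -> int:
        return len(self.boxes)

    def predict_row(self, row) -> float:
        for box, target, _ in self.boxes:
            if box.contains(row):
                return target
        return self.default_value

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.default_value, dtype=float)
        unassigned = np.ones(len(X), dtype=bool)
        for box, target, _ in self.boxes:
            hit = box.membership(X) & unassigned
            out[hit] = target
            unassigned &= ~hit
        return out

    def to_json(self) -> dict:
        return {
            "boxes": [
                {"rules": b.to_json(), "target": t, "support": s}
                for b, t, s in self.boxes
            ],
            "default_value": self.default_value,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DecisionList":
        boxes = [
            (Box.from_json(item["rules"]), item["target"], item["support"])
            for item in obj["boxes"]
        ]
        return cls(boxes, obj["default_value"])

    def dumps(self) -> str:
        return json.dumps(self.to_json(), sort_keys=True)


# -- thin functional wrappers ------------------------------------------------

def box_contains(box: Box, row) -> bool:
    return box.contains(row)


def box_support(box: Box, X: pd.DataFrame) -> float:
    return box.support(X)


def decision_list_predict(dl: DecisionList, row) -> float:
    return dl.predict_row(row)
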