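"""Target (objective) functions evaluated on the observations inside a box.

PRIM maximizes a target function ``f`` over box-shaped regions.  Two targets
are supported:

* ``mean`` — the arithmetic mean of a quantitative (or 0/1 coded binary)
  outcome, f(y) = (1/n) * sum(y_i);
* ``hazard`` — a constant-hazard estimate for right-censored survival
  outcomes, f(t, delta) = sum(delta_i) / sum(t_i), i.e. events per unit of
  observed time.

Minimization is realized by sign-flipping the outcome (mean target only) and
back-transforming reported box values; there is no accepted definition of a
sign flip for a hazard rate, so ``hazard`` + ``minimize`` is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmptyBoxError",
    "TargetSpec",
    "SurvivalOutcome",
    "mean_target",
    "hazard_target",
    "apply_direction",
]


class EmptyBoxError(ValueError):
    """A target function was evaluated on an empty box."""


@dataclass(frozen=True)
class TargetSpec:
    """Which target function to use and in which direction to optimize."""

    kind: str = "mean"  # {"mean", "hazard"}
    direction: str = "maximize"  # {"maximize", "minimize"}

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "hazard"):
            raise ValueError(f"unknown target kind: {self.kind!r}")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        if self.kind == "hazard" and self.direction == "minimize":
            raise ValueError(
                "minimization is not defined for the hazard target; "
                "only mean targets support direction='minimize'"
            )


class SurvivalOutcome:
    """A right-censored survival outcome: times t_i > 0 and event flags.

    Parameters
    ----------
    time : array-like of positive floats
        Observed time (event or censoring time) per observation.
    event : array-like of {0, 1}
        1 if the event occurred at ``time``, 0 if censored.
    """

    def __init__(self, time, event) -> None:
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        if time.ndim != 1 or event.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if time.size and not np.all(time > 0):
            raise ValueError("all survival times must be strictly positive")
        if not np.all(np.isin(event, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")
        self.time = time
        self.event = event.astype(int)

    def __len__(self) -> int:
        return self.time.size

    def __getitem__(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SurvivalOutcome(n={len(self)}, "
            f"events={int(self.event.sum())})"
        )


def mean_target(y) -> float:
    """Arithmetic-mean target: sum(y_i) / n on the in-box observations."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise EmptyBoxError("mean target evaluated on an empty box")
    if np.isnan(y).any():
        raise ValueError("mean target requires an outcome without missing values")
    return float(y.sum() / y.size)


def hazard_target(s: SurvivalOutcome) -> float:
    """Constant-hazard target: total events / total observed time.

    Zero events in a box is a valid hazard of 0.0 (not an error); the
    denominator is always positive because survival times are.
    """
    if not isinstance(s, SurvivalOutcome):
        raise TypeError("hazard target requires a SurvivalOutcome")
    if len(s) == 0:
        raise EmptyBoxError("hazard target evaluated on an empty box")
    return float(s.event.sum() / s.time.sum())


def apply_direction(y, spec: TargetSpec):
    """Transform the outcome so the search can always maximize.

    Returns ``y`` unchanged for ``maximize`` and ``-y`` for ``minimize``
    (mean target only).  Callers must back-transform reported box targets
    (negate them) when minimizing.
    """
    if spec.direction == "maximize":
        return y
    if spec.kind != "mean":
        raise ValueError("direction='minimize' is only supported for the mean target")
    return -np.asarray(y, dtype=float)


def target_ratio_arrays(y, spec: TargetSpec):
    """Internal: express the target as a ratio sum(num)/sum(den) per subset.

    mean  -> num = y (sign-flipped for minimize), den = 1
    hazard-> num = event, den = time

    Both PRIM targets have this form, which lets the peeling inner loop
    evaluate candidates from running sums.
    """
    if spec.kind == "mean":
        num = np.asarray(apply_direction(y, spec), dtype=float)
        den = np.ones_like(num)
    else:
        if not isinstance(y, SurvivalOutcome):
            raise TypeError("hazard target requires a SurvivalOutcome")
        num = y.event.astype(float)
        den = y.time.astype(float)
    if np.isnan(num).any() or np.isnan(den).any():
        raise ValueError("outcome contains missing values")
    return num, den


def back_transform(value: float, spec: TargetSpec) -> float:
    """Map an internally maximized target value back to the original scale."""
    if spec.direction == "minimize":
        return -value
    return value
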