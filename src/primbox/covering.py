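"""Covering: sequential multi-box search assembling a decision list.

After a box is accepted, the observations it contains are removed and the
whole multiple-peeling search is re-run on the remainder, so each box is
found on data the earlier boxes do not cover.  Only observations are
removed, never regions, so later boxes may geometrically overlap earlier
ones; prediction resolves the overlap by list order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._data import ColumnSet
from .box import DecisionList
from .peeling import _as_frame
from .targets import TargetSpec, back_transform, target_ratio_arrays
from .trajectory import (
    MultiPeelSettings,
    _multiple_peel_internal,
    dominance_filter,
    select_box_fmin,
    select_box_opt_beta,
)

__all__ = ["StopCriteria", "cover"]


@dataclass(frozen=True)
class StopCriteria:
    """When to stop adding boxes to the decision list.

    At least one of the three criteria must be set.  ``min_target`` and
    ``min_support`` are checked on the data the candidate box was found on
    (the current, reduced search set).
    """

    max_boxes: Optional[int] = None
    min_target: Optional[float] = None
    min_support: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_boxes is None and self.min_target is None \
                and self.min_support is None:
            raise ValueError("at least one stop criterion must be provided")
        if self.max_boxes is not None and self.max_boxes < 1:
            raise ValueError("max_boxes must be >= 1")


def _select(points, policy: str, param: float):
    if policy == "opt_beta":
        return select_box_opt_beta(points, param)
    if policy == "fmin":
        return select_box_fmin(points, param)
    raise ValueError(f"unknown selection policy: {policy!r}")


def _cover_internal(cols: ColumnSet, num: np.ndarray, den: np.ndarray,
                    settings: MultiPeelSettings, policy: str,
                    policy_param: float, stop: StopCriteria,
                    target: TargetSpec):
    remaining = np.arange(cols.n)
    boxes = []
    rounds = []
    while True:
        if stop.max_boxes is not None and len(boxes) >= stop.max_boxes:
            break
        n_rem = remaining.size
        if n_rem < max(2, math.ceil(settings.beta_min * n_rem)):
            break
        sub_cols = cols.take(remaining)
        sub_num, sub_den = num[remaining], den[remaining]
        points = _multiple_peel_internal(sub_cols, sub_num, sub_den, settings)
        front = dominance_filter(points)
        chosen = _select(front, policy, policy_param)
        rounds.append({"points": points, "front": front, "selected": chosen})
        if chosen is None:
            break
        # when settings.paste is set, trajectory boxes are already pasted
        box, tgt, sup = chosen.box, chosen.target, chosen.support
        if stop.min_target is not None and tgt < stop.min_target:
            break
        if stop.min_support is not None and sup < stop.min_support:
            break
        boxes.append((box, back_transform(tgt, target), sup))
        covered = sub_cols.rule_mask(box.rules)
        remaining = remaining[~covered]
        if remaining.size == 0:
            break
    if remaining.size:
        default = float(num[remaining].sum() / den[remaining].sum())
    else:
        default = float(num.sum() / den.sum())
    dl = DecisionList(boxes, back_transform(default, target))
    return dl, rounds


def cover(X, y, settings: MultiPeelSettings, policy: str, policy_param: float,
          stop: StopCriteria, target: TargetSpec = TargetSpec()) -> DecisionList:
    """Iterated box search; returns the fitted decision list.

    Each round runs multiple peeling on the not-yet-covered observations,
    dominance-filters the pooled trajectory, applies the selection policy
    (``"opt_beta"`` with a support floor or ``"fmin"`` with a target floor)
    and, when ``settings.paste`` is set, pastes the accepted box.  Box
    targets/supports are recorded relative to the data they were found on.
    """
    X = _as_frame(X)
    if len(X) == 0:
        raise ValueError("covering requires a non-empty data table")
    cols = ColumnSet.from_frame(X)
    num, den = target_ratio_arrays(y, target)
    dl, _ = _cover_internal(cols, num, den, settings, policy, policy_param,
                            stop, target)
    return dl
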