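"""Multiple peeling over an alpha grid, bumping, dominance filtering and
box selection policies.

A single peeling trajectory depends on the peeling fraction alpha and on the
noise in the sample.  Multiple peeling stabilizes the picture by pooling the
trajectories of (a) several alpha values and (b) optional bootstrap resamples
("bumping").  Boxes found on a bootstrap sample are re-evaluated on the
original data before pooling, so all (target, support) pairs are comparable.
Dominance filtering then discards every box that another box beats in target
without being smaller, or beats in support without a lower target — the
remaining points form the Pareto front from which a user (or an automatic
policy) picks the final box.

Two selection policies mirror contrasting styles of user involvement:

* ``select_box_opt_beta`` — the user knows the true subgroup size and takes
  the highest-target box among those with at least that support;
* ``select_box_fmin`` — the user insists on a minimum box target and takes
  the largest-support box achieving it, possibly concluding that no subgroup
  exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._data import ColumnSet, box_from_rules
from .peeling import (
    PeelSettings,
    TrajectoryPoint,
    _paste_sequence_internal,
    _peel_sequence_internal,
    _as_frame,
)
from .targets import TargetSpec, target_ratio_arrays

__all__ = [
    "MultiPeelSettings",
    "multiple_peel",
    "dominance_filter",
    "select_box_opt_beta",
    "select_box_fmin",
    "trajectory_frame",
    "plot_trajectory",
]

_EPS = 1e-12


@dataclass(frozen=True)
class MultiPeelSettings:
    """Metaparameters of a multiple-peeling run.

    alphas : strictly increasing peeling fractions, each in (0, 0.5].
    n_bootstrap : bootstrap resamples per alpha (0 disables bumping).
    beta_min : minimum box support.
    seed : seed for the bootstrap resampling streams.
    paste : whether to paste every trajectory box before pooling.
    alpha_paste : pasting fraction.
    paste_lookahead : declining paste steps tolerated before stopping.
    """

    alphas: Sequence[float] = (0.05,)
    n_bootstrap: int = 0
    beta_min: float = 0.1
    seed: Optional[int] = None
    paste: bool = False
    alpha_paste: float = 0.01
    paste_lookahead: int = 0

    def __post_init__(self) -> None:
        alphas = tuple(float(a) for a in self.alphas)
        object.__setattr__(self, "alphas", alphas)
        if not alphas:
            raise ValueError("alphas must be non-empty")
        if any(not 0 < a <= 0.5 for a in alphas):
            raise ValueError("every alpha must lie in (0, 0.5]")
        if any(b <= a for a, b in zip(alphas, alphas[1:])) or \
                len(set(alphas)) != len(alphas):
            raise ValueError("alphas must be strictly increasing without duplicates")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be non-negative")
        if not 0 < self.beta_min <= 1:
            raise ValueError("beta_min must lie in (0, 1]")

    def peel_settings(self, alpha: float) -> PeelSettings:
        return PeelSettings(alpha=alpha, beta_min=self.beta_min,
                            alpha_paste=self.alpha_paste,
                            paste_lookahead=self.paste_lookahead)


def _multiple_peel_internal(cols: ColumnSet, num: np.ndarray, den: np.ndarray,
                            settings: MultiPeelSettings) -> list[TrajectoryPoint]:
    """Pooled trajectory on a ColumnSet; supports/targets on that data."""
    rng_seq = np.random.SeedSequence(
        settings.seed if settings.seed is not None else 0
    )
    n = cols.n
    points: list[TrajectoryPoint] = []
    order = 0
    for alpha in settings.alphas:
        runs = [(None, cols, num, den)]
        if settings.n_bootstrap:
            children = rng_seq.spawn(settings.n_bootstrap)
            for b, child in enumerate(children, start=1):
                rng = np.random.default_rng(child)
                take = rng.integers(0, n, size=n)
                runs.append((b, cols.take(take), num[take], den[take]))
        for boot_id, run_cols, run_num, run_den, in runs:
            ps = settings.peel_settings(alpha)
            traj, _ = _peel_sequence_internal(run_cols, run_num, run_den, ps)
            for p in traj:
                if boot_id is not None:
                    # re-evaluate the box on the original data
                    mask = cols.rule_mask(p.box.rules)
                    size = int(mask.sum())
                    if size == 0 or np.sum(den[mask]) <= 0:
                        continue
                    p.support = size / n
                    p.target = float(num[mask].sum() / den[mask].sum())
                    if p.support < settings.beta_min - _EPS:
                        continue
                if settings.paste:
                    rules, tgt, sup = _paste_sequence_internal(
                        cols, num, den, dict(p.box.rules),
                        settings.peel_settings(alpha))
                    p.box = box_from_rules(rules)
                    p.target, p.support = tgt, sup
                p.alpha = alpha
                p.bootstrap_id = boot_id
                p.order = order
                order += 1
                points.append(p)
    return points


def multiple_peel(X, y, settings: MultiPeelSettings,
                  target: TargetSpec = TargetSpec()) -> list[TrajectoryPoint]:
    """Pool peeling trajectories over the alpha grid and bootstrap resamples.

    All supports and targets of the returned points refer to the original
    data, also for boxes found on bootstrap resamples.
    """
    X = _as_frame(X)
    if len(X) == 0:
        raise ValueError("multiple peeling requires a non-empty data table")
    cols = ColumnSet.from_frame(X)
    num, den = target_ratio_arrays(y, target)
    return _multiple_peel_internal(cols, num, den, settings)


def dominance_filter(points: list[TrajectoryPoint]) -> list[TrajectoryPoint]:
    """Keep the Pareto front over (target, support).

    A point is dominated when another point has target >= its target with
    strictly larger support, or strictly larger target with support >= its
    support.  Among exact (target, support) duplicates the earliest point in
    pooling order is kept.
    """
    if not points:
        return []
    f = np.array([p.target for p in points])
    b = np.array([p.support for p in points])
    # sort by support desc, target desc, original position asc
    pos = np.arange(len(points))
    order = np.lexsort((pos, -f, -b))
    keep: list[int] = []
    best_f_larger_b = -np.inf  # max target among strictly larger supports
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and b[order[j]] == b[order[i]]:
            j += 1
        group = order[i:j]
        group_max = f[group].max()
        if group_max > best_f_larger_b:
            # keep earliest-pooled point among duplicates of the group max
            winners = group[f[group] == group_max]
            keep.append(int(winners[pos[winners].argmin()]))
        best_f_larger_b = max(best_f_larger_b, group_max)
        i = j
    keep.sort()
    return [points[i] for i in keep]


def select_box_opt_beta(points: list[TrajectoryPoint],
                        beta_true: float) -> Optional[TrajectoryPoint]:
    """Highest-target box among those with support >= ``beta_true``.

    Ties prefer larger support, then earlier pooling order.  The all-data
    box always qualifies, so a result exists whenever the pool contains it.
    """
    if not 0 < beta_true <= 1:
        raise ValueError("beta_true must lie in (0, 1]")
    best = None
    for p in points:
        if p.support < beta_true - _EPS:
            continue
        if best is None or p.target > best.target or (
                p.target == best.target and p.support > best.support):
            best = p
    return best


def select_box_fmin(points: list[TrajectoryPoint],
                    f_min: float) -> Optional[TrajectoryPoint]:
    """Largest-support box among those with target >= ``f_min``.

    Returns None when no box reaches the requested target — the
    "no subgroup predicted" outcome.  Ties prefer the higher target.
    """
    best = None
    for p in points:
        if p.target < f_min:
            continue
        if best is None or p.support > best.support or (
                p.support == best.support and p.target > best.target):
            best = p
    return best


def trajectory_frame(points: list[TrajectoryPoint]) -> pd.DataFrame:
    """Tidy table of a (pooled) trajectory for export or plotting."""
    return pd.DataFrame({
        "step": [p.step_index for p in points],
        "alpha": [p.alpha for p in points],
        "bootstrap_id": [p.bootstrap_id for p in points],
        "support": [p.support for p in points],
        "target": [p.target for p in points],
    })


def plot_trajectory(points: list[TrajectoryPoint], ax=None):
    """Support-vs-target scatter with dominated points dimmed."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    front = dominance_filter(points)
    front_ids = {id(p) for p in front}
    if ax is None:
        _, ax = plt.subplots()
    dom = [p for p in points if id(p) not in front_ids]
    if dom:
        ax.scatter([p.support for p in dom], [p.target for p in dom],
                   s=8, c="lightsteelblue", label="dominated")
    ax.scatter([p.support for p in front], [p.target for p in front],
               s=18, c="crimson", label="Pareto front")
    ax.set_xlabel("box support $\\beta$")
    ax.set_ylabel("box target $f$")
    ax.legend(loc="best")
    return ax
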