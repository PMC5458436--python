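"""Top-down peeling and bottom-up pasting of a single box.

Peeling starts from the box containing all observations and repeatedly removes
a small marginal fraction (a candidate subbox): for every continuous variable
the ``ceil(alpha * n_box)`` smallest or largest in-box values, for every
categorical variable one level, and, when missing values are present inside
the box, the whole missing category of a variable.  Among all candidates the
one maximizing the target on the remaining observations is removed.  The
sequence stops before the box support would fall below ``beta_min``, so every
recorded box keeps at least that share of the data.

Pasting is the reverse move applied to a finished box: candidate subboxes
(the nearest ``ceil(alpha_paste * n_box)`` outside observations beyond one
bound, or one excluded level) are re-admitted as long as the in-box target
does not decline, optionally looking a few declining steps ahead and keeping
the best box seen.  Peeling decisions are greedy and conditional on earlier
steps, so pasting can recover support (and sometimes target) lost to a
locally optimal peel.

Quantile convention: a continuous candidate removes exactly the
``ceil(alpha * n_box)`` most extreme in-box observations (stable order, ties
broken by row position), which guarantees every peel removes at least one and
at most ``ceil(alpha * n_box)`` observations even under heavy ties.  After a
peel the new closed bound sits at the most extreme retained value, so printed
rules describe the retained data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ._data import (
    CATEGORICAL,
    CONTINUOUS,
    ColumnSet,
    box_from_rules,
    set_categorical,
    tighten_continuous,
)
from .box import Box, CategoricalRule, ContinuousRule
from .targets import TargetSpec, target_ratio_arrays

__all__ = [
    "PeelSettings",
    "TrajectoryPoint",
    "candidate_subboxes",
    "peel_step",
    "peel_sequence",
    "paste_candidates",
    "paste_sequence",
]


@dataclass(frozen=True)
class PeelSettings:
    """Metaparameters of one peel/paste run.

    alpha : peeling fraction in (0, 0.5]; small values (0.05-0.1) make the
        search "patient".
    beta_min : minimum box support in (0, 1]; peeling never records a box
        below this share of the data.
    alpha_paste : pasting fraction in (0, 0.5].
    paste_lookahead : number of declining paste steps to tolerate before
        stopping (the best box seen is returned).
    """

    alpha: float = 0.05
    beta_min: float = 0.1
    alpha_paste: float = 0.01
    paste_lookahead: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 0.5]")
        if not 0 < self.alpha_paste <= 0.5:
            raise ValueError("alpha_paste must lie in (0, 0.5]")
        if not 0 < self.beta_min <= 1:
            raise ValueError("beta_min must lie in (0, 1]")
        if self.paste_lookahead < 0:
            raise ValueError("paste_lookahead must be non-negative")


@dataclass
class TrajectoryPoint:
    """One box of a peeling sequence with its support/target trade-off.

    Support and target always refer to the data the trajectory is reported
    on (the original sample, also for boxes found on bootstrap resamples).
    """

    box: Box
    support: float
    target: float
    step_index: int
    alpha: Optional[float] = None
    bootstrap_id: Optional[int] = None
    order: int = field(default=0, compare=False)  # pooling/provenance order


@dataclass
class _Candidate:
    """A removable (peel) or admittable (paste) subbox."""

    variable: str
    move: str  # "lower" | "upper" | "level" | "missing"
    level: object = None
    rows: np.ndarray = None  # local positions (peel) / global rows (paste)
    apply_rule: Callable[[dict], None] = None


# ---------------------------------------------------------------------------
# peeling internals (ColumnSet based)
# ---------------------------------------------------------------------------

def _peel_candidates(cols: ColumnSet, idx: np.ndarray, rules: dict,
                     alpha: float) -> list[_Candidate]:
    n_box = idx.size
    k = math.ceil(alpha * n_box)
    out: list[_Candidate] = []
    for j, name in enumerate(cols.names):
        arr = cols.arrays[j]
        vals = arr[idx]
        if cols.kinds[j] == CONTINUOUS:
            miss = np.isnan(vals)
            n_miss = int(miss.sum())
            pos = np.flatnonzero(~miss)
            v = vals[pos]
            has_missing_inside = n_miss > 0
            if v.size > k and v.min() < v.max():
                order = np.argsort(v, kind="stable")
                low_rows = pos[order[:k]]
                new_lower = float(v[order[k]])
                out.append(_Candidate(
                    name, "lower", rows=low_rows,
                    apply_rule=_mk_cont_update(name, lower=new_lower,
                                               default_im=has_missing_inside),
                ))
                high_rows = pos[order[-k:]]
                new_upper = float(v[order[-k - 1]])
                out.append(_Candidate(
                    name, "upper", rows=high_rows,
                    apply_rule=_mk_cont_update(name, upper=new_upper,
                                               default_im=has_missing_inside),
                ))
            if 0 < n_miss < n_box:
                out.append(_Candidate(
                    name, "missing", rows=np.flatnonzero(miss),
                    apply_rule=_mk_cont_update(name, include_missing=False,
                                               default_im=False),
                ))
        else:
            miss = vals == -1
            n_miss = int(miss.sum())
            cats = cols.categories[j]
            present = np.unique(vals[~miss]) if n_miss < n_box else np.array([], int)
            rule = rules.get(name)
            allowed = set(rule.levels) if rule is not None else {
                cats[c] for c in present
            }
            has_missing_inside = n_miss > 0
            for c in present:  # categories are in sorted order
                rows = np.flatnonzero(vals == c)
                if rows.size == n_box:
                    continue  # would empty the box
                level = cats[c]
                new_levels = allowed - {level}
                im = rule.include_missing if rule is not None else has_missing_inside
                if not new_levels and not im:
                    continue
                out.append(_Candidate(
                    name, "level", level=level, rows=rows,
                    apply_rule=_mk_cat_update(name, frozenset(new_levels), im),
                ))
            if 0 < n_miss < n_box:
                im_levels = frozenset(allowed)
                out.append(_Candidate(
                    name, "missing", rows=np.flatnonzero(miss),
                    apply_rule=_mk_cat_update(name, im_levels, False),
                ))
    return out


def _mk_cont_update(name, lower=None, upper=None, include_missing=None,
                    default_im=False):
    def update(rules: dict) -> None:
        if name not in rules:
            tighten_continuous(rules, name, include_missing=default_im)
        tighten_continuous(rules, name, lower=lower, upper=upper,
                           include_missing=include_missing)
    return update


def _mk_cat_update(name, levels, include_missing):
    def update(rules: dict) -> None:
        set_categorical(rules, name, levels, include_missing)
    return update


def _best_candidate(cands, num_in, den_in):
    """Pick the candidate maximizing the post-removal ratio target."""
    if not cands:
        return None
    s_num = num_in.sum()
    s_den = den_in.sum()
    best, best_val = None, -np.inf
    for cand in cands:
        den_rem = s_den - den_in[cand.rows].sum()
        if den_rem <= 0:
            continue
        val = (s_num - num_in[cand.rows].sum()) / den_rem
        if val > best_val:  # strict: ties keep the earlier candidate
            best, best_val = cand, val
    return best


def _peel_sequence_internal(cols: ColumnSet, num: np.ndarray, den: np.ndarray,
                            settings: PeelSettings):
    """Run one peeling sequence; returns (points, final rule map)."""
    n = cols.n
    idx = np.arange(n)
    rules: dict = {}
    points: list[TrajectoryPoint] = []
    target = float(num.sum() / den.sum())
    points.append(TrajectoryPoint(box_from_rules(rules), 1.0, target, 0))
    step = 0
    while True:
        num_in = num[idx]
        den_in = den[idx]
        cands = _peel_candidates(cols, idx, rules, settings.alpha)
        cand = _best_candidate(cands, num_in, den_in)
        if cand is None:
            break
        new_size = idx.size - cand.rows.size
        if new_size / n < settings.beta_min - 1e-12:
            break  # the step would undershoot the support floor
        keep = np.ones(idx.size, dtype=bool)
        keep[cand.rows] = False
        idx = idx[keep]
        cand.apply_rule(rules)
        step += 1
        target = float(num[idx].sum() / den[idx].sum())
        points.append(TrajectoryPoint(box_from_rules(rules), idx.size / n,
                                      target, step))
    return points, rules


# ---------------------------------------------------------------------------
# pasting internals
# ---------------------------------------------------------------------------

def _paste_candidates_internal(cols: ColumnSet, rules: dict,
                               in_mask: np.ndarray,
                               alpha_paste: float) -> list[_Candidate]:
    n_box = int(in_mask.sum())
    m = math.ceil(alpha_paste * n_box)
    out: list[_Candidate] = []
    for name in list(rules):
        rule = rules[name]
        j = cols.names.index(name)
        arr = cols.arrays[j]
        others = cols.rule_mask(rules, skip=name) & ~in_mask
        if isinstance(rule, ContinuousRule):
            nonmiss = ~np.isnan(arr)
            if rule.lower > -math.inf:
                pool = np.flatnonzero(others & nonmiss & (arr < rule.lower)
                                      & (arr <= rule.upper))
                if pool.size:
                    take = pool[np.argsort(-arr[pool], kind="stable")][:m]
                    new_lower = float(arr[take].min())
                    out.append(_Candidate(
                        name, "lower", rows=take,
                        apply_rule=_mk_cont_update(name, lower=new_lower),
                    ))
            if rule.upper < math.inf:
                pool = np.flatnonzero(others & nonmiss & (arr > rule.upper)
                                      & (arr >= rule.lower))
                if pool.size:
                    take = pool[np.argsort(arr[pool], kind="stable")][:m]
                    new_upper = float(arr[take].max())
                    out.append(_Candidate(
                        name, "upper", rows=take,
                        apply_rule=_mk_cont_update(name, upper=new_upper),
                    ))
            if not rule.include_missing:
                pool = np.flatnonzero(others & np.isnan(arr))
                if pool.size:
                    out.append(_Candidate(
                        name, "missing", rows=pool,
                        apply_rule=_mk_cont_update(name, include_missing=True),
                    ))
        else:
            cats = cols.categories[j]
            excluded = [lv for lv in cats if lv not in rule.levels]
            for level in excluded:
                code = cats.index(level)
                pool = np.flatnonzero(others & (arr == code))
                if pool.size:
                    new_levels = frozenset(rule.levels | {level})
                    out.append(_Candidate(
                        name, "level", level=level, rows=pool,
                        apply_rule=_mk_cat_update(name, new_levels,
                                                  rule.include_missing),
                    ))
            if not rule.include_missing:
                pool = np.flatnonzero(others & (arr == -1))
                if pool.size:
                    out.append(_Candidate(
                        name, "missing", rows=pool,
                        apply_rule=_mk_cat_update(name, rule.levels, True),
                    ))
    return out


def _paste_sequence_internal(cols: ColumnSet, num: np.ndarray, den: np.ndarray,
                             rules: dict, settings: PeelSettings):
    """Greedy pasting with lookahead; returns (best rule map, target, support)."""
    rules = dict(rules)
    in_mask = cols.rule_mask(rules)
    if not in_mask.any():
        raise ValueError("paste started from a box containing no observations")
    s_num = float(num[in_mask].sum())
    s_den = float(den[in_mask].sum())
    cur_target = s_num / s_den
    cur_support = in_mask.mean()
    best = (dict(rules), cur_target, float(cur_support))
    declines = 0
    while True:
        cands = _paste_candidates_internal(cols, rules, in_mask,
                                           settings.alpha_paste)
        if not cands:
            break
        pick, pick_val = None, -np.inf
        for cand in cands:
            val = (s_num + num[cand.rows].sum()) / (s_den + den[cand.rows].sum())
            if val > pick_val:
                pick, pick_val = cand, float(val)
        if pick_val < cur_target:
            if declines >= settings.paste_lookahead:
                break
            declines += 1
        else:
            declines = 0
        in_mask = in_mask.copy()
        in_mask[pick.rows] = True
        pick.apply_rule(rules)
        s_num += float(num[pick.rows].sum())
        s_den += float(den[pick.rows].sum())
        cur_target = s_num / s_den
        cur_support = float(in_mask.mean())
        if cur_target > best[1] or (cur_target == best[1]
                                    and cur_support > best[2]):
            best = (dict(rules), cur_target, cur_support)
            declines = 0
    return best


# ---------------------------------------------------------------------------
# public DataFrame-level operations
# ---------------------------------------------------------------------------

def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])


def candidate_subboxes(box: Box, X_in, alpha: float) -> list[_Candidate]:
    """Enumerate the removable subboxes of a box given its in-box data.

    ``X_in`` must contain exactly the observations currently inside the box.
    Candidate ``rows`` index into ``X_in``.  Candidates that would remove
    zero or all in-box observations are dropped.
    """
    X_in = _as_frame(X_in)
    if len(X_in) == 0:
        raise ValueError("candidate enumeration requires a non-empty box")
    cols = ColumnSet.from_frame(X_in)
    return _peel_candidates(cols, np.arange(cols.n), dict(box.rules), alpha)


def peel_step(box: Box, X, y, alpha: float,
              target: TargetSpec = TargetSpec()):
    """One peeling step: returns (new box, chosen candidate) or None."""
    X = _as_frame(X)
    num, den = target_ratio_arrays(y, target)
    inside = box.membership(X)
    if not inside.any():
        raise ValueError("peel_step requires a box with positive support")
    X_in = X.loc[inside]
    cands = candidate_subboxes(box, X_in, alpha)
    cand = _best_candidate(cands, num[inside], den[inside])
    if cand is None:
        return None
    rules = dict(box.rules)
    cand.apply_rule(rules)
    return box_from_rules(rules), cand


def peel_sequence(X, y, settings: PeelSettings,
                  target: TargetSpec = TargetSpec()) -> list[TrajectoryPoint]:
    """Full peeling sequence from the all-data box down to ``beta_min``."""
    X = _as_frame(X)
    if len(X) == 0:
        raise ValueError("peeling requires a non-empty data table")
    cols = ColumnSet.from_frame(X)
    num, den = target_ratio_arrays(y, target)
    points, _ = _peel_sequence_internal(cols, num, den, settings)
    for p in points:
        p.alpha = settings.alpha
    return points


def paste_candidates(box: Box, X, alpha_paste: float) -> list[_Candidate]:
    """Enumerate the admittable subboxes of a box; ``rows`` index into X."""
    X = _as_frame(X)
    cols = ColumnSet.from_frame(X)
    in_mask = cols.rule_mask(dict(box.rules))
    return _paste_candidates_internal(cols, dict(box.rules), in_mask,
                                      alpha_paste)


def paste_sequence(box: Box, X, y, settings: PeelSettings,
                   target: TargetSpec = TargetSpec()) -> Box:
    """Paste a peeled box outward; never returns a lower-target box."""
    X = _as_frame(X)
    cols = ColumnSet.from_frame(X)
    num, den = target_ratio_arrays(y, target)
    rules, _, _ = _paste_sequence_internal(cols, num, den, dict(box.rules),
                                           settings)
    return box_from_rules(rules)
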