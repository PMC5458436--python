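"""Monte-Carlo study engine: data generator, evaluation, and method grid.

The data-generating process: six independent covariates X1..X6 ~ U(-1, 1);
one or two axis-aligned square subgroups defined on (X1, X2) only; outcome
y ~ N(mu, 1) with mu = delta inside a true subgroup and 0 elsewhere, so
delta equals the signal-to-noise ratio.  Square layouts:

* ``one_center``  — one square centered at the origin;
* ``one_margin``  — one square anchored in the (+1, +1) corner;
* ``two_center``  — two equal disjoint squares centered at (-1/2, -1/2) and
  (+1/2, +1/2) (diagonal, chessboard-like placement);
* ``two_margin``  — two equal squares anchored in the (-1, -1) and (+1, +1)
  corners.

Predicted subgroups are scored on an independent test sample by comparing
predicted box membership with true membership: sensitivity, specificity and
Youden's J = Sens + Spec - 1 (0 for a random classifier, 1 for a perfect
one).

Four method variants are compared, mirroring two styles of PRIM user
involvement and two CART configurations:

* ``prim_opt_beta`` — PRIM, highest box mean subject to the (known) true
  per-box support;
* ``prim_fmin``     — PRIM, largest support subject to box mean >= 2, with
  beta_min = 7/n; may predict no subgroup;
* ``cart_maxdepth`` — depth-limited regression tree (depth 4/8 centered,
  2/4 margin layouts for one/two subgroups);
* ``cart_pruned``   — depth-30 tree pruned to the minimum 10-fold
  cross-validated error; may collapse to the root leaf.

Both PRIM variants use the alpha grid {0.01, 0.02, ..., 0.5} without
bootstrap resampling, and covering limited to the true number of subgroups.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .box import Box, ContinuousRule
from .prim import PRIM
from .tree import CARTRegressor

__all__ = [
    "SimulationDesign",
    "EvalResult",
    "true_boxes",
    "simulate_dataset",
    "evaluate_prediction",
    "run_method",
    "run_study",
    "aggregate_study",
    "DELTA_GRID",
    "PRIM_ALPHA_GRID",
]

DELTA_GRID = (0.0, 0.33, 0.67, 1.0, 1.33, 1.67, 2.0, 2.33, 2.67, 3.0)
PRIM_ALPHA_GRID = tuple(np.round(np.arange(1, 51) * 0.01, 2))
LAYOUTS = ("one_center", "one_margin", "two_center", "two_margin")
METHODS = ("prim_opt_beta", "prim_fmin", "cart_maxdepth", "cart_pruned")

_COLUMNS = [f"X{j}" for j in range(1, 7)]


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the study grid.

    ``beta`` is the support of EACH true subgroup (so the total covered
    share is ``2 * beta`` for two-subgroup layouts).
    """

    n: int = 250
    delta: float = 1.0
    beta: float = 0.20
    layout: str = "one_center"
    p: int = 6
    sigma: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout: {self.layout!r}")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")

    @property
    def n_subgroups(self) -> int:
        return 2 if self.layout.startswith("two") else 1


def _square(x_lo, x_hi, y_lo, y_hi) -> Box:
    return Box({
        "X1": ContinuousRule(x_lo, x_hi),
        "X2": ContinuousRule(y_lo, y_hi),
    })


def true_boxes(design: SimulationDesign) -> list[Box]:
    """Axis-aligned true subgroup squares on (X1, X2).

    Each square's area fraction of [-1, 1]^2 equals ``design.beta``, so its
    side length is 2 * sqrt(beta).
    """
    side = 2.0 * math.sqrt(design.beta)
    h = side / 2.0
    if design.layout == "one_center":
        return [_square(-h, h, -h, h)]
    if design.layout == "one_margin":
        return [_square(1 - side, 1, 1 - side, 1)]
    if side > 1.0:
        raise ValueError(
            "two-subgroup squares must fit in one quadrant "
            f"(per-box support {design.beta} is too large)")
    if design.layout == "two_center":
        return [
            _square(-0.5 - h, -0.5 + h, -0.5 - h, -0.5 + h),
            _square(0.5 - h, 0.5 + h, 0.5 - h, 0.5 + h),
        ]
    # two_margin
    return [
        _square(-1, -1 + side, -1, -1 + side),
        _square(1 - side, 1, 1 - side, 1),
    ]


def _membership_union(boxes: Sequence[Box], X: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(X), dtype=bool)
    for box in boxes:
        mask |= box.membership(X)
    return mask


def simulate_dataset(design: SimulationDesign, n_obs: Optional[int] = None,
                     rng=None):
    """Draw (X, y, truth) from the design's data-generating process."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = design.n if n_obs is None else int(n_obs)
    X = pd.DataFrame(rng.uniform(-1.0, 1.0, size=(n, design.p)),
                     columns=_COLUMNS[: design.p])
    truth = _membership_union(true_boxes(design), X)
    mu = np.where(truth, design.delta, 0.0)
    y = rng.normal(mu, design.sigma)
    return X, y, truth


@dataclass
class EvalResult:
    """Test-set agreement between predicted and true subgroup membership."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_json(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
        }


def evaluate_prediction(predicted: Sequence[Box], design: SimulationDesign,
                        n_test: int = 10_000, seed=None) -> EvalResult:
    """Score predicted boxes against the true ones on a fresh test sample."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(-1.0, 1.0, size=(n_test, design.p)),
                     columns=_COLUMNS[: design.p])
    truth = _membership_union(true_boxes(design), X)
    pred = _membership_union(predicted, X)
    tp = int((truth & pred).sum())
    fn = int((truth & ~pred).sum())
    fp = int((~truth & pred).sum())
    tn = int((~truth & ~pred).sum())
    return EvalResult(tp, fn, fp, tn)


def _cart_max_depth(design: SimulationDesign) -> int:
    if design.layout == "one_center":
        return 4
    if design.layout == "two_center":
        return 8
    if design.layout == "one_margin":
        return 2
    return 4  # two_margin


def run_method(X, y, method: str, design: SimulationDesign,
               seed=None) -> list[Box]:
    """Fit one configured method and return its predicted boxes (0, 1 or 2)."""
    k = design.n_subgroups
    n = len(X)
    if method == "prim_opt_beta":
        model = PRIM(alphas=PRIM_ALPHA_GRID, beta_min=design.beta,
                     n_bootstrap=0, selector="opt_beta",
                     beta_true=design.beta, max_boxes=k)
        model.fit(X, y)
        return model.boxes_
    if method == "prim_fmin":
        model = PRIM(alphas=PRIM_ALPHA_GRID, beta_min=7.0 / n,
                     n_bootstrap=0, selector="fmin", f_min=2.0, max_boxes=k)
        model.fit(X, y)
        return model.boxes_
    if method == "cart_maxdepth":
        model = CARTRegressor(max_depth=_cart_max_depth(design),
                              min_split=20, min_leaf=7,
                              complexity_penalty=0.01, prune_rule="none")
        model.fit(X, y)
        return model.subgroups(k)
    if method == "cart_pruned":
        model = CARTRegressor(max_depth=30, min_split=20, min_leaf=7,
                              complexity_penalty=0.01, n_cv_folds=10,
                              prune_rule="min_cv", random_state=seed)
        model.fit(X, y)
        return model.subgroups(k)
    raise ValueError(f"unknown method: {method!r}")


def _rep_rng(master_seed: int, cell_key: tuple, rep: int):
    """Independent, reproducible stream per (cell, replicate)."""
    digest = zlib.crc32(repr(cell_key).encode()) % (2 ** 31)
    ss = np.random.SeedSequence([int(master_seed) % (2 ** 31), digest, rep])
    return np.random.default_rng(ss), int(ss.generate_state(1)[0] % (2 ** 31))


def run_study(designs: Sequence[SimulationDesign],
              methods: Sequence[str] = METHODS,
              deltas: Sequence[float] = DELTA_GRID,
              n_reps: int = 250, seed: int = 0,
              n_test: int = 10_000) -> pd.DataFrame:
    """Run the full method-comparison grid; returns one tidy row per
    (design, delta, method, replicate)."""
    rows = []
    for design in designs:
        for delta in deltas:
            cell_design = SimulationDesign(
                n=design.n, delta=float(delta), beta=design.beta,
                layout=design.layout, p=design.p, sigma=design.sigma)
            for rep in range(n_reps):
                cell_key = (design.n, design.layout, round(design.beta, 6),
                            round(float(delta), 6))
                rng, sub_seed = _rep_rng(seed, cell_key, rep)
                X, y, _ = simulate_dataset(cell_design, rng=rng)
                for method in methods:
                    boxes = run_method(X, y, method, cell_design,
                                       seed=sub_seed)
                    res = evaluate_prediction(boxes, cell_design,
                                              n_test=n_test,
                                              seed=sub_seed + 1)
                    rows.append({
                        "n": design.n, "layout": design.layout,
                        "beta": design.beta, "delta": float(delta),
                        "method": method, "rep": rep,
                        "detected": int(len(boxes) > 0),
                        "sens": res.sensitivity, "spec": res.specificity,
                        "j": res.youden_j,
                    })
    return pd.DataFrame(rows)


def aggregate_study(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell detection proportion and median/IQR of Sens, Spec and J."""
    def q25(s):
        return s.quantile(0.25)

    def q75(s):
        return s.quantile(0.75)

    agg = results.groupby(["n", "layout", "beta", "delta", "method"]).agg(
        detected=("detected", "mean"),
        sens_median=("sens", "median"), sens_q25=("sens", q25),
        sens_q75=("sens", q75),
        spec_median=("spec", "median"), spec_q25=("spec", q25),
        spec_q75=("spec", q75),
        j_median=("j", "median"), j_q25=("j", q25), j_q75=("j", q75),
        n_reps=("rep", "count"),
    ).reset_index()
    return agg
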