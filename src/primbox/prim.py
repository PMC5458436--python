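"""The PRIM estimator: peeling/pasting box search with a sklearn interface.

``PRIM`` searches covariate space for axis-aligned boxes in which the outcome
target (mean, or hazard rate for survival outcomes) is outstanding, using
multiple peeling over an alpha grid, optional bootstrap bumping, dominance
filtering, a box-selection policy, optional pasting, and covering for more
than one box.  The fitted model is a decision list and predicts the box
target of the first box containing an observation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._data import ColumnSet
from .covering import StopCriteria, _cover_internal
from .peeling import _as_frame
from .targets import SurvivalOutcome, TargetSpec, target_ratio_arrays
from .trajectory import MultiPeelSettings

__all__ = ["PRIM"]


class PRIM(BaseEstimator, RegressorMixin):
    """Patient Rule Induction Method subgroup search.

    Parameters
    ----------
    alphas : sequence of float, default (0.05,)
        Peeling fractions; a strictly increasing grid in (0, 0.5].  Pooling
        several values stabilizes the trajectory.
    beta_min : float, default 0.1
        Minimum box support; peeling stops before undershooting it.
    n_bootstrap : int, default 0
        Bootstrap resamples per alpha ("bumping"); boxes are re-evaluated on
        the original data before pooling.
    selector : {"opt_beta", "fmin"}, default "opt_beta"
        Box selection policy on the dominance-filtered trajectory:
        highest target subject to a support floor, or largest support
        subject to a target floor.
    beta_true : float, optional
        Support floor of the "opt_beta" policy; defaults to ``beta_min``.
    f_min : float, optional
        Target floor of the "fmin" policy (required for that policy).
    max_boxes : int, default 1
        Number of boxes sought via covering.
    min_target, min_support : float, optional
        Additional covering stop criteria, checked on the reduced search data.
    paste : bool, default False
        Paste each accepted box (and trajectory boxes) outward.
    alpha_paste : float, default 0.01
        Pasting fraction.
    paste_lookahead : int, default 0
        Declining paste steps tolerated before stopping.
    target : {"mean", "hazard"}, default "mean"
        Target function; "hazard" expects a ``SurvivalOutcome`` (or a
        2-column time/event array) as ``y``.
    direction : {"maximize", "minimize"}, default "maximize"
        Minimization sign-flips the outcome internally (mean target only);
        reported box targets are back-transformed.  Selector floors refer to
        the original outcome scale with flipped inequality semantics, i.e.
        ``f_min`` acts as an upper bound when minimizing.
    random_state : int, optional
        Seed of the bootstrap streams.

    Attributes
    ----------
    decision_list_ : DecisionList
        Ordered boxes with targets/supports and the default value.
    boxes_ : list of Box
        The accepted boxes in covering order (possibly empty).
    trajectory_ : list of TrajectoryPoint
        Pooled trajectory of the first covering round.
    front_ : list of TrajectoryPoint
        Its dominance-filtered Pareto front.
    n_features_in_, feature_names_in_ : sklearn-standard input metadata.
    """

    def __init__(self, alphas: Sequence[float] = (0.05,), beta_min: float = 0.1,
                 n_bootstrap: int = 0, selector: str = "opt_beta",
                 beta_true: Optional[float] = None, f_min: Optional[float] = None,
                 max_boxes: int = 1, min_target: Optional[float] = None,
                 min_support: Optional[float] = None, paste: bool = False,
                 alpha_paste: float = 0.01, paste_lookahead: int = 0,
                 target: str = "mean", direction: str = "maximize",
                 random_state: Optional[int] = None) -> None:
        self.alphas = alphas
        self.beta_min = beta_min
        self.n_bootstrap = n_bootstrap
        self.selector = selector
        self.beta_true = beta_true
        self.f_min = f_min
        self.max_boxes = max_boxes
        self.min_target = min_target
        self.min_support = min_support
        self.paste = paste
        self.alpha_paste = alpha_paste
        self.paste_lookahead = paste_lookahead
        self.target = target
        self.direction = direction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _coerce_y(self, y):
        if self.target == "hazard":
            if isinstance(y, SurvivalOutcome):
                return y
            arr = np.asarray(y, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(
                    "hazard target expects a SurvivalOutcome or an (n, 2) "
                    "array of (time, event)")
            return SurvivalOutcome(arr[:, 0], arr[:, 1])
        return np.asarray(y, dtype=float).ravel()

    def fit(self, X, y):
        X = _as_frame(X)
        y = self._coerce_y(y)
        if len(X) != (len(y) if not isinstance(y, SurvivalOutcome) else len(y)):
            raise ValueError("X and y have inconsistent lengths")
        spec = TargetSpec(kind=self.target, direction=self.direction)
        settings = MultiPeelSettings(
            alphas=tuple(self.alphas), n_bootstrap=self.n_bootstrap,
            beta_min=self.beta_min, seed=self.random_state,
            paste=self.paste, alpha_paste=self.alpha_paste,
            paste_lookahead=self.paste_lookahead)
        if self.selector == "opt_beta":
            policy_param = self.beta_true if self.beta_true is not None \
                else self.beta_min
        elif self.selector == "fmin":
            if self.f_min is None:
                raise ValueError("selector='fmin' requires f_min")
            policy_param = self.f_min
            if self.direction == "minimize":
                policy_param = -policy_param
        else:
            raise ValueError(f"unknown selector: {self.selector!r}")
        stop = StopCriteria(max_boxes=self.max_boxes,
                            min_target=self.min_target,
                            min_support=self.min_support)
        cols = ColumnSet.from_frame(X)
        num, den = target_ratio_arrays(y, spec)
        dl, rounds = _cover_internal(cols, num, den, settings, self.selector,
                                     policy_param, stop, spec)
        self.decision_list_ = dl
        self.boxes_ = [b for b, _, _ in dl.boxes]
        self.trajectory_ = rounds[0]["points"] if rounds else []
        self.front_ = rounds[0]["front"] if rounds else []
        self.default_value_ = dl.default_value
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self._target_spec = spec
        return self

    def predict(self, X) -> np.ndarray:
        """Decision-list prediction: first containing box's target."""
        if not hasattr(self, "decision_list_"):
            raise AttributeError("PRIM instance is not fitted yet")
        return self.decision_list_.predict(_as_frame(X))

    def membership(self, X) -> np.ndarray:
        """Boolean mask: inside the union of the fitted boxes."""
        X = _as_frame(X)
        mask = np.zeros(len(X), dtype=bool)
        for box in self.boxes_:
            mask |= box.membership(X)
        return mask
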