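"""PRIM on right-censored survival outcomes via the constant-hazard target.

Under the assumption of time-constant risks, the events-per-time ratio
sum(delta_i) / sum(t_i) estimates the hazard rate of the observations inside
a box, so maximizing it finds subgroups at elevated risk.  Selection
policies, dominance filtering and covering apply unchanged; only the target
function differs.

A synthetic generator with exponential event times (different rates inside
and outside a planted box) and independent exponential censoring supports
parameter-recovery testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .box import Box, ContinuousRule
from .targets import SurvivalOutcome, TargetSpec
from .trajectory import MultiPeelSettings, TrajectoryPoint, multiple_peel

__all__ = [
    "prim_survival",
    "simulate_survival",
    "variable_inclusion_frequency",
]


def prim_survival(X, s: SurvivalOutcome,
                  settings: MultiPeelSettings) -> list[TrajectoryPoint]:
    """Multiple peeling with the hazard-rate target.

    Trajectory targets are hazard rates (events per time unit).  All-censored
    data is valid but yields an all-zero trajectory; a warning is emitted.
    """
    if not isinstance(s, SurvivalOutcome):
        raise TypeError("prim_survival requires a SurvivalOutcome")
    if s.event.sum() == 0:
        warnings.warn("all observations are censored: every box hazard is 0",
                      UserWarning, stacklevel=2)
    return multiple_peel(X, s, settings, target=TargetSpec(kind="hazard"))


def _censoring_rate_for(c: float, event_rates: np.ndarray) -> float:
    # P(censoring before event) for Exp(rate) event vs Exp(c) censoring
    return float(np.mean(c / (event_rates + c)))


def simulate_survival(n: int, hazard_in: float, hazard_out: float,
                      censor_rate: float, box: Box, seed=None, p: int = 6):
    """Synthetic survival data with a planted constant-hazard subgroup.

    Covariates are i.i.d. Uniform(-1, 1); event times are exponential with
    rate ``hazard_in`` inside ``box`` and ``hazard_out`` outside; censoring
    times are independent exponentials whose rate is solved numerically so
    the expected share of censored observations equals ``censor_rate``.

    Returns (X, SurvivalOutcome, truth mask).
    """
    if hazard_in <= 0 or hazard_out <= 0:
        raise ValueError("hazard rates must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(-1.0, 1.0, size=(n, p)),
                     columns=[f"X{j}" for j in range(1, p + 1)])
    truth = box.membership(X)
    rates = np.where(truth, hazard_in, hazard_out)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        return X, SurvivalOutcome(event_times, np.ones(n, dtype=int)), truth
    hi = 1e6 * max(hazard_in, hazard_out)
    c = brentq(lambda v: _censoring_rate_for(v, rates) - censor_rate,
               1e-12, hi)
    censor_times = rng.exponential(1.0 / c, size=n)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return X, SurvivalOutcome(time, event), truth


def variable_inclusion_frequency(points: list[TrajectoryPoint]) -> dict:
    """Share of (non-dominated) boxes whose rule map restricts each variable.

    For every variable appearing in any box, returns the proportions of boxes
    restricting it at all plus a split by bound side: a finite lower bound, a
    finite upper bound, or a level subset (categorical).  Interpreting the
    front as the user's menu of equally defensible boxes, these proportions
    estimate how likely each variable is to define the chosen subgroup.
    """
    n = len(points)
    out: dict[str, dict[str, float]] = {}
    if n == 0:
        return out
    for p in points:
        for name, rule in p.box.rules.items():
            entry = out.setdefault(
                name, {"any": 0.0, "lower": 0.0, "upper": 0.0, "levels": 0.0})
            entry["any"] += 1
            if isinstance(rule, ContinuousRule):
                if rule.lower > -np.inf:
                    entry["lower"] += 1
                if rule.upper < np.inf:
                    entry["upper"] += 1
            else:
                entry["levels"] += 1
    for entry in out.values():
        for key in entry:
            entry[key] /= n
    return out
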