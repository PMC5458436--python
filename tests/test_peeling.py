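import math

import numpy as np
import pandas as pd
import pytest

from primbox import (
    Box,
    ContinuousRule,
    PeelSettings,
    candidate_subboxes,
    paste_candidates,
    paste_sequence,
    peel_sequence,
    peel_step,
)
from primbox.simulate import SimulationDesign, simulate_dataset

from conftest import random_table


def brute_force_peel_choice(X, y, alpha):
    """Independent oracle: enumerate every candidate removal of the all-data
    box with plain Python and return the retained row set of the best one.

    Convention under test: a continuous candidate removes the
    ceil(alpha * n) smallest (stable by row order) or largest values; a
    categorical candidate removes one level; ties between candidates keep
    the earlier one in (column order, lower-before-upper, sorted levels).
    """
    n = len(X)
    k = math.ceil(alpha * n)
    candidates = []
    for name in X.columns:
        col = X[name]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.to_numpy()
            if len(set(vals)) < 2 or k >= n:
                continue
            order = sorted(range(n), key=lambda i: vals[i])  # stable
            candidates.append(set(order[:k]))
            candidates.append(set(order[n - k:]))
        else:
            for level in sorted(col.unique()):
                rows = set(np.flatnonzero((col == level).to_numpy()))
                if 0 < len(rows) < n:
                    candidates.append(rows)
    best_keep, best_val = None, -np.inf
    for removed in candidates:
        keep = [i for i in range(n) if i not in removed]
        val = sum(y[i] for i in keep) / len(keep)
        if val > best_val:
            best_keep, best_val = set(keep), val
    return best_keep, best_val


class TestCandidateEnumeration:
    def test_two_candidates_per_varying_continuous_variable(self, rng):
        X, _ = random_table(rng, 40, 6)
        cands = candidate_subboxes(Box(), X, alpha=0.1)
        assert len(cands) == 12

    def test_constant_variable_yields_no_candidates(self, rng):
        X, _ = random_table(rng, 30, 2)
        X["x2"] = 1.0
        cands = candidate_subboxes(Box(), X, alpha=0.1)
        assert {c.variable for c in cands} == {"x1"}

    def test_lower_candidate_removes_exactly_the_minimum(self):
        X = pd.DataFrame({"x1": np.arange(1.0, 11.0)})
        cands = candidate_subboxes(Box(), X, alpha=0.1)  # k = 1
        lower = next(c for c in cands if c.move == "lower")
        assert list(lower.rows) == [0]
        upper = next(c for c in cands if c.move == "upper")
        assert list(upper.rows) == [9]

    def test_missing_category_candidate(self, rng):
        X, _ = random_table(rng, 30, 2)
        X.loc[:4, "x1"] = np.nan
        cands = candidate_subboxes(Box(), X, alpha=0.1)
        missing = [c for c in cands if c.move == "missing"]
        assert len(missing) == 1
        assert set(missing[0].rows) == set(range(5))


class TestPeelStep:
    def test_monotone_signal_peels_the_low_tail(self, rng):
        X = pd.DataFrame({"x1": np.linspace(0, 1, 30)})
        y = X["x1"].to_numpy() * 2.0  # strictly increasing
        _, cand = peel_step(Box(), X, y, alpha=0.1)
        assert cand.variable == "x1" and cand.move == "lower"

    def test_tie_break_takes_first_candidate(self, rng):
        X, _ = random_table(rng, 20, 2)
        y = np.ones(20)  # all candidates tie
        _, cand = peel_step(Box(), X, y, alpha=0.1)
        assert cand.variable == "x1" and cand.move == "lower"

    def test_no_candidates_returns_none(self):
        X = pd.DataFrame({"x1": [1.0] * 5})
        assert peel_step(Box(), X, np.arange(5.0), alpha=0.2) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n_rows = int(gen.integers(10, 31))
        n_cols = int(gen.integers(1, 4))
        X, y = random_table(gen, n_rows, n_cols)
        alpha = float(gen.uniform(0.05, 0.4))
        oracle_keep, oracle_val = brute_force_peel_choice(X, y.to_numpy()
                                                          if hasattr(y, "to_numpy") else y,
                                                          alpha)
        _, cand = peel_step(Box(), X, y, alpha=alpha)
        kept = set(range(n_rows)) - set(int(i) for i in cand.rows)
        assert kept == oracle_keep
        assert np.mean([y[i] for i in kept]) == pytest.approx(oracle_val)


class TestPeelSequence:
    def test_beta_min_one_keeps_only_the_full_box(self, small_table):
        X, y = small_table
        points = peel_sequence(X, y, PeelSettings(alpha=0.1, beta_min=1.0))
        assert len(points) == 1
        assert points[0].support == 1.0
        assert points[0].box == Box()

    def test_supports_strictly_decrease(self, small_table):
        X, y = small_table
        points = peel_sequence(X, y, PeelSettings(alpha=0.1, beta_min=0.1))
        supports = [p.support for p in points]
        assert all(a > b for a, b in zip(supports, supports[1:]))

    def test_every_recorded_box_respects_the_support_floor(self, small_table):
        X, y = small_table
        beta_min = 0.15
        points = peel_sequence(X, y, PeelSettings(alpha=0.07,
                                                  beta_min=beta_min))
        assert all(p.support >= beta_min for p in points)

    def test_patient_peeling_with_wide_fraction(self, rng):
        # alpha=0.25, support floor 7.5%: the run should take roughly
        # log(0.075)/log(0.75) ~ 9 steps and stop just above the floor
        n = 200
        X = pd.DataFrame({"x1": rng.uniform(-10, 10, n),
                          "x2": rng.uniform(-10, 10, n)})
        y = ((np.abs(X["x1"]) < 5) & (np.abs(X["x2"]) < 5)).astype(float)
        points = peel_sequence(X, y.to_numpy(),
                               PeelSettings(alpha=0.25, beta_min=0.075))
        assert 8 <= len(points) <= 12
        assert points[-1].support >= 0.075
        # one more quarter peel would undershoot the floor
        n_last = round(points[-1].support * n)
        assert (n_last - math.ceil(0.25 * n_last)) / n < 0.075

    def test_removal_counts_bounded_even_with_ties(self, rng):
        n = 120
        X = pd.DataFrame({"x1": rng.integers(0, 5, n).astype(float),
                          "x2": rng.uniform(-1, 1, n)})
        y = rng.normal(size=n)
        alpha = 0.1
        points = peel_sequence(X, y, PeelSettings(alpha=alpha, beta_min=0.05))
        sizes = [round(p.support * n) for p in points]
        for n_box, n_next in zip(sizes, sizes[1:]):
            removed = n_box - n_next
            assert 1 <= removed <= math.ceil(alpha * n_box)

    def test_rules_describe_retained_data(self, rng):
        X, y = random_table(rng, 80, 2)
        points = peel_sequence(X, y, PeelSettings(alpha=0.1, beta_min=0.2))
        final = points[-1]
        inside = final.box.membership(X)
        assert inside.mean() == pytest.approx(final.support)
        assert y[inside].mean() == pytest.approx(final.target)


class TestPasteCandidates:
    def test_full_range_box_has_no_candidates(self, rng):
        X, _ = random_table(rng, 30, 2)
        assert paste_candidates(Box(), X, 0.1) == []

    def test_upper_candidate_admits_nearest_outside_points(self):
        X = pd.DataFrame({"x1": np.arange(20.0)})
        box = Box({"x1": ContinuousRule(0.0, 9.0)})  # 10 rows outside above
        cands = paste_candidates(box, X, alpha_paste=0.3)  # m = 3
        upper = next(c for c in cands if c.move == "upper")
        assert sorted(upper.rows) == [10, 11, 12]

    def test_categorical_candidate_readmits_excluded_level(self, rng):
        from primbox import CategoricalRule
        X = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5 + ["c"] * 5})
        box = Box({"g": CategoricalRule(frozenset({"a", "b"}))})
        cands = paste_candidates(box, X, 0.1)
        assert len(cands) == 1
        assert cands[0].level == "c"
        assert set(cands[0].rows) == set(range(10, 15))


class TestPasteSequence:
    def test_no_improving_candidate_returns_box_unchanged(self):
        X = pd.DataFrame({"x1": np.arange(10.0)})
        y = np.where(X["x1"] >= 5, 1.0, 0.0)
        box = Box({"x1": ContinuousRule(5.0, 9.0)})
        out = paste_sequence(box, X, y,
                             PeelSettings(alpha_paste=0.2, paste_lookahead=0))
        assert out == box

    def test_lookahead_recovers_from_a_local_dip(self):
        # row 4 is a dip; row 3 carries a large gain behind it
        X = pd.DataFrame({"x1": np.arange(10.0)})
        y = np.array([0, 0, 0, 5.0, 0.0, 1, 1, 1, 1, 1])
        box = Box({"x1": ContinuousRule(5.0, 9.0)})
        greedy = paste_sequence(box, X, y,
                                PeelSettings(alpha_paste=0.1,
                                             paste_lookahead=0))
        patient = paste_sequence(box, X, y,
                                 PeelSettings(alpha_paste=0.1,
                                              paste_lookahead=2))
        assert greedy == box
        assert patient.rules["x1"].lower == 3.0
        inside = patient.membership(X)
        assert y[inside].mean() > 1.0

    def test_never_returns_a_lower_target_box(self, rng):
        for seed in range(10):
            gen = np.random.default_rng(seed)
            X, y = random_table(gen, 60, 2)
            points = peel_sequence(X, y, PeelSettings(alpha=0.15,
                                                      beta_min=0.1))
            box = points[-1].box
            before = y[box.membership(X)].mean()
            pasted = paste_sequence(box, X, y,
                                    PeelSettings(alpha_paste=0.05,
                                                 paste_lookahead=2))
            after = y[pasted.membership(X)].mean()
            assert after >= before - 1e-12

    def test_recovers_support_after_over_peeling(self):
        design = SimulationDesign(n=400, delta=3.0, beta=0.2,
                                  layout="one_center", seed=5)
        X, y, _ = simulate_dataset(design)
        points = peel_sequence(X, y, PeelSettings(alpha=0.1, beta_min=0.05))
        box = points[-1].box  # peeled far below the true 20% support
        before_support = box.membership(X).mean()
        before_target = y[box.membership(X)].mean()
        pasted = paste_sequence(box, X, y,
                                PeelSettings(alpha_paste=0.05,
                                             paste_lookahead=1))
        after_mask = pasted.membership(X)
        assert after_mask.mean() > before_support
        assert y[after_mask].mean() >= before_target - 1e-12
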