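"""Kaplan-Meier estimation and the area between survival curves.

The product-limit estimator is checked against an independent hand-written
oracle (exhaustively over all event/censoring patterns of small cohorts) and
against lifelines' KaplanMeierFitter; the exact rectangle-sum area is checked
against brute-force fine-grid numerical integration.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stsm.survival import (StepSurvivalFunction, abs_area, abs_norm,
                           km_estimate, survival_at)

from conftest import build_case_base


def oracle_product_limit(times, events):
    """Independent product-limit computation: plain loops, no vectorization."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    t_sorted = [times[i] for i in order]
    e_sorted = [events[i] for i in order]
    s = 1.0
    jumps, probs = [], []
    for t in sorted(set(t_sorted)):
        at_risk = sum(1 for x in t_sorted if x >= t)
        deaths = sum(1 for x, e in zip(t_sorted, e_sorted) if x == t and e == 1)
        if deaths:
            s *= 1.0 - deaths / at_risk
            jumps.append(t)
            probs.append(s)
    return jumps, probs


class TestKmEstimate:
    def test_hand_worked_example(self):
        S = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        # S(1) = 3/4, S(2) = 3/4 * 2/3 = 1/2, S(4) = 1/2 * 0/1 = 0
        assert S.jump_times.tolist() == [1, 2, 4]
        np.testing.assert_allclose(S.probs, [0.75, 0.5, 0.0])

    def test_all_censored_gives_constant_one(self):
        S = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(S.jump_times) == 0
        assert survival_at(S, 100.0) == 1.0

    def test_single_event(self):
        S = km_estimate([5.0], [1])
        assert survival_at(S, 4.999) == 1.0
        assert survival_at(S, 5.0) == 0.0

    @pytest.mark.parametrize("n", range(1, 7))
    def test_exhaustive_against_hand_oracle(self, n):
        """Every event/censoring pattern on small cohorts, including ties."""
        rng = np.random.default_rng(n)
        time_sets = [rng.integers(1, 4, n).astype(float) for _ in range(4)]
        time_sets.append(np.full(n, 2.0))  # all tied
        for times in time_sets:
            for events in itertools.product([0, 1], repeat=n):
                S = km_estimate(times, list(events))
                jumps, probs = oracle_product_limit(list(times), list(events))
                assert S.jump_times.tolist() == jumps
                np.testing.assert_allclose(S.probs, probs, atol=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(42)
        times = rng.exponential(1.0, 80).round(2)  # rounding forces ties
        events = rng.integers(0, 2, 80)
        S = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        grid = np.linspace(0, times.max(), 57)
        ours = survival_at(S, grid)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])
        with pytest.raises(ValueError):
            km_estimate([1.0, 2.0], [1])


class TestSurvivalAt:
    def test_right_continuous_step_lookup(self):
        S = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        assert survival_at(S, 0.0) == 1.0
        assert survival_at(S, 2.5) == 0.5
        assert survival_at(S, 2.0) == 0.5  # right-continuous at the jump
        assert survival_at(S, 99.0) == 0.0  # constant extension

    @given(st.lists(st.tuples(st.floats(0.01, 50), st.integers(0, 1)),
                    min_size=1, max_size=30))
    def test_bounds_and_monotonicity(self, obs):
        times = [t for t, _ in obs]
        events = [e for _, e in obs]
        S = km_estimate(times, events)
        grid = np.linspace(0, max(times) * 1.2, 97)
        vals = survival_at(S, grid)
        assert np.all(vals <= 1.0) and np.all(vals >= 0.0)
        assert np.all(np.diff(vals) <= 1e-15)
        if len(S.jump_times) == 0 or S.jump_times[0] > 0:
            assert survival_at(S, 0.0) == 1.0


def _random_step(rng, max_t=1.0):
    k = rng.integers(1, 8)
    jumps = np.sort(rng.uniform(0, max_t, k))
    jumps = np.unique(jumps)
    probs = np.sort(rng.uniform(0, 1, len(jumps)))[::-1]
    return StepSurvivalFunction(jumps, probs, n_obs=len(jumps))


class TestAbsArea:
    def test_identical_curves_give_zero(self):
        S = km_estimate([1, 2, 5], [1, 0, 1])
        assert abs_area(S, S, 10.0) == 0.0

    def test_single_rectangle(self):
        ones = StepSurvivalFunction(np.array([]), np.array([]), 1)
        drop = StepSurvivalFunction(np.array([0.5]), np.array([0.0]), 1)
        assert abs_area(ones, drop, 1.0) == pytest.approx(0.5)

    def test_against_fine_grid_integration(self):
        rng = np.random.default_rng(3)
        T = 1.0
        grid = np.arange(0, T, 1e-4 * T)
        for _ in range(20):
            S1, S2 = _random_step(rng), _random_step(rng)
            exact = abs_area(S1, S2, T)
            brute = np.sum((survival_at(S1, grid) - survival_at(S2, grid))) * 1e-4 * T
            assert abs(exact - brute) < 1e-3 * T

    def test_antisymmetry_is_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            S1, S2 = _random_step(rng), _random_step(rng)
            assert abs_area(S1, S2, 1.0) == -abs_area(S2, S1, 1.0)

    def test_additive_over_partition(self):
        # rescale a sub-curve so [0, a] + translated [a, T] = [0, T]
        rng = np.random.default_rng(5)
        S1, S2 = _random_step(rng), _random_step(rng)
        T, a = 1.0, 0.4
        whole = abs_area(S1, S2, T)
        first = abs_area(S1, S2, a)
        # remaining strip computed directly from the step evaluations
        grid = np.unique(np.concatenate(([a], S1.jump_times, S2.jump_times, [T])))
        grid = grid[(grid >= a) & (grid <= T)]
        left, widths = grid[:-1], np.diff(grid)
        second = float(np.sum((survival_at(S1, left) - survival_at(S2, left)) * widths))
        assert whole == pytest.approx(first + second, abs=1e-12)

    def test_bounded_by_horizon(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            S1, S2 = _random_step(rng), _random_step(rng)
            assert abs(abs_area(S1, S2, 1.0)) <= 1.0
        ones = StepSurvivalFunction(np.array([]), np.array([]), 1)
        zero = StepSurvivalFunction(np.array([0.0]), np.array([0.0]), 1)
        assert abs_area(ones, zero, 1.0) == 1.0

    def test_requires_positive_horizon(self):
        S = km_estimate([1.0], [1])
        with pytest.raises(ValueError):
            abs_area(S, S, 0.0)


class TestAbsNorm:
    def test_two_rectangle_hand_computation(self):
        # deceased: half die at T/2, half at T; alive: any size, curve == 1
        # integral of 1 - S_deceased: 0 on [0, T/2), 0.5 * T/2 on [T/2, T)
        T = 8.0
        cb = build_case_base([4.0, 4.0, 8.0, 8.0, 8.0], [1, 1, 1, 1, 0])
        assert abs_norm(cb, T) == pytest.approx(T / 4)

    def test_maximal_separation(self):
        # every deceased case dies immediately: normalized area equals T = 1
        cb = build_case_base([0.0, 0.0, 1.0], [1, 1, 0])
        assert abs_norm(cb, 1.0) == pytest.approx(1.0)

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError, match="no alive"):
            abs_norm(build_case_base([1, 2], [1, 1]), 2.0)
        with pytest.raises(ValueError, match="no deceased"):
            abs_norm(build_case_base([1, 2], [0, 0]), 2.0)
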