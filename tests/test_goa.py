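import math

import numpy as np
import pytest
from scipy.optimize import brentq

from goafs.goa import (
    CoefficientDraw,
    GoaParams,
    SocialForceParams,
    comfort_distance,
    draw_coefficients,
    initialize_population,
    mutate,
    run,
    schedule_a,
    schedule_a2,
    social_force,
)
from goafs.mask import FeatureMask


class TestSocialForce:
    def test_value_at_zero_is_f_minus_one(self):
        assert social_force(0.0, SocialForceParams(f=0.5)) == pytest.approx(-0.5)

    def test_decays_to_zero(self):
        assert abs(social_force(1000.0)) < 1e-12

    def test_comfort_distance_closed_form_vs_bisection(self):
        params = SocialForceParams(f=0.5, l=1.5)
        root = comfort_distance(params)
        assert root == pytest.approx(3 * math.log(2), abs=1e-12)
        oracle = brentq(lambda r: social_force(r, params), 1e-9, 50.0, xtol=1e-12)
        assert root == pytest.approx(oracle, abs=1e-9)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            social_force(-0.1)

    def test_repulsive_below_attractive_above_comfort(self):
        params = SocialForceParams()
        r0 = comfort_distance(params)
        assert social_force(r0 * 0.5, params) < 0 < social_force(r0 * 1.5, params)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SocialForceParams(f=0.0)
        with pytest.raises(ValueError):
            SocialForceParams(l=1.0)


@pytest.mark.parametrize("t,max_iter,a,a2", [
    (0, 100, 2.0, -1.0),
    (100, 100, 0.0, -2.0),
    (50, 100, 1.0, -1.5),
    (10, 40, 1.5, -1.25),
])
def test_schedules_are_linear(t, max_iter, a, a2):
    assert schedule_a(t, max_iter) == pytest.approx(a)
    assert schedule_a2(t, max_iter) == pytest.approx(a2)


def test_schedule_rejects_out_of_range_iteration():
    with pytest.raises(ValueError):
        schedule_a(101, 100)
    with pytest.raises(ValueError):
        schedule_a2(-1, 100)


class TestCoefficients:
    def test_zero_a_pins_A_to_zero(self, rng):
        for _ in range(20):
            assert draw_coefficients(0.0, -1.0, rng).A == 0.0

    def test_ranges_and_mean_over_many_draws(self, rng):
        n = 10_000
        draws = [draw_coefficients(2.0, -1.5, rng) for _ in range(n)]
        A = np.array([d.A for d in draws])
        C = np.array([d.C for d in draws])
        L = np.array([d.l_coef for d in draws])
        assert (-2.0 <= A).all() and (A <= 2.0).all()
        assert (0.0 <= C).all() and (C <= 2.0).all()
        assert (-1.5 <= L).all() and (L <= 1.0).all()
        # A = 2·a·r1 − a is uniform on [−a, a]: sd = a/sqrt(3)
        se = (2.0 / math.sqrt(3)) / math.sqrt(n)
        assert abs(A.mean()) < 3 * se
        assert A.min() < -1.8 and A.max() > 1.8

    def test_l_coef_interval_at_a2_minus_one(self, rng):
        draws = [draw_coefficients(1.0, -1.0, rng) for _ in range(200)]
        assert all(-1.0 <= d.l_coef <= 1.0 for d in draws)


class TestMutate:
    def test_zero_probability_is_identity(self, rng):
        m = FeatureMask.from_indices((1, 5, 13), 13)
        assert mutate(m, 0.0, rng) == m

    def test_full_probability_redraws_bernoulli_half(self, rng):
        m = FeatureMask.from_indices((1,), 13)
        n = 10_000
        marg = np.zeros(13)
        for _ in range(n):
            marg += mutate(m, 1.0, rng).asarray()
        marg /= n
        se = 0.5 / math.sqrt(n)
        # the non-empty repair adds ~2^-13 of bias, well inside 3 SE
        assert (np.abs(marg - 0.5) < 3 * se + 1e-3).all()

    def test_result_is_always_non_empty(self, rng):
        m = FeatureMask.from_indices((1,), 2)
        for _ in range(2000):
            assert mutate(m, 1.0, rng).size >= 1

    def test_probability_validation(self, rng):
        with pytest.raises(ValueError):
            mutate(FeatureMask.full(13), 1.5, rng)


class TestInitializePopulation:
    def test_size_and_non_emptiness(self, rng):
        pop = initialize_population(50, 13, rng)
        assert len(pop) == 50
        assert all(m.size >= 1 for m in pop)

    def test_seed_reproducibility(self):
        a = initialize_population(20, 13, np.random.default_rng(5))
        b = initialize_population(20, 13, np.random.default_rng(5))
        assert a == b

    def test_bit_marginals_near_half(self):
        rng = np.random.default_rng(99)
        n = 10_000
        marg = np.zeros(13)
        for m in (initialize_population(2, 13, rng) for _ in range(n // 2)):
            marg += m[0].asarray().astype(int) + m[1].asarray().astype(int)
        marg /= n
        se = 0.5 / math.sqrt(n)
        assert (np.abs(marg - 0.5) < 3 * se + 1e-3).all()


def popcount(mask: FeatureMask) -> float:
    return float(mask.size)


class TestRun:
    def test_counting_objective_reaches_global_minimum(self):
        params = GoaParams(pop_size=20, max_iter=40, seed=1)
        state = run(params, popcount, collect_trace=False)
        assert state.best_fitness == 1.0
        assert state.best_mask.size == 1

    def test_history_is_non_increasing(self):
        state = run(GoaParams(pop_size=15, max_iter=30, seed=2), popcount)
        assert all(a >= b for a, b in zip(state.history, state.history[1:]))

    def test_constant_fitness_settles_immediately(self):
        state = run(GoaParams(pop_size=10, max_iter=5, seed=3), lambda m: 7.0,
                    collect_trace=False)
        assert state.best_fitness == 7.0
        assert state.history == [7.0] * 6

    def test_deterministic_under_fixed_seed(self):
        p = GoaParams(pop_size=12, max_iter=15, seed=4)
        a = run(p, popcount, collect_trace=False)
        b = run(p, popcount, collect_trace=False)
        assert a.best_mask == b.best_mask
        assert a.history == b.history
        assert a.population == b.population

    def test_every_evaluated_mask_is_non_empty(self):
        seen = []

        def spy(mask):
            seen.append(mask)
            return popcount(mask)

        run(GoaParams(pop_size=10, max_iter=20, seed=5), spy, collect_trace=False)
        assert seen and all(m.size >= 1 for m in seen)

    def test_trace_records_schedule_quantities(self):
        state = run(GoaParams(pop_size=8, max_iter=10, seed=6), popcount)
        tr = state.trace
        assert list(tr["t"]) == list(range(1, 11))
        assert tr["a"].iloc[0] == pytest.approx(schedule_a(1, 10))
        assert tr["a2"].iloc[-1] == pytest.approx(-2.0)
        assert (tr["best_fitness"].diff().dropna() <= 0).all()

    def test_fitness_failure_carries_context(self):
        def broken(mask):
            raise RuntimeError("boom")

        from goafs.goa import GoaError
        with pytest.raises(GoaError, match="iteration 0"):
            run(GoaParams(pop_size=5, max_iter=2, seed=7), broken)

    def test_tie_break_prefers_smaller_subsets(self):
        # constant objective: elitism + tie-break should end on a small mask
        state = run(GoaParams(pop_size=30, max_iter=30, seed=8),
                    lambda m: 0.0, collect_trace=False)
        assert state.best_mask.size == 1
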