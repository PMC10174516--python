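import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gasselect import hgso_core
from gasselect.exceptions import EvaluationError, ParameterError
from gasselect.hgso_core import (
    GasPopulation,
    HGSOParams,
    SearchSpace,
    assign_clusters,
    count_worst,
    diversity,
    exploration_exploitation,
    hgso_iteration,
    initialize_population,
    interaction_gamma,
    reinitialize_worst,
    run_hgso,
    temperature,
    update_henry,
    update_positions,
    update_solubility,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class _HalfRng:
    """Stub stream returning 0.5 everywhere (pins the init draws)."""

    def random(self, size=None):
        if size is None:
            return 0.5
        return np.full(size, 0.5)


class TestInit:
    def test_positions_at_extremes(self):
        space = SearchSpace(3, -2.0, 4.0)
        params = HGSOParams(n_agents=4, n_clusters=2, seed=0)

        class _Zero(_HalfRng):
            def random(self, size=None):
                return np.zeros(size) if size is not None else 0.0

        pop = initialize_population(space, params, _Zero())
        np.testing.assert_array_equal(pop.positions, np.full((4, 3), -2.0))

        class _One(_HalfRng):
            def random(self, size=None):
                return np.ones(size) if size is not None else 1.0

        pop = initialize_population(space, params, _One())
        np.testing.assert_array_equal(pop.positions, np.full((4, 3), 4.0))

    def test_half_draws_scale_constants(self):
        # rand = 0.5 with l1=0.05, l2=100, l3=0.01
        space = SearchSpace(2, -1.0, 1.0)
        params = HGSOParams(n_agents=4, n_clusters=2, seed=0)
        pop = initialize_population(space, params, _HalfRng())
        np.testing.assert_allclose(pop.henry, 0.025)
        np.testing.assert_allclose(pop.pressure, 50.0)
        np.testing.assert_allclose(pop.cvals, 0.005)
        np.testing.assert_allclose(pop.solubility, 1.25)  # K*H*P = 1*0.025*50


class TestClusters:
    def test_even_partition(self):
        sizes = np.bincount(assign_clusters(10, 2))
        assert sizes.tolist() == [5, 5]

    def test_remainder_spread(self):
        sizes = np.bincount(assign_clusters(7, 3))
        assert sizes.tolist() == [3, 2, 2]

    def test_singletons(self):
        assert np.bincount(assign_clusters(4, 4)).tolist() == [1, 1, 1, 1]

    def test_too_many_clusters(self):
        with pytest.raises(ParameterError):
            assign_clusters(3, 4)


class TestScalars:
    def test_temperature_values(self):
        assert temperature(50, 100) == pytest.approx(0.606531, abs=1e-6)
        assert temperature(100, 100) == pytest.approx(math.exp(-1), abs=1e-9)

    def test_temperature_monotone(self):
        ts = [temperature(t, 100) for t in range(1, 101)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_temperature_domain(self):
        with pytest.raises(ParameterError):
            temperature(0, 100)
        with pytest.raises(ParameterError):
            temperature(101, 100)

    def test_update_henry_value(self):
        assert update_henry(0.05, 0.01, 0.606531, 298.15) == pytest.approx(
            0.049184, abs=1e-6
        )

    def test_update_henry_fixed_points(self):
        assert update_henry(0.3, 0.0, 0.5, 298.15) == pytest.approx(0.3)
        assert update_henry(0.3, 0.7, 298.15, 298.15) == pytest.approx(0.3)

    def test_update_henry_bad_temp(self):
        with pytest.raises(ParameterError):
            update_henry(0.05, 0.01, 0.0, 298.15)

    def test_solubility_products(self):
        assert update_solubility(1.0, 0.05, 50.0) == pytest.approx(2.5)
        assert update_solubility(1.0, 0.025, 50.0) == pytest.approx(1.25)

    def test_gamma_value(self):
        assert interaction_gamma(0.1, 0.2, 1.0, 0.05) == pytest.approx(
            math.exp(-0.6), abs=1e-9
        )
        assert interaction_gamma(0.1, 0.2, 1.0, 0.05) == pytest.approx(0.548812, abs=1e-6)

    def test_gamma_ratio_one(self):
        assert interaction_gamma(0.4, 0.4, 2.0, 0.05) == pytest.approx(2 * math.exp(-1))

    def test_gamma_linear_in_beta(self):
        g1 = interaction_gamma(0.1, 0.3, 1.0, 0.05)
        g2 = interaction_gamma(0.1, 0.3, 2.0, 0.05)
        assert g2 == pytest.approx(2 * g1)


class TestWorst:
    def test_count_worst_bounds(self):
        class _U:
            def __init__(self, v):
                self.v = v

            def random(self):
                return self.v

        assert count_worst(30, _U(0.5)) == 4
        assert count_worst(30, _U(0.0)) == 3
        assert count_worst(30, _U(1.0)) == 6

    def test_count_worst_min_one_for_big_pops(self):
        class _Zero:
            def random(self):
                return 0.0

        assert count_worst(10, _Zero()) == 1
        assert count_worst(5, _Zero()) == 0

    def _pop(self):
        space = SearchSpace(2, -1.0, 1.0)
        params = HGSOParams(n_agents=4, n_clusters=2, seed=0)
        pop = initialize_population(space, params, np.random.default_rng(0))
        pop.fitness = np.array([3.0, 1.0, 3.0, 0.5])
        return pop, space

    def test_zero_worst_noop(self):
        pop, space = self._pop()
        before = pop.positions.copy()
        reinitialize_worst(pop, 0, space, np.random.default_rng(1))
        np.testing.assert_array_equal(pop.positions, before)

    def test_full_reset_within_bounds(self):
        pop, space = self._pop()
        reinitialize_worst(pop, 4, space, np.random.default_rng(1))
        assert np.all(pop.positions >= -1) and np.all(pop.positions <= 1)
        assert np.all(np.isinf(pop.fitness))

    def test_tie_break_lowest_index_first(self):
        pop, space = self._pop()
        replaced = reinitialize_worst(pop, 1, space, np.random.default_rng(1))
        assert replaced.tolist() == [0]  # fitness 3.0 tie between agents 0 and 2


class TestDiversity:
    def test_identical_agents_zero(self):
        assert diversity(np.ones((5, 3))) == 0.0

    def test_hand_value(self):
        assert diversity(np.array([[0.0, 0.0], [2.0, 2.0]])) == pytest.approx(1.0)

    @given(s=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity(self, s):
        pos = np.array([[0.0, 1.0], [2.0, -1.0], [0.5, 0.25]])
        assert diversity(s * pos) == pytest.approx(abs(s) * diversity(pos), abs=1e-9)

    def test_percent_split(self):
        expl, expt = exploration_exploitation([2.0, 1.0, 4.0])
        np.testing.assert_allclose(expl, [50, 25, 100])
        np.testing.assert_allclose(expt, [50, 75, 0])
        np.testing.assert_allclose(expl + expt, 100)

    def test_all_zero_series_raises(self):
        with pytest.raises(ParameterError):
            exploration_exploitation([0.0, 0.0])


class TestRun:
    def test_constant_objective(self):
        space = SearchSpace(3, -1, 1)
        params = HGSOParams(n_agents=8, n_clusters=2, max_iter=10, seed=4)
        _, best, trace = run_hgso(lambda x: 7.5, space, params)
        assert best == 7.5
        assert np.all(trace.best_fitness == 7.5)

    def test_same_seed_identical_traces(self):
        space = SearchSpace(4, -5, 5)
        params = HGSOParams(n_agents=10, max_iter=15, seed=12)
        b1, f1, t1 = run_hgso(sphere, space, params)
        b2, f2, t2 = run_hgso(sphere, space, params)
        assert f1 == f2
        np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(t1.best_fitness, t2.best_fitness)
        np.testing.assert_array_equal(t1.div, t2.div)

    def test_best_non_increasing_and_bounded(self):
        space = SearchSpace(4, -5, 5)
        for seed in range(3):
            params = HGSOParams(n_agents=12, max_iter=20, seed=seed)
            best, _, trace = run_hgso(sphere, space, params)
            assert np.all(np.diff(trace.best_fitness) <= 0)
            assert np.all(best >= -5) and np.all(best <= 5)

    def test_non_finite_objective_names_agent(self):
        space = SearchSpace(2, -1, 1)
        params = HGSOParams(n_agents=4, n_clusters=1, max_iter=3, seed=0)
        with pytest.raises(EvaluationError, match="agent"):
            run_hgso(lambda x: float("nan"), space, params)

    def test_trace_length_equals_budget(self):
        space = SearchSpace(2, -1, 1)
        params = HGSOParams(n_agents=5, n_clusters=1, max_iter=7, seed=0)
        _, _, trace = run_hgso(sphere, space, params)
        assert len(trace) == 7

    def test_coefficients_stay_positive(self):
        space = SearchSpace(3, -2, 2)
        params = HGSOParams(n_agents=9, n_clusters=3, max_iter=25, seed=2)
        rng = np.random.default_rng(params.seed)
        pop = initialize_population(space, params, rng)
        for i in range(pop.n_agents):
            pop.fitness[i] = sphere(pop.positions[i])
        hgso_core._refresh_bests(pop, params.n_clusters)
        for t in range(1, params.max_iter + 1):
            hgso_iteration(pop, space, params, sphere, rng, t)
            assert np.all(pop.henry > 0)
            assert np.all(pop.pressure > 0)
            assert np.all(pop.cvals > 0)
            assert np.all(pop.solubility > 0)
            assert np.all(pop.positions >= space.lower)
            assert np.all(pop.positions <= space.upper)

    def test_diversity_trends_down_on_sphere(self):
        space = SearchSpace(5, -5, 5)
        ratios = []
        for seed in range(5):
            params = HGSOParams(n_agents=20, max_iter=40, seed=seed)
            _, _, trace = run_hgso(sphere, space, params)
            head = trace.div[:4].mean()
            tail = trace.div[-4:].mean()
            ratios.append(tail < head)
        assert np.median(ratios) == 1.0


class TestSingleAgentHandStep:
    def test_pinned_single_step_matches_hand_formula(self):
        space = SearchSpace(1, -10.0, 10.0)
        params = HGSOParams(n_agents=1, n_clusters=1, seed=0)
        pop = GasPopulation(
            positions=np.array([[2.0]]),
            fitness=np.array([0.5]),
            cluster_id=np.array([0]),
            henry=np.array([0.05]),
            pressure=np.array([50.0]),
            cvals=np.array([0.01]),
            solubility=np.array([2.5]),
            cluster_best_pos=np.array([[1.0]]),
            cluster_best_fit=np.array([0.2]),
            best_pos=np.array([1.0]),
            best_fit=0.2,
        )

        class _Pinned:
            def __init__(self):
                self.calls = 0

            def random(self, size=None):
                self.calls += 1
                if self.calls == 1:  # flag draw: 0.4 < 0.5 -> F = +1
                    return np.array([0.4])
                return np.array([0.25])  # r

        update_positions(pop, space, params, _Pinned())
        gamma = math.exp(-(0.2 + 0.05) / (0.5 + 0.05))
        expected = 2.0 + 1 * 0.25 * gamma * (1.0 - 2.0) + 1 * 0.25 * 1.0 * (2.5 * 1.0 - 2.0)
        assert pop.positions[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_fixed_point_when_all_at_best(self):
        space = SearchSpace(2, -10.0, 10.0)
        params = HGSOParams(n_agents=1, n_clusters=1, seed=0)
        x = np.array([3.0, -2.0])
        pop = GasPopulation(
            positions=x[None, :].copy(),
            fitness=np.array([1.0]),
            cluster_id=np.array([0]),
            henry=np.array([0.05]),
            pressure=np.array([20.0]),
            cvals=np.array([0.01]),
            solubility=np.array([1.0]),  # S = 1 so the global term also vanishes
            cluster_best_pos=x[None, :].copy(),
            cluster_best_fit=np.array([1.0]),
            best_pos=x.copy(),
            best_fit=1.0,
        )
        update_positions(pop, space, params, np.random.default_rng(0))
        np.testing.assert_allclose(pop.positions[0], x, atol=1e-12)
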