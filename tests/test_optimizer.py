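"""Unit and property tests for the TEO/dTEO minimiser."""

import math

import numpy as np
import pytest

from dermelm.exceptions import ConfigError
from dermelm.optimizer import (
    ChaoticStream,
    OptimizerConfig,
    chaos_next,
    cost_ratio,
    gaussian_mutate,
    initialize_population,
    minimize,
    step,
)


def _sphere(x):
    return float(x @ x)


class TestChaoticMap:
    @pytest.mark.parametrize(
        "f,alpha,expected",
        [
            (0.5, 2.3, 0.575),  # 2.3 * 0.25 * sin(pi/2)
            (0.7, 2.3, 2.3 * 0.49 * math.sin(0.7 * math.pi)),
        ],
    )
    def test_map_arithmetic(self, f, alpha, expected):
        assert chaos_next(f, alpha) == pytest.approx(expected, rel=1e-12)

    def test_small_state_clipped_to_interior(self):
        assert 0.0 < chaos_next(1e-9, 2.3) < 1e-6

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_domain_error(self, bad):
        with pytest.raises(ConfigError):
            chaos_next(bad, 2.3)

    def test_stream_stays_in_unit_interval(self):
        stream = ChaoticStream(0.7, 2.3)
        vals = np.array([stream.draw() for _ in range(100_000)])
        assert np.all((vals > 0.0) & (vals < 1.0))


class TestInitialization:
    def test_degenerate_bounds_give_constant_population(self, rng):
        config = OptimizerConfig(bounds_low=[0.0, 0.0], bounds_high=[0.0, 0.0])
        state = initialize_population(config, rng)
        assert np.all(state.temperatures == 0.0)

    @pytest.mark.parametrize("variant", ["teo", "dteo"])
    def test_range_containment(self, variant):
        config = OptimizerConfig(
            bounds_low=[-1.0], bounds_high=[1.0], population_size=1000, variant=variant
        )
        state = initialize_population(config, np.random.default_rng(0))
        assert state.temperatures.min() >= -1.0
        assert state.temperatures.max() <= 1.0

    def test_seed_determinism(self):
        config = OptimizerConfig(bounds_low=[-2.0, 0.0], bounds_high=[3.0, 1.0])
        a = initialize_population(config, np.random.default_rng(9)).temperatures
        b = initialize_population(config, np.random.default_rng(9)).temperatures
        np.testing.assert_array_equal(a, b)

    def test_odd_population_rejected(self):
        with pytest.raises(ConfigError):
            OptimizerConfig(bounds_low=[0.0], bounds_high=[1.0], population_size=7)


class TestCostRatio:
    @pytest.mark.parametrize(
        "ci,cw,expected", [(8.0, 8.0, 1.0), (0.0, 8.0, 0.0), (2.0, 8.0, 0.25)]
    )
    def test_values(self, ci, cw, expected):
        assert cost_ratio(ci, cw) == expected

    def test_all_equal_convention(self):
        assert cost_ratio(0.0, 0.0) == 1.0


class TestGaussianMutation:
    def test_zero_decay_is_identity(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(gaussian_mutate(x, 0.0, rng), x)

    def test_zero_vector_fixed(self, rng):
        out = gaussian_mutate(np.zeros(5), 1.0, rng)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_moments_of_full_mutation(self):
        rng = np.random.default_rng(3)
        samples = gaussian_mutate(np.ones(100_000), 1.0, rng)
        se = 1.0 / math.sqrt(samples.size)
        assert abs(samples.mean() - 1.0) < 3 * se
        assert abs(samples.std() - 1.0) < 3 * se * math.sqrt(2)


class TestStep:
    def _evaluated_state(self, config, objective, seed=0):
        rng = np.random.default_rng(seed)
        state = initialize_population(config, rng)
        state.costs = np.array([objective(t) for t in state.temperatures])
        return state, rng

    def test_fixed_point_at_optimum(self):
        config = OptimizerConfig(
            bounds_low=[-5.0, -5.0],
            bounds_high=[5.0, 5.0],
            population_size=8,
            m1=0,
            m2=0,
            pr=0.0,
            variant="teo",
        )
        state, rng = self._evaluated_state(config, _sphere)
        state.temperatures[:] = 0.0
        state.costs[:] = 0.0
        out = step(state, _sphere, config, rng)
        assert out.costs.min() == 0.0
        assert np.all(out.temperatures == 0.0)

    def test_elitism_keeps_best_nonincreasing(self):
        config = OptimizerConfig(
            bounds_low=[-5.0] * 3,
            bounds_high=[5.0] * 3,
            population_size=10,
            memory_size=1,
            max_iterations=30,
        )
        state, rng = self._evaluated_state(config, _sphere, seed=4)
        best = state.costs.min()
        for _ in range(30):
            state = step(state, _sphere, config, rng)
            assert state.costs.min() <= best + 1e-15
            best = min(best, state.costs.min())

    def test_bounds_containment_every_step(self):
        config = OptimizerConfig(
            bounds_low=[-1.0, 0.0], bounds_high=[1.0, 2.0], population_size=12
        )
        state, rng = self._evaluated_state(config, _sphere, seed=5)
        for _ in range(20):
            state = step(state, _sphere, config, rng)
            assert np.all(state.temperatures >= config.bounds_low - 1e-12)
            assert np.all(state.temperatures <= config.bounds_high + 1e-12)

    def test_cooling_moves_toward_environment_in_expectation(self):
        """A cooling object at 1.0 paired with an environment at 0.0 moves
        strictly closer to the optimum on average over many replicates."""
        config = OptimizerConfig(
            bounds_low=[-2.0],
            bounds_high=[2.0],
            population_size=2,
            pr=0.0,
            variant="teo",
            max_iterations=10,
        )
        moved = []
        for s in range(2000):
            rng = np.random.default_rng(s)
            state = initialize_population(config, rng)
            state.temperatures[:] = np.array([[0.0], [1.0]])
            state.costs = np.array([0.0, 1.0])
            out = step(state, _sphere, config, rng)
            # memory holds {0.0, new}; the non-memory slot is the update
            moved.append(float(np.max(np.abs(out.temperatures))))
        assert np.mean(moved) < 1.0

    def test_nonfinite_objective_becomes_inf(self):
        config = OptimizerConfig(
            bounds_low=[-1.0], bounds_high=[1.0], population_size=4, memory_size=0
        )

        def bad(x):
            return float("nan")

        state, rng = self._evaluated_state(config, _sphere, seed=6)
        out = step(state, bad, config, rng)
        assert np.isinf(out.costs).any()


class TestMinimize:
    def test_history_monotone_and_consistent(self):
        config = OptimizerConfig(
            bounds_low=[-5.0, -5.0], bounds_high=[5.0, 5.0], population_size=20,
            max_iterations=40, seed=11,
        )
        result = minimize(_sphere, config)
        assert np.all(np.diff(result.history) <= 0)
        assert result.best_cost == result.history[-1]
        assert result.best_cost == result.history.min()
        assert np.all(np.abs(result.best_vector) <= 5.0)

    def test_constant_objective(self):
        config = OptimizerConfig(
            bounds_low=[0.0, 0.0], bounds_high=[1.0, 1.0], population_size=10,
            max_iterations=5, seed=2,
        )
        result = minimize(lambda x: 3.5, config)
        assert result.best_cost == 3.5

    def test_sphere_convergence(self):
        """dTEO at full budget reaches ~1e-6 on the 2-D sphere almost always."""
        hits = 0
        for s in range(20):
            config = OptimizerConfig(
                bounds_low=[-5.0, -5.0], bounds_high=[5.0, 5.0], seed=s
            )
            if minimize(_sphere, config).best_cost < 1e-6:
                hits += 1
        assert hits >= 19

    def test_evaluation_count_matches_protocol(self):
        config = OptimizerConfig(
            bounds_low=[-1.0], bounds_high=[1.0], population_size=10,
            max_iterations=7, seed=0,
        )
        result = minimize(_sphere, config)
        # init evaluates the population, each step the cooling half
        assert result.evaluations == 10 + 7 * 5

    def test_dteo_beats_teo_on_f1_reduced_protocol(self):
        """Stochastic dominance of the developed variant on the sphere."""
        from dermelm.benchmarks import get_function

        f1 = get_function("F1", dim_multivariate=10)
        wins = 0
        reps = 10
        for s in range(reps):
            results = {}
            for variant in ("teo", "dteo"):
                config = OptimizerConfig(
                    bounds_low=f1.bounds_low,
                    bounds_high=f1.bounds_high,
                    population_size=40,
                    max_iterations=50,
                    variant=variant,
                    seed=s,
                )
                results[variant] = minimize(f1.evaluate, config).best_cost
            wins += results["dteo"] <= results["teo"]
        assert wins >= reps - 2
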