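import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from impa.mpa_core import (
    OptimizerConfig,
    PopulationState,
    StepSample,
    brownian_matrix,
    compute_cf,
    fads_perturbation,
    levy_matrix,
    memory_save,
    phase1_kernel,
    phase2_brownian_kernel,
    phase2_update,
    phase3_kernel,
    phase_of_iteration,
    update_elite,
)


def _state(prey, fitness, best_idx=None):
    prey = np.atleast_2d(np.asarray(prey, dtype=float))
    fitness = np.asarray(fitness, dtype=float)
    i = int(np.argmin(fitness)) if best_idx is None else best_idx
    return PopulationState(
        prey=prey.copy(),
        fitness=fitness.copy(),
        best_position=prey[i].copy(),
        best_fitness=float(fitness[i]),
        prev_prey=prey.copy(),
        prev_fitness=fitness.copy(),
    )


class TestStepSamplers:
    def test_brownian_seeded_determinism(self):
        a = brownian_matrix(10, 4, np.random.default_rng(3))
        b = brownian_matrix(10, 4, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_brownian_moments(self):
        x = brownian_matrix(100_000, 1, np.random.default_rng(0))
        assert abs(x.mean()) < 0.02
        assert abs(x.var() - 1.0) < 0.02

    def test_levy_seeded_determinism(self):
        a = levy_matrix(10, 4, 1.5, np.random.default_rng(3))
        b = levy_matrix(10, 4, 1.5, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_levy_is_heavier_tailed_than_normal(self):
        rng = np.random.default_rng(0)
        levy = levy_matrix(100_000, 1, 1.5, rng).ravel()
        normal = np.random.default_rng(1).standard_normal(100_000)

        def kurtosis(x):
            z = (x - x.mean()) / x.std()
            return float(np.mean(z**4))

        assert kurtosis(levy) > kurtosis(normal)
        assert np.mean(np.abs(levy) > 3) > np.mean(np.abs(normal) > 3)

    def test_levy_exponent_validated(self):
        with pytest.raises(ValueError):
            levy_matrix(2, 2, 2.5, np.random.default_rng(0))


class TestCF:
    @pytest.mark.parametrize("it, it_max, expected", [(0, 50, 1.0), (50, 50, 0.0), (25, 50, 0.5)])
    def test_closed_forms(self, it, it_max, expected):
        assert compute_cf(it, it_max) == pytest.approx(expected, abs=1e-15)

    def test_monotone_non_increasing(self):
        vals = [compute_cf(it, 200) for it in range(201)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))
        assert vals[0] == 1.0 and vals[-1] == 0.0


class TestPhaseRegimes:
    def test_iteration_thirds(self):
        phases = [phase_of_iteration(it, 50) for it in range(1, 51)]
        assert phases == sorted(phases)  # 1 -> 2 -> 3, never backwards
        assert phases[0] == 1 and phases[-1] == 3
        assert phases.count(2) > 0


class TestPhaseKernels:
    """Single-step hand evaluations of the velocity equations on 1-D instances."""

    def test_phase1_zero_step_leaves_prey(self):
        prey = np.array([[3.0], [7.0]])
        steps = StepSample(np.zeros((2, 1)), np.zeros((2, 1)), np.ones((2, 1)))
        out = phase1_kernel(prey, np.full((2, 1), 5.0), steps, 0.5)
        assert np.array_equal(out, prey)

    def test_phase1_hand_value(self):
        # Elite=5, prey=3, both Brownian factors 1, R=1, P=0.5 -> 3 + 0.5*(5-3) = 4
        steps = StepSample(np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)))
        out = phase1_kernel(np.array([[3.0]]), np.array([[5.0]]), steps, 0.5)
        assert out == pytest.approx(np.array([[4.0]]), abs=1e-12)

    def test_phase2_brownian_hand_value(self):
        # Elite=2, prey=1, RB=1, P=0.5, CF=0.5 -> 2 + 0.25*(2-1) = 2.25
        steps = StepSample(np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)))
        out = phase2_brownian_kernel(np.array([[1.0]]), np.array([[2.0]]), steps, 0.5, 0.5)
        assert out == pytest.approx(np.array([[2.25]]), abs=1e-12)

    def test_phase2_collapses_to_elite_at_cf_zero(self):
        steps = StepSample(np.ones((3, 2)), np.ones((3, 2)), np.ones((3, 2)))
        elite = np.full((3, 2), 4.0)
        out = phase2_brownian_kernel(np.zeros((3, 2)), elite, steps, 0.5, 0.0)
        assert np.array_equal(out, elite)

    def test_phase3_hand_value(self):
        # Elite=4, prey=1, RL=1, P=0.5, CF=1 -> 4 + 0.5*(4-1) = 5.5
        steps = StepSample(np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)))
        out = phase3_kernel(np.array([[1.0]]), np.array([[4.0]]), steps, 0.5, 1.0)
        assert out == pytest.approx(np.array([[5.5]]), abs=1e-12)

    def test_phase2_split_assigns_exactly_half_to_levy(self):
        n, d = 6, 2
        prey = np.arange(n * d, dtype=float).reshape(n, d)
        state = _state(prey, np.arange(n, dtype=float))
        zero = StepSample(np.zeros((3, d)), np.zeros((3, d)), np.zeros((3, d)))
        one = StepSample(np.ones((3, d)), np.ones((3, d)), np.ones((3, d)))
        # zero Lévy steps leave the first half at its old positions; the
        # Brownian half is Elite-anchored and moves regardless
        out = phase2_update(
            state, it=20, it_max=50, p=0.5, rng=np.random.default_rng(0),
            steps_levy=zero, steps_brownian=one,
        )
        assert np.array_equal(out[:3], prey[:3])
        assert not np.array_equal(out[3:], prey[3:])

    def test_phase2_rejects_odd_population(self):
        state = _state(np.ones((3, 1)), np.zeros(3))
        with pytest.raises(ValueError):
            phase2_update(state, 20, 50, 0.5, np.random.default_rng(0))

    def test_updates_deterministic_under_fixed_seed(self):
        state = _state(np.random.default_rng(0).uniform(size=(4, 3)), np.arange(4.0))
        a = phase2_update(state, 20, 50, 0.5, np.random.default_rng(9))
        b = phase2_update(state, 20, 50, 0.5, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestFADs:
    def test_else_branch_with_identical_rows_is_identity(self):
        prey = np.tile(np.array([1.5, -2.0]), (6, 1))
        out = fads_perturbation(
            prey, cf=0.7, fads=0.0, lb=np.array([-5.0, -5.0]), ub=np.array([5.0, 5.0]),
            rng=np.random.default_rng(0),
        )
        assert np.allclose(out, prey)

    def test_jump_and_mask_frequencies(self):
        """Entry-perturbation rate = P(r <= FADs) * P(mask) = 0.04 at FADs 0.2."""
        n, d = 100_000, 5
        prey = np.zeros((n, d))
        out = fads_perturbation(
            prey, cf=1.0, fads=0.2, lb=np.ones(d), ub=np.full(d, 2.0),
            rng=np.random.default_rng(1),
        )
        frac = np.mean(out != 0.0)
        assert abs(frac - 0.04) < 0.005

    def test_default_fads_constant(self):
        assert OptimizerConfig().fads == 0.2
        assert OptimizerConfig().p == 0.5


class TestMemorySave:
    def test_all_current_better_keeps_current(self):
        state = _state(np.ones((3, 2)), np.zeros(3))
        state.prev_prey = np.full((3, 2), 9.0)
        state.prev_fitness = np.full(3, 10.0)
        memory_save(state)
        assert np.array_equal(state.prey, np.ones((3, 2)))

    def test_all_previous_better_restores_previous(self):
        state = _state(np.ones((3, 2)), np.full(3, 10.0))
        state.prev_prey = np.full((3, 2), 9.0)
        state.prev_fitness = np.zeros(3)
        memory_save(state)
        assert np.array_equal(state.prey, np.full((3, 2), 9.0))
        assert np.array_equal(state.fitness, np.zeros(3))

    def test_mixed_case_matches_rowwise_oracle(self, rng):
        n, d = 50, 4
        cur_p, prev_p = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        cur_f, prev_f = rng.uniform(size=n), rng.uniform(size=n)
        state = _state(cur_p, cur_f)
        state.prev_prey, state.prev_fitness = prev_p.copy(), prev_f.copy()
        memory_save(state)
        for j in range(n):  # brute-force row comparison
            if cur_f[j] <= prev_f[j]:
                assert np.array_equal(state.prey[j], cur_p[j])
            else:
                assert np.array_equal(state.prey[j], prev_p[j])

    def test_requires_populated_memory(self):
        state = _state(np.ones((2, 1)), np.zeros(2))
        state.prev_prey = None
        with pytest.raises(ValueError):
            memory_save(state)


class TestUpdateElite:
    def test_strictly_better_row_takes_over(self):
        state = _state(np.array([[1.0, 1.0], [2.0, 2.0]]), np.array([5.0, 3.0]))
        state.best_fitness, state.best_position = 4.0, np.zeros(2)
        update_elite(state)
        assert state.best_fitness == 3.0
        assert np.array_equal(state.elite, np.tile([2.0, 2.0], (2, 1)))

    def test_tie_keeps_incumbent(self):
        state = _state(np.array([[1.0], [2.0]]), np.array([4.0, 5.0]))
        state.best_fitness, state.best_position = 4.0, np.array([9.0])
        update_elite(state)
        assert np.array_equal(state.best_position, np.array([9.0]))

    def test_elite_rows_always_identical(self, rng):
        state = _state(rng.normal(size=(7, 3)), rng.uniform(size=7))
        update_elite(state)
        assert np.all(state.elite == state.elite[0])


class TestConfigValidation:
    @pytest.mark.parametrize("n", [1, 3, 0, 7])
    def test_odd_or_tiny_population_rejected(self, n):
        with pytest.raises(ValueError):
            OptimizerConfig(n_agents=n)

    def test_levy_exponent_range(self):
        with pytest.raises(ValueError):
            OptimizerConfig(levy_exponent=2.5)


@settings(max_examples=60, deadline=None)
@given(st.integers(3, 500), st.data())
def test_cf_bounded_and_non_increasing(it_max, data):
    it1 = data.draw(st.integers(0, it_max))
    it2 = data.draw(st.integers(it1, it_max))
    c1, c2 = compute_cf(it1, it_max), compute_cf(it2, it_max)
    assert 0.0 <= c2 <= c1 <= 1.0
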