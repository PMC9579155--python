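import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungcad.ipso import (PsoConfig, adaptive_inertia, decode_position,
                          dynamic_factors, encode_params, make_cv_fitness,
                          optimize, update_particle)
from lungcad.mkl_svm import KernelParams


class TestAdaptiveInertia:
    def test_above_average_particles_get_terminal_weight(self):
        assert adaptive_inertia(0.9, 0.8, 0.95) == pytest.approx(0.4)

    def test_average_particle_continuous_with_upper_branch(self):
        assert adaptive_inertia(0.8, 0.8, 0.95) == pytest.approx(0.4)

    def test_best_particle_in_lower_subgroup_gets_start_weight(self):
        # f_i == f_max but f_i <= f_avg is impossible unless f_avg == f_max;
        # the closest admissible case: f_i just below f_avg, far above others
        assert adaptive_inertia(0.95, 0.95, 0.95) == pytest.approx(0.4)
        # numerator-zero case: f_i == f_max with f_avg < f_max via clipping path
        w = adaptive_inertia(0.50, 0.80, 0.95, omega_s=0.9, omega_e=0.4)
        expected = 0.9 - (0.50 - 0.95) * 0.5 / (0.80 - 0.95)
        assert w == pytest.approx(np.clip(expected, 0.4, 0.9))

    @given(f_i=st.floats(0, 1), f_avg=st.floats(0, 1), f_max=st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_weight_always_within_band(self, f_i, f_avg, f_max):
        f_max = max(f_max, f_avg)
        w = adaptive_inertia(f_i, f_avg, f_max)
        assert 0.4 <= w <= 0.9


class TestDynamicFactors:
    def test_first_iteration_uses_extremes(self):
        c1, c2 = dynamic_factors(1, 200)
        assert c1 == pytest.approx(2.5)
        assert c2 == pytest.approx(0.5)

    def test_midpoint_matches_direct_formula(self):
        big_t = 100
        t = big_t // 2 + 1
        c1, c2 = dynamic_factors(t, big_t)
        assert c1 == pytest.approx(2.5 - (t - 1) / big_t * 2.5)
        assert c2 == pytest.approx(0.5 + (t - 1) / big_t * 0.5)

    def test_schedules_strictly_monotone(self):
        c1s, c2s = zip(*(dynamic_factors(t, 50) for t in range(1, 51)))
        assert all(a > b for a, b in zip(c1s, c1s[1:]))
        assert all(a < b for a, b in zip(c2s, c2s[1:]))

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            dynamic_factors(0, 10)
        with pytest.raises(ValueError):
            dynamic_factors(11, 10)


class TestUpdateParticle:
    LOWER = np.array([-10.0])
    UPPER = np.array([10.0])
    VMAX = np.array([4.0])

    def test_converged_particle_is_stationary(self, rng):
        x = np.array([1.0])
        x_new, v_new = update_particle(x, np.zeros(1), x, x, 0.7, 2.0, 2.0,
                                       self.LOWER, self.UPPER, self.VMAX, rng)
        np.testing.assert_array_equal(x_new, x)
        np.testing.assert_array_equal(v_new, np.zeros(1))

    def test_pure_drift_when_factors_zero(self, rng):
        x, v = np.array([1.0]), np.array([2.5])
        x_new, v_new = update_particle(x, v, x, x, 1.0, 0.0, 0.0,
                                       self.LOWER, self.UPPER, self.VMAX, rng)
        np.testing.assert_allclose(v_new, v)
        np.testing.assert_allclose(x_new, x + v)

    def test_hand_worked_update_with_velocity_clipping(self):
        class HalfRng:
            def uniform(self, size=None):
                return np.full(size, 0.5) if size else 0.5

        x, v = np.array([0.0]), np.array([2.0])
        p_i, p_g = np.array([1.0]), np.array([3.0])
        # v' = 0.5*2 + 2*0.5*(1-0) + 2*0.5*(3-0) = 5 -> clipped to 4
        x_new, v_new = update_particle(x, v, p_i, p_g, 0.5, 2.0, 2.0,
                                       self.LOWER, self.UPPER, self.VMAX, HalfRng())
        np.testing.assert_allclose(v_new, [4.0])
        np.testing.assert_allclose(x_new, [4.0])

    def test_position_clipped_to_bounds(self, rng):
        x, v = np.array([9.5]), np.array([4.0])
        x_new, _ = update_particle(x, v, x, x, 1.0, 0.0, 0.0,
                                   self.LOWER, self.UPPER, self.VMAX, rng)
        assert x_new[0] == 10.0


class TestOptimize:
    @staticmethod
    def sphere(x):
        return -float(np.sum(x * x))

    def _config(self, **kw):
        base = dict(n_particles=15, n_iterations=60,
                    lower=np.full(3, -5.0), upper=np.full(3, 5.0), seed=0)
        base.update(kw)
        return PsoConfig(**base)

    def test_sphere_converges_near_optimum(self):
        res = optimize(self.sphere, self._config(n_iterations=200, n_particles=20))
        assert res.best_fitness >= -1e-2

    def test_trace_monotone_and_positions_bounded(self):
        res = optimize(self.sphere, self._config(seed=3))
        assert np.all(np.diff(res.trace) >= 0)
        assert np.all(res.positions >= -5.0) and np.all(res.positions <= 5.0)

    def test_constant_objective_flat_trace(self):
        res = optimize(lambda x: 1.25, self._config(n_iterations=10))
        assert np.all(res.trace == 1.25)

    def test_seeded_determinism(self):
        a = optimize(self.sphere, self._config(seed=11))
        b = optimize(self.sphere, self._config(seed=11))
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_nonfinite_fitness_warned_and_ignored(self):
        def sometimes_nan(x):
            return np.nan if x[0] > 0 else self.sphere(x)

        with pytest.warns(RuntimeWarning):
            res = optimize(sometimes_nan, self._config(n_iterations=5))
        assert np.isfinite(res.best_fitness)

    def test_early_stop_halts_search(self):
        res = optimize(self.sphere, self._config(early_stop_fitness=-10.0,
                                                 n_iterations=100))
        assert res.trace.size < 101
        assert res.best_fitness >= -10.0

    def test_constant_inertia_fixed_factors_is_standard_pso(self):
        res = optimize(self.sphere, self._config(inertia=0.7, factors=(2.0, 2.0),
                                                 n_iterations=100))
        assert res.best_fitness >= -1.0  # standard PSO still solves the sphere


class TestPositionCoding:
    def test_decode_hand_values(self):
        p = decode_position([0.0, 0.0, 0.5])
        assert (p.C, p.g, p.gamma, p.d) == (1.0, 1.0, 0.5, 3)
        p = decode_position([9.0, 7.0, 1.0])
        assert (p.C, p.g, p.gamma) == (512.0, 128.0, 1.0)

    def test_roundtrip(self):
        params = KernelParams(C=2.0 ** 3.5, g=2.0 ** -2.25, gamma=0.37)
        np.testing.assert_allclose(encode_params(decode_position(
            encode_params(params))), encode_params(params))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            decode_position([10.0, 0.0, 0.5])


class TestCvFitness:
    def test_deterministic_and_bounded(self, separable_data):
        x, y = separable_data
        fit = make_cv_fitness(x, y, fold_seed=4)
        pos = np.array([1.0, 0.0, 0.5])
        v1, v2 = fit(pos), fit(pos)
        assert v1 == v2
        assert 0.0 <= v1 <= 1.0

    def test_separable_data_scores_high(self, separable_data):
        x, y = separable_data
        fit = make_cv_fitness(x, y, fold_seed=0)
        assert fit(np.array([0.0, 0.0, 0.5])) >= 0.95
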