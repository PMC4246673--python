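"""Model-core tests: kernels, sigmoid, matrix construction, Euler stepping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from masskf import networks
from masskf.statespace import (build_state_space, mean_firing_rate,
                               postsynaptic_kernel, steady_state)
from conftest import loop_rhs


class TestPostsynapticKernel:
    def test_zero_before_onset(self):
        assert postsynaptic_kernel(-0.001, 0.010) == 0.0

    @pytest.mark.parametrize("tau", [0.010, 0.020, 0.0303])
    def test_peak_at_tau_with_amplitude_1_over_e(self, tau):
        assert postsynaptic_kernel(tau, tau) == pytest.approx(np.exp(-1))
        t = np.linspace(0, 10 * tau, 2000)
        assert np.max(postsynaptic_kernel(t, tau)) <= np.exp(-1) + 1e-12

    @pytest.mark.parametrize("tau", [0.010, 0.020])
    def test_integrates_to_tau(self, tau):
        val, _ = quad(lambda t: postsynaptic_kernel(t, tau), 0, 50 * tau)
        assert val == pytest.approx(tau, rel=1e-6)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            postsynaptic_kernel(0.01, 0.0)


class TestMeanFiringRate:
    def test_half_rate_at_threshold(self):
        assert mean_firing_rate(6.0, 6.0, 3.0) == pytest.approx(0.5)

    def test_limits(self):
        assert mean_firing_rate(1e3, 6.0, 3.0) == pytest.approx(1.0)
        assert mean_firing_rate(-1e3, 6.0, 3.0) == pytest.approx(0.0)

    def test_matches_gaussian_integral(self):
        # the sigmoid is the CDF of N(v0, sigma^2): integrate the density
        density = lambda x: np.exp(-(x - 6.0)**2 / (2 * 9.0)) / np.sqrt(2 * np.pi * 9.0)
        val, _ = quad(density, -np.inf, 9.0)
        assert mean_firing_rate(9.0, 6.0, 3.0) == pytest.approx(val, abs=1e-9)
        assert val == pytest.approx(0.84134, abs=1e-5)

    @given(st.floats(-12, 12), st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_bounded_symmetric(self, a, v0):
        g_hi = mean_firing_rate(v0 + a, v0, 3.0)
        g_lo = mean_firing_rate(v0 - a, v0, 3.0)
        assert 0.0 < g_hi < 1.0
        assert g_hi + g_lo == pytest.approx(1.0, abs=1e-12)
        if a > 1e-12:
            assert g_hi > g_lo


class TestBuildStateSpace:
    def test_augmented_dimension_single(self, single_spec, single_model):
        assert single_spec.n_intra == 5 and single_spec.n_inter == 0
        assert single_model.n == 15

    def test_augmented_dimension_four(self, four_spec, four_model):
        assert four_spec.n_intra == 20 and four_spec.n_inter == 8
        assert four_model.n == 84
        # index map is a bijection onto 0..n-1
        im = four_model.index_map
        allpos = np.concatenate([im.v, im.z, im.alpha])
        assert sorted(allpos) == list(range(84))

    @pytest.mark.parametrize("model_fixture", ["single_model", "four_model"])
    def test_vectorized_drift_matches_loop_oracle(self, model_fixture, request):
        model = request.getfixturevalue(model_fixture)
        spec = model.spec
        rng = np.random.default_rng(7)
        for _ in range(100):
            xi = rng.normal(0, 20, model.n)
            u = rng.normal(220, 30)
            np.testing.assert_allclose(model.rhs(xi, u), loop_rhs(spec, xi, u),
                                       rtol=1e-12, atol=1e-9)

    def test_parameter_rows_are_zero(self, single_model):
        ia = single_model.index_map.alpha
        assert np.all(single_model.A[ia] == 0)
        assert np.all(single_model.B[ia] == 0)
        assert np.all(single_model.D1[ia] == 0)

    def test_zero_state_structure(self, single_model):
        # at xi=0 with u=0 only the B term can act, and only on z rows
        xi = np.zeros(single_model.n)
        out = single_model.rhs(xi, 0.0)
        im = single_model.index_map
        assert np.all(out[im.v] == 0)
        assert np.all(out[im.alpha] == 0)

    def test_gamma_rows_sum_incoming_psps(self, four_model):
        spec = four_model.spec
        for j, pid in enumerate(four_model.population_ids):
            expected = np.zeros(four_model.n)
            for c in spec.connections:
                if c.target == pid:
                    expected[four_model.index_map.v[c.index]] = 1.0
            np.testing.assert_array_equal(four_model.gamma[j], expected)

    def test_dangling_source_rejected(self):
        spec = networks.single_region()
        import dataclasses
        bad = dataclasses.replace(spec.connections[1], source="e9")
        with pytest.raises(KeyError):
            dataclasses.replace(spec, connections=(spec.connections[0], bad)
                                + spec.connections[2:])


class TestEulerStep:
    def test_origin_with_zero_gains_is_fixed(self, single_model):
        xi = np.zeros(single_model.n)
        np.testing.assert_array_equal(single_model.euler_step(xi, 0.0), xi)

    def test_parameters_invariant(self, four_model):
        rng = np.random.default_rng(3)
        xi = rng.normal(0, 10, four_model.n)
        out = four_model.euler_step(xi, 220.0)
        ia = four_model.index_map.alpha
        np.testing.assert_array_equal(out[ia], xi[ia])

    def test_single_connection_steady_state(self):
        # one connection driven by constant input converges to alpha*tau*phi
        spec = networks.single_region()
        model = build_state_space(spec)
        xi = np.zeros(model.n)
        xi[model.index_map.alpha[0]] = 3.2     # u->p connection only
        u = 220.0
        for _ in range(20000):
            xi_next = model.euler_step(xi, u)
            # freeze every other connection at zero to isolate the u->p stage
            keep = np.zeros(model.n, dtype=bool)
            keep[[model.index_map.v[0], model.index_map.z[0]]] = True
            keep[model.index_map.alpha] = True
            xi = np.where(keep, xi_next, 0.0)
        v_star = 3.2 * spec.connections[0].tau * u
        assert xi[model.index_map.v[0]] == pytest.approx(v_star, rel=1e-4)

    def test_discretized_impulse_response_approaches_kernel(self):
        # the (v, z) stage driven by a unit-area firing-rate impulse is the
        # synaptic kernel (for alpha = 1); the Euler discretization converges
        # to it as the step shrinks
        tau, alpha = 0.010, 1.0
        def impulse_response(delta):
            n = int(round(0.08 / delta))
            v = z = 0.0
            out = np.empty(n)
            times = delta * np.arange(1, n + 1)
            for k in range(n):
                phi = 1.0 / delta if k == 0 else 0.0   # unit-area impulse
                v, z = v + delta * z, z + delta * (
                    alpha / tau * phi - 2 / tau * z - v / tau**2)
                out[k] = v
            return times, out
        tc, coarse = impulse_response(0.001)
        tf, fine = impulse_response(0.00001)
        err_coarse = np.max(np.abs(coarse - postsynaptic_kernel(tc, tau)))
        err_fine = np.max(np.abs(fine - postsynaptic_kernel(tf, tau)))
        assert err_fine < err_coarse / 10
        assert err_fine < 5e-3 * np.exp(-1)


class TestSteadyState:
    def test_drift_vanishes_at_fixed_point(self, single_model):
        xi = steady_state(single_model)
        out = single_model.rhs(xi, single_model.spec.input_mean)
        assert np.max(np.abs(out)) < 1e-6

    def test_four_region_fixed_point(self, four_model):
        xi = steady_state(four_model)
        out = four_model.rhs(xi, four_model.spec.input_mean)
        assert np.max(np.abs(out)) < 1e-5
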