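"""Filter tests: analytic sigmoid moments, unscented transform, updates."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erf

import masskf.kalman as K
from masskf import simulator as sim
from masskf.statespace import build_state_space, mean_firing_rate, steady_state


def quadrature_expected_rate(mu, var, v0=6.0, slope=3.0):
    """Independent oracle: numeric expectation of the sigmoid of a Gaussian."""
    if var == 0:
        return mean_firing_rate(mu, v0, slope)
    sd = np.sqrt(var)
    f = lambda x: mean_firing_rate(x, v0, slope) * \
        np.exp(-(x - mu)**2 / (2 * var)) / (sd * np.sqrt(2 * np.pi))
    val, _ = quad(f, mu - 12 * sd, mu + 12 * sd, limit=200)
    return val


class TestAnalyticExpectedRate:
    def test_zero_variance_reduces_to_sigmoid(self):
        for v in (-3.0, 6.0, 11.5):
            assert K.analytic_expected_rate(v, 0.0, 6.0, 3.0) == \
                pytest.approx(mean_firing_rate(v, 6.0, 3.0))

    def test_half_at_threshold_any_variance(self):
        for var in (0.0, 1.0, 50.0):
            assert K.analytic_expected_rate(6.0, var, 6.0, 3.0) == \
                pytest.approx(0.5)

    def test_known_value(self):
        # frozen from the quadrature oracle at mu=9, var=7
        oracle = quadrature_expected_rate(9.0, 7.0)
        assert oracle == pytest.approx(0.77337, abs=2e-5)
        assert K.analytic_expected_rate(9.0, 7.0, 6.0, 3.0) == \
            pytest.approx(oracle, abs=1e-9)

    def test_matches_quadrature_on_grid_to_4_decimals(self):
        for mu in np.linspace(-20, 40, 13):
            for var in (0.0, 0.5, 4.0, 25.0, 100.0):
                assert K.analytic_expected_rate(mu, var, 6.0, 3.0) == \
                    pytest.approx(quadrature_expected_rate(mu, var), abs=1e-4)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            K.analytic_expected_rate(0.0, -1.0, 6.0, 3.0)


class TestSigmaPoints:
    def test_scalar_unit_gaussian(self):
        state = K.AugmentedState(np.zeros(1), np.eye(1))
        X, wm, wc = K.sigma_points(state, K.FilterConfig())
        assert X.shape == (1, 3)
        assert X[0, 0] == 0.0
        assert X[0, 1] == -X[0, 2] != 0.0
        assert X @ wm == pytest.approx(0.0)
        assert ((X - 0.0)**2 @ wc) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 15, 40])
    def test_reconstruction_identities(self, n):
        rng = np.random.default_rng(n)
        A = rng.normal(size=(n, n))
        cov = A @ A.T + n * np.eye(n)
        mean = rng.normal(0, 5, n)
        X, wm, wc = K.sigma_points(K.AugmentedState(mean, cov),
                                   K.FilterConfig())
        np.testing.assert_allclose(X @ wm, mean, atol=1e-10)
        Y = X - mean[:, None]
        np.testing.assert_allclose((Y * wc) @ Y.T, cov, atol=1e-8)

    def test_parameter_coordinates_respect_bounds(self, single_model):
        cfg = K.FilterConfig()
        x0, P0, Q, R, lo, hi, _ = K.materialize(single_model, cfg, 1)
        state = K.AugmentedState(x0, 4 * P0)
        X, _, _ = K.sigma_points(state, cfg, lo, hi)
        ia = single_model.index_map.alpha
        assert np.all(X[ia] >= lo[ia][:, None] - 1e-12)
        assert np.all(X[ia] <= hi[ia][:, None] + 1e-12)

    def test_indefinite_covariance_reported(self):
        state = K.AugmentedState(np.zeros(2), np.diag([1.0, -1.0]))
        with pytest.raises(np.linalg.LinAlgError):
            K.sigma_points(state, K.FilterConfig())


class TestPopulationMoments:
    def test_moments_match_direct_projection(self, single_model):
        rng = np.random.default_rng(1)
        mean = rng.normal(0, 5, 15)
        S = rng.normal(size=(15, 15))
        P = S @ S.T
        v_hat, var_hat = K.population_moments(
            single_model, K.AugmentedState(mean, P))
        assert v_hat.shape == var_hat.shape == (3,)
        for j, row in enumerate(single_model.gamma):
            assert v_hat[j] == pytest.approx(row @ mean)
            assert var_hat[j] == pytest.approx(row @ P @ row)
        assert np.all(var_hat >= 0)


class TestPredict:
    def test_zero_covariance_equals_euler_step(self, single_model):
        xi = steady_state(single_model) + 0.5
        post = K.AugmentedState(xi, np.zeros((15, 15)))
        m_prior = K.predict_mean(single_model, post, 220.0)
        np.testing.assert_allclose(m_prior,
                                   single_model.euler_step(xi, 220.0),
                                   atol=1e-12)

    def test_parameter_entries_unchanged(self, single_model):
        rng = np.random.default_rng(2)
        xi = rng.normal(0, 5, 15)
        P = np.eye(15) * 4.0
        m_prior = K.predict_mean(single_model,
                                 K.AugmentedState(xi, P), 220.0)
        ia = single_model.index_map.alpha
        np.testing.assert_array_equal(m_prior[ia], xi[ia])

    def test_analytic_mean_beats_sigma_mean_against_monte_carlo(
            self, single_model):
        # propagate a broad Gaussian belief one step; compare both prior
        # means to a large-sample Monte-Carlo push-through
        rng = np.random.default_rng(8)
        mean = steady_state(single_model)
        sd = np.zeros(15)
        im = single_model.index_map
        sd[im.v] = 4.0
        P = np.diag(sd**2)
        samples = rng.normal(size=(10**6, 15)) * sd + mean
        stepped = np.array([0.0])
        prop = K._Propagator(single_model)
        mc = prop.step(samples.T, 220.0).mean(axis=1)
        post = K.AugmentedState(mean, P)
        analytic = K.predict_mean(single_model, post, 220.0)
        X, wm, _ = K.sigma_points(post, K.FilterConfig())
        sigma_mean = prop.step(X, 220.0) @ wm
        err_analytic = np.abs(analytic - mc)
        err_sigma = np.abs(sigma_mean - mc)
        mc_se = prop.step(samples[:1000].T, 220.0).std(axis=1) / np.sqrt(1000)
        assert np.all(err_analytic <= np.maximum(3 * mc_se, 1e-9))
        z_rows = im.z[single_model.source_pop >= 0]
        assert err_analytic[z_rows].sum() < err_sigma[z_rows].sum()

    def test_linear_double_matches_closed_form(self, single_model):
        # with the sigmoid replaced by identity the UT prediction is exact:
        # P_prior = Ad P Ad^T + Q for the purely linear part of the model
        cfg = K.FilterConfig()
        n = 15
        rng = np.random.default_rng(4)
        A_lin = np.eye(n) + 0.001 * single_model.A    # drop B/D nonlinearity
        mean = rng.normal(0, 3, n)
        S = rng.normal(size=(n, n))
        P = S @ S.T + np.eye(n)
        Q = np.diag(rng.uniform(0, 0.1, n))
        X, wm, wc = K.sigma_points(K.AugmentedState(mean, P), cfg)
        Xp = A_lin @ X
        P_prior = K.predict_cov(Xp, A_lin @ mean, wc, Q)
        np.testing.assert_allclose(P_prior, A_lin @ P @ A_lin.T + Q,
                                   atol=1e-8)

    def test_zero_q_zero_p_gives_zero_prior_cov(self, single_model):
        cfg = K.FilterConfig()
        mean = steady_state(single_model)
        X, wm, wc = K.sigma_points(
            K.AugmentedState(mean, np.zeros((15, 15))), cfg)
        prop = K._Propagator(single_model)
        Xp = prop.step(X, 220.0)
        P_prior = K.predict_cov(Xp, Xp @ wm, wc, np.zeros((15, 15)))
        # zero up to the Cholesky jitter floor used for degenerate beliefs
        np.testing.assert_allclose(P_prior, 0.0, atol=1e-6)


class TestUpdate:
    def _setup(self, n=6, m=2, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.normal(size=(n, n))
        P = S @ S.T + np.eye(n)
        mean = rng.normal(0, 2, n)
        H = rng.normal(size=(m, n))
        return K.AugmentedState(mean, P, tag="prior"), H, rng

    def test_huge_r_keeps_prior(self):
        prior, H, rng = self._setup()
        y = rng.normal(0, 1, 2)
        post, _ = K.update(prior, y, H, 1e12 * np.eye(2))
        np.testing.assert_allclose(post.mean, prior.mean, atol=1e-6)
        np.testing.assert_allclose(post.cov, prior.cov, rtol=1e-6)

    def test_tiny_r_reproduces_measurement(self):
        rng = np.random.default_rng(1)
        H = rng.normal(size=(4, 4))          # square invertible montage
        S = rng.normal(size=(4, 4))
        prior = K.AugmentedState(rng.normal(0, 2, 4), S @ S.T + np.eye(4),
                                 tag="prior")
        y = rng.normal(0, 5, 4)
        post, _ = K.update(prior, y, H, 1e-12 * np.eye(4))
        np.testing.assert_allclose(H @ post.mean, y, atol=1e-5)

    def test_posterior_variance_never_exceeds_prior(self):
        prior, H, rng = self._setup(seed=3)
        post, _ = K.update(prior, rng.normal(0, 1, 2), H, np.eye(2))
        assert np.all(np.diag(post.cov) <= np.diag(prior.cov) + 1e-12)

    def test_gain_clipping(self, single_model):
        cfg = K.FilterConfig()
        x0, P0, Q, R, lo, hi, _ = K.materialize(single_model, cfg, 1)
        ia = single_model.index_map.alpha
        state = K.AugmentedState(x0, P0)
        state.mean[ia[0]] = 350.0      # above the input-gain upper bound
        state.mean[ia[3]] = -50000.0   # below the inhibitory lower bound
        clipped = K.clip(state, lo, hi)
        assert clipped.mean[ia[0]] == 300.0
        assert clipped.mean[ia[3]] == -40000.0
        inb = K.clip(clipped, lo, hi)
        np.testing.assert_array_equal(inb.mean, clipped.mean)
        np.testing.assert_array_equal(inb.cov, state.cov)


class TestLinearReduction:
    """With the sigmoid bypassed both variants are the textbook Kalman filter."""

    def _textbook_kf(self, A, H, Q, R, x0, P0, ys):
        x, P = x0.copy(), P0.copy()
        means = []
        for y in ys:
            x = A @ x
            P = A @ P @ A.T + Q
            S = H @ P @ H.T + R
            Kg = P @ H.T @ np.linalg.inv(S)
            x = x + Kg @ (y - H @ x)
            P = (np.eye(len(x)) - Kg @ H) @ P
            means.append(x.copy())
        return np.array(means)

    @pytest.mark.parametrize("variant", ["analytic", "ukf"])
    def test_matches_textbook_filter(self, variant, monkeypatch):
        rng = np.random.default_rng(12)
        n, m, T = 6, 2, 200
        A = np.eye(n) + 0.01 * rng.normal(size=(n, n))
        H = rng.normal(size=(m, n))
        Q = 0.01 * np.eye(n)
        R = 0.1 * np.eye(m)
        x0 = rng.normal(0, 1, n)
        P0 = np.eye(n)
        ys = rng.normal(0, 1, (T, m))

        # drive masskf's machinery with a linear test double
        cfg = K.FilterConfig()
        scale, wm, wc = cfg.ut.weights(n)
        x, P = x0.copy(), P0.copy()
        means = []
        lo = np.full(n, -np.inf)
        hi = np.full(n, np.inf)
        for y in ys:
            post = K.AugmentedState(x, P)
            X, wm, wc = K.sigma_points(post, cfg, lo, hi)
            Xp = A @ X
            m_prior = A @ x if variant == "analytic" else Xp @ wm
            P_prior = K.predict_cov(Xp, m_prior, wc, Q)
            post2, _ = K.update(
                K.AugmentedState(m_prior, P_prior, tag="prior"), y, H, R,
                lo, hi)
            x, P = post2.mean, post2.cov
            means.append(x.copy())
        np.testing.assert_allclose(np.array(means),
                                   self._textbook_kf(A, H, Q, R, x0, P0, ys),
                                   rtol=1e-7, atol=1e-9)


class TestRunFilter:
    def test_state_tracking_with_pinned_parameters(self, single_model):
        scen = sim.alpha_single_scenario(duration=8.0)
        res = sim.simulate(scen, seed=21, model=single_model)
        true_g = scen.spec.true_gains()
        x0 = steady_state(single_model, gains=true_g)
        n = single_model.n
        P0 = np.zeros(n)
        im = single_model.index_map
        P0[im.v] = 100.0
        P0[im.z] = 600.0**2
        cfg = K.FilterConfig(x0=x0, P0=np.diag(P0), q_zin_std=10.0,
                             param_inflation_rel=0.0)
        est = K.run_filter(single_model, res.ecog, cfg, H=res.montage)
        rms = [np.sqrt(np.mean((est.psp(i)[-1000:] - res.psp(i)[-1000:])**2))
               for i in range(5)]
        assert max(rms) < 0.5          # well under the 1 mV noise floor

    def test_gains_never_escape_bounds(self, single_model):
        scen = sim.alpha_single_scenario(duration=3.0)
        res = sim.simulate(scen, seed=5, model=single_model)
        cfg = K.FilterConfig(param_inflation_rel=1e-3)
        est = K.run_filter(single_model, res.ecog, cfg, H=res.montage)
        lo, hi = scen.spec.gain_bounds()
        g = est.gains()
        assert np.all(g >= lo - 1e-9)
        assert np.all(g <= hi + 1e-9)

    def test_bitwise_reproducible(self, single_model):
        scen = sim.alpha_single_scenario(duration=1.0)
        res = sim.simulate(scen, seed=2, model=single_model)
        cfg = K.FilterConfig(param_inflation_rel=1e-3)
        e1 = K.run_filter(single_model, res.ecog, cfg, H=res.montage)
        e2 = K.run_filter(single_model, res.ecog, cfg, H=res.montage)
        np.testing.assert_array_equal(e1.means, e2.means)
        np.testing.assert_array_equal(e1.stds, e2.stds)

    def test_covariance_stays_symmetric_psd(self, single_model):
        # spot-check via posterior stds being finite and real over a run
        scen = sim.alpha_single_scenario(duration=2.0)
        res = sim.simulate(scen, seed=6, model=single_model)
        est = K.run_filter(single_model, res.ecog,
                           K.FilterConfig(param_inflation_rel=1e-3),
                           H=res.montage)
        assert np.all(np.isfinite(est.stds))

    def test_unknown_variant_rejected(self, single_model):
        with pytest.raises(ValueError):
            K.run_filter(single_model, np.zeros((10, 1)), variant="ekf")
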