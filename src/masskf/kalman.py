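"""Joint state-parameter estimation for the neural mass network.

The filter is a constrained Kalman filter over the augmented state
(synaptic PSPs, their derivatives, and the connectivity gains).  Two
variants share the same unscented-transform covariance prediction and
linear measurement update and differ only in the prior-mean prediction:

``analytic``
    The expectation of the sigmoid of a Gaussian membrane potential has a
    closed form — for X ~ N(mu, s2) and the error-function activation g,
    E[g(X)] = Phi((mu - v0) / sqrt(sigma^2 + s2)) — so the prior mean is
    propagated exactly through the nonlinearity (up to the factorization
    E[(B xi) o g(C xi)] ~= (B xi_hat) o E[g(C xi_hat)], which ignores the
    gain/potential cross-correlation and becomes exact as the gain
    estimates converge).

``ukf``
    The standard unscented Kalman filter: the prior mean is the weighted
    mean of the propagated sigma points.

Physiological bounds on the gains are enforced by clipping: parameter
coordinates of the sigma points and of every prior/posterior mean are
clamped to the bounds; covariances are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .networks import NetworkSpec
from .statespace import StateSpaceModel, build_state_space, steady_state

#: default initial standard deviations of the state entries, taken from the
#: spread of noise-free forward simulations (PSPs swing ~10 mV around their
#: mean; their derivatives ~2*pi*10Hz times that)
DEFAULT_P0_V_STD = 10.0       # mV
DEFAULT_P0_Z_STD = 600.0      # mV/s

#: default per-step process-noise standard deviations used for inversion
DEFAULT_Q_V_STD = 1e-3        # mV, PSP rows (model-mismatch floor)
DEFAULT_Q_Z_STD = 0.02        # mV/s, derivative rows
DEFAULT_Q_ZIN_STD = 7.0       # mV/s, derivative rows of input synapses


def analytic_expected_rate(mean, variance, v0, sigma_slope):
    """Closed-form E[g(X)] for X ~ N(mean, variance), g the erf sigmoid.

    Reduces to the plain sigmoid at zero variance; flattens with growing
    variance (the extra spread adds to the firing-threshold variance).
    """
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ValueError("variance must be >= 0")
    mean = np.asarray(mean, dtype=float)
    denom = np.sqrt(2.0 * (sigma_slope**2 + variance))
    out = 0.5 * (erf((mean - v0) / denom) + 1.0)
    return out if out.ndim else float(out)


@dataclass
class AugmentedState:
    """Gaussian belief over the augmented state vector."""

    mean: np.ndarray
    cov: np.ndarray
    tag: str = "posterior"        # "prior" or "posterior"

    def std(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


@dataclass(frozen=True)
class UTParams:
    """Scaled symmetric unscented-transform constants.

    ``spread`` fixes the per-axis distance of the off-center points in
    posterior standard deviations independently of the state dimension
    (the effective Julier-style scaling alpha becomes spread/sqrt(n)), so
    the transform samples the sigmoid nonlinearity equally locally for a
    single region or a multi-region network.  Setting ``alpha`` directly
    overrides this.  With alpha = 1, beta = 0, kappa = 0 the set reduces
    to the plain symmetric form with uniform weights 1/(2n) and zero
    center weight, which reproduces the generating mean and covariance
    exactly with non-negative weights at any dimension.
    """

    alpha: float | None = None
    beta: float = 2.0
    kappa: float | str = 0.0
    spread: float = 2.324

    def weights(self, n: int):
        kappa = 3.0 - n if self.kappa == "classic" else self.kappa
        alpha = self.alpha
        if alpha is None:
            alpha = self.spread / np.sqrt(n + kappa)
        lam = alpha**2 * (n + kappa) - n
        c = n + lam
        if c <= 0:
            raise ValueError("ut parameters give non-positive scaling n+lambda")
        wm = np.full(2 * n + 1, 1.0 / (2.0 * c))
        wm[0] = lam / c
        wc = wm.copy()
        wc[0] += 1.0 - alpha**2 + self.beta
        return np.sqrt(c), wm, wc


@dataclass
class FilterConfig:
    """Everything the filter needs besides the model and the data.

    ``q_*_std`` are per-step process-noise standard deviations; ``r_std``
    the assumed measurement noise (mV).  ``param_inflation_rel`` > 0
    switches the filter into tracking mode, adding per-step variance
    ``(param_inflation_rel * |gain estimate|)**2`` (floored at
    ``param_inflation_floor * bound_width``) to every gain entry so the
    estimates can explore and follow slow drift, an added uncertainty
    that stays small relative to the magnitude of each parameter.
    ``input_value`` is the
    input the filter assumes (the mean drive; the realization is unknown
    to it).
    """

    q_v_std: float = DEFAULT_Q_V_STD
    q_z_std: float = DEFAULT_Q_Z_STD
    q_zin_std: float = DEFAULT_Q_ZIN_STD
    r_std: float = 1.0
    p0_v_std: float = DEFAULT_P0_V_STD
    p0_z_std: float = DEFAULT_P0_Z_STD
    p0_param_frac: float = 0.05   # initial gain sd = frac * bound width
    init_gain_frac: float = 0.10  # initial gain guess = frac * active bound
    init_gain_frac_inter: float = 0.02  # weaker prior for long-range coupling
    ut: UTParams = field(default_factory=UTParams)
    param_inflation_rel: float = 3e-3
    param_inflation_floor: float = 1e-3
    param_inflation_decay_s: float = 25.0  # e-folding time; 0 = constant
    param_inflation_min_rel: float = 1e-4  # floor of the decayed rate
    param_inflation_min_rel_input: float | None = None  # override, input gains
    backend: str = "auto"                  # "auto" | "numba" | "numpy"
    input_value: float | None = None
    x0: np.ndarray | None = None
    P0: np.ndarray | None = None
    Q: np.ndarray | None = None
    R: np.ndarray | None = None
    jitter_start: float = 1e-12
    jitter_stop: float = 1e-6

    def __post_init__(self):
        if self.param_inflation_rel < 0:
            raise ValueError("param_inflation_rel must be >= 0")
        for name in ("q_v_std", "q_z_std", "q_zin_std", "r_std",
                     "p0_v_std", "p0_z_std", "p0_param_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def initial_gains(spec: NetworkSpec, frac: float = 0.10,
                  frac_inter: float = 0.02) -> np.ndarray:
    """Best-guess gains for a weakly coupled circuit.

    Each gain starts at a fraction of its physiologically active bound
    (the bound of larger magnitude), i.e. a small coupling of the right
    sign.  Starting weak keeps every population in the responsive
    (unsaturated) part of the sigmoid, so the filter's early sensitivities
    are alive; the estimates then grow toward the data.  Long-range
    (inter-region) pathways start at a smaller fraction, reflecting the
    standard prior that coupling between cortical areas is much weaker
    than coupling within a column.
    """
    lo, hi = spec.gain_bounds()
    f = np.array([frac_inter if c.kind == "inter" else frac
                  for c in spec.connections])
    return np.where(np.abs(lo) > np.abs(hi), f * lo, f * hi)


def materialize(model: StateSpaceModel, config: FilterConfig,
                n_channels: int):
    """Resolve config defaults into concrete x0, P0, Q, R and bound vectors."""
    spec = model.spec
    idx = model.index_map
    n = model.n
    lo_a, hi_a = spec.gain_bounds()
    lo = np.full(n, -np.inf)
    hi = np.full(n, np.inf)
    lo[idx.alpha], hi[idx.alpha] = lo_a, hi_a

    if config.x0 is None:
        x0 = np.zeros(n)
        x0[idx.alpha] = initial_gains(spec, config.init_gain_frac,
                                      config.init_gain_frac_inter)
    else:
        x0 = np.asarray(config.x0, dtype=float).copy()
    if config.P0 is None:
        p0 = np.empty(n)
        p0[idx.v] = config.p0_v_std**2
        p0[idx.z] = config.p0_z_std**2
        p0[idx.alpha] = (config.p0_param_frac * (hi_a - lo_a))**2
        P0 = np.diag(p0)
    else:
        P0 = np.asarray(config.P0, dtype=float).copy()
    if config.Q is None:
        q = np.empty(n)
        q[idx.v] = config.q_v_std**2
        q[idx.z] = config.q_z_std**2
        for c in spec.connections:
            if c.kind == "input":
                q[idx.z[c.index]] = config.q_zin_std**2
        q[idx.alpha] = 0.0
        Q = np.diag(q)
    else:
        Q = np.asarray(config.Q, dtype=float).copy()
    if config.R is None:
        R = config.r_std**2 * np.eye(n_channels)
    else:
        R = np.asarray(config.R, dtype=float).copy()
    floor = config.param_inflation_floor * (hi_a - lo_a)
    return x0, P0, Q, R, lo, hi, floor


def clip(state: AugmentedState, lo: np.ndarray,
         hi: np.ndarray) -> AugmentedState:
    """Clamp the mean elementwise into [lo, hi]; covariance untouched."""
    return replace(state, mean=np.clip(state.mean, lo, hi))


def _chol_with_jitter(P: np.ndarray, start: float, stop: float) -> np.ndarray:
    scale = max(np.trace(P) / len(P), 1.0)
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    jitter = start
    while jitter <= stop:
        try:
            return np.linalg.cholesky(P + jitter * scale * np.eye(len(P)))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError("covariance is numerically indefinite")


def sigma_points(state: AugmentedState, config: FilterConfig,
                 lo: np.ndarray | None = None, hi: np.ndarray | None = None):
    """Symmetric sigma-point set (n, 2n+1) with mean/covariance weights.

    If bounds are given, every point's parameter coordinates are clamped
    into them (constraining the sample space of the transform).
    """
    n = len(state.mean)
    scale, wm, wc = config.ut.weights(n)
    L = _chol_with_jitter(state.cov, config.jitter_start, config.jitter_stop)
    X = np.empty((n, 2 * n + 1))
    X[:, 0] = state.mean
    X[:, 1:n + 1] = state.mean[:, None] + scale * L
    X[:, n + 1:] = state.mean[:, None] - scale * L
    if lo is not None:
        bounded = np.isfinite(lo) | np.isfinite(hi)
        for r in np.flatnonzero(bounded):
            m_r = state.mean[r]
            room = min(hi[r] - m_r, m_r - lo[r])
            d = X[r, 1:n + 1] - m_r
            if room > 0:
                f = np.minimum(1.0, room / np.maximum(np.abs(d), 1e-300))
                X[r, 1:n + 1] = m_r + d * f
                X[r, n + 1:] = m_r - d * f
            else:
                np.clip(X[r], lo[r], hi[r], out=X[r])
    return X, wm, wc


class _Propagator:
    """Precomputed index machinery for fast Euler propagation."""

    def __init__(self, model: StateSpaceModel):
        spec = model.spec
        idx = model.index_map
        self.model = model
        self.delta = spec.delta
        self.v_idx = idx.v
        self.z_idx = idx.z
        self.a_idx = idx.alpha
        self.tau = np.array([c.tau for c in spec.connections])
        self.internal = model.source_pop >= 0
        self.src = model.source_pop[self.internal]
        self.gamma = model.gamma
        self.v0 = spec.v0
        self.slope = spec.sigma_slope

    def rates(self, X):
        """Sigmoid firing rate of every internal population, per column."""
        arg = (self.gamma @ X - self.v0) / (np.sqrt(2.0) * self.slope)
        return 0.5 * (erf(arg) + 1.0)

    def drive(self, X, u, rates):
        d = np.empty((len(self.tau),) + X.shape[1:])
        d[~self.internal] = u
        d[self.internal] = rates[self.src]
        return d

    def step(self, X, u, rates=None):
        """Euler step of a point (1-D) or point set (2-D, columns)."""
        if rates is None:
            rates = self.rates(X)
        V, Z, A = X[self.v_idx], X[self.z_idx], X[self.a_idx]
        tau = self.tau if X.ndim == 1 else self.tau[:, None]
        out = X.copy()
        out[self.v_idx] += self.delta * Z
        out[self.z_idx] += self.delta * (
            (A * self.drive(X, u, rates) - 2.0 * Z) / tau - V / tau**2)
        return out

    def expected_rates(self, mean, cov):
        """Analytic E[g] per population from the joint belief."""
        mu = self.gamma @ mean
        var = np.einsum("ij,ij->i", self.gamma @ cov, self.gamma)
        var = np.clip(var, 0.0, None)
        return analytic_expected_rate(mu, var, self.v0, self.slope)


def population_moments(model: StateSpaceModel, state: AugmentedState):
    """Mean and variance of each internal population's membrane potential.

    Returns ``(v_hat, var_hat)``, where ``v_hat[j] = gamma_j @ mean`` and
    ``var_hat[j] = gamma_j P gamma_j^T``; rows are ordered like
    ``model.population_ids``.  These are the Gaussian moments fed to the
    closed-form expected firing rate.
    """
    v_hat = model.gamma @ state.mean
    var_hat = np.clip(np.einsum("ij,ij->i", model.gamma @ state.cov,
                                model.gamma), 0.0, None)
    return v_hat, var_hat


def predict_mean(model: StateSpaceModel, posterior: AugmentedState,
                 u: float, prop: _Propagator | None = None) -> np.ndarray:
    """Prior mean via the analytic expectation of the sigmoid.

    Identical to a noise-free Euler step of the mean except that each
    population's firing rate is replaced by its closed-form expectation
    under the posterior belief; gain entries pass through unchanged.
    """
    if not np.all(np.isfinite(posterior.mean)):
        raise FloatingPointError("non-finite posterior mean")
    prop = _Propagator(model) if prop is None else prop
    rates = prop.expected_rates(posterior.mean, posterior.cov)
    return prop.step(posterior.mean, u, rates=rates)


def predict_cov(Xp: np.ndarray, prior_mean: np.ndarray, wc: np.ndarray,
                Q: np.ndarray) -> np.ndarray:
    """Weighted scatter of propagated sigma points about the prior mean."""
    Y = Xp - prior_mean[:, None]
    P = (Y * wc) @ Y.T + Q
    return 0.5 * (P + P.T)


def update(prior: AugmentedState, y: np.ndarray, H: np.ndarray,
           R: np.ndarray, lo: np.ndarray | None = None,
           hi: np.ndarray | None = None):
    """Linear measurement update (Joseph-stabilized) plus gain clipping."""
    y = np.atleast_1d(y)
    if y.shape[0] != H.shape[0]:
        raise ValueError("measurement dimension does not match montage")
    PHt = prior.cov @ H.T
    S = H @ PHt + R
    innov = y - H @ prior.mean
    try:
        K = np.linalg.solve(S, PHt.T).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular innovation covariance") from err
    mean = prior.mean + K @ innov
    IKH = np.eye(len(mean)) - K @ H
    cov = IKH @ prior.cov @ IKH.T + K @ R @ K.T
    cov = 0.5 * (cov + cov.T)
    if lo is not None:
        mean = np.clip(mean, lo, hi)
    return AugmentedState(mean, cov, tag="posterior"), innov


@dataclass
class EstimationResult:
    """Per-step posterior summary of a filtering run."""

    variant: str
    times: np.ndarray
    means: np.ndarray            # (n_steps, n_augmented) posterior means
    stds: np.ndarray             # (n_steps, n_augmented) posterior sds
    innovations: np.ndarray      # (n_steps, n_channels)
    model: StateSpaceModel

    def gains(self) -> np.ndarray:
        return self.means[:, self.model.index_map.alpha]

    def gain_stds(self) -> np.ndarray:
        return self.stds[:, self.model.index_map.alpha]

    def psp(self, connection_index: int) -> np.ndarray:
        return self.means[:, self.model.index_map.v[connection_index]]

    def terminal_gains(self) -> np.ndarray:
        return self.gains()[-1]


def run_filter(model: StateSpaceModel, measurements: np.ndarray,
               config: FilterConfig | None = None,
               variant: str = "analytic",
               H: np.ndarray | None = None,
               progress: bool = False) -> EstimationResult:
    """Sequential predict/update over an ECoG recording.

    ``measurements`` is (n_steps, n_channels) sampled at the model step.
    The input realization is unknown to the filter: prediction uses the
    constant mean drive.  Raises ``FloatingPointError`` with the step
    index if the estimate diverges.
    """
    if config is None:
        config = FilterConfig()
    if variant not in ("analytic", "ukf"):
        raise ValueError("variant must be 'analytic' or 'ukf'")
    ys = np.atleast_2d(np.asarray(measurements, dtype=float))
    if ys.shape[0] < ys.shape[1]:
        raise ValueError("measurements must be (n_steps, n_channels)")
    if H is None:
        from .simulator import build_montage
        H = build_montage(model.spec)
    n_steps, n_ch = ys.shape
    x0, P0, Q, R, lo, hi, infl_floor = materialize(model, config, n_ch)
    infl_rel = config.param_inflation_rel
    decay = config.param_inflation_decay_s
    min_rel_vec = _min_rel_vector(model, config)
    if config.backend not in ("auto", "numba", "numpy"):
        raise ValueError("backend must be auto, numba or numpy")
    use_fast = config.backend in ("auto", "numba") and not progress
    if use_fast:
        from . import _fastpath
        if _fastpath.HAVE_NUMBA or config.backend == "numba":
            return _run_fast(model, ys, config, variant, H, x0, P0, Q, R,
                             lo, hi, infl_floor)
    prop = _Propagator(model)
    a_idx = model.index_map.alpha
    u = model.spec.input_mean if config.input_value is None \
        else config.input_value

    post = AugmentedState(x0.copy(), P0.copy())
    means = np.empty((n_steps, model.n))
    stds = np.empty((n_steps, model.n))
    innovs = np.empty((n_steps, n_ch))
    for t in range(n_steps):
        X, wm, wc = sigma_points(post, config, lo, hi)
        Xp = prop.step(X, u)
        if variant == "analytic":
            m_prior = predict_mean(model, post, u, prop=prop)
        else:
            m_prior = Xp @ wm
        np.clip(m_prior, lo, hi, out=m_prior)
        P_prior = predict_cov(Xp, m_prior, wc, Q)
        if infl_rel > 0:
            base_rel = infl_rel if decay <= 0 else \
                infl_rel * np.exp(-t * model.spec.delta / decay)
            rel = np.maximum(base_rel, min_rel_vec)
            step_sd = rel * np.maximum(np.abs(m_prior[a_idx]), infl_floor)
            P_prior[a_idx, a_idx] += step_sd**2
        prior = AugmentedState(m_prior, P_prior, tag="prior")
        post, innov = update(prior, ys[t], H, R, lo, hi)
        if not np.all(np.isfinite(post.mean)):
            raise FloatingPointError(f"filter diverged at step {t}")
        means[t] = post.mean
        stds[t] = post.std()
        innovs[t] = innov
        if progress and (t + 1) % 1000 == 0:
            _log_innovation(t + 1, model.spec.delta, innovs)
    times = model.spec.delta * np.arange(1, n_steps + 1)
    return EstimationResult(variant=variant, times=times, means=means,
                            stds=stds, innovations=innovs, model=model)


def _log_innovation(step: int, delta: float, innovs: np.ndarray) -> None:
    import logging
    sl = innovs[max(0, step - 1000):step]
    logging.getLogger("masskf").info(
        "t=%.1fs innovation rms=%.3f mV", step * delta,
        float(np.sqrt(np.mean(sl**2))))


def _min_rel_vector(model, config: FilterConfig) -> np.ndarray:
    """Per-connection floor of the decayed inflation rate."""
    out = np.full(model.spec.n_connections, config.param_inflation_min_rel,
                  dtype=float)
    if config.param_inflation_min_rel_input is not None:
        for c in model.spec.connections:
            if c.kind == "input":
                out[c.index] = config.param_inflation_min_rel_input
    return out


def _run_fast(model, ys, config, variant, H, x0, P0, Q, R, lo, hi,
              infl_floor) -> EstimationResult:
    """Dispatch to the compiled inner loop (numba)."""
    from ._fastpath import _filter_loop

    spec = model.spec
    idx = model.index_map
    scale, wm, wc = config.ut.weights(model.n)
    tau = np.array([c.tau for c in spec.connections])
    internal = model.source_pop >= 0
    src = np.where(internal, model.source_pop, 0).astype(np.int64)
    u = spec.input_mean if config.input_value is None else config.input_value
    means, stds, innovs, fail_step, code = _filter_loop(
        np.ascontiguousarray(ys), x0, P0, Q, R,
        np.ascontiguousarray(H, dtype=float), lo, hi,
        idx.v.astype(np.int64), idx.z.astype(np.int64),
        idx.alpha.astype(np.int64), tau, internal, src,
        np.ascontiguousarray(model.gamma), float(spec.v0),
        float(spec.sigma_slope), float(spec.delta), float(u), float(scale),
        wm, wc, float(config.param_inflation_rel),
        np.asarray(infl_floor, dtype=float),
        float(config.param_inflation_decay_s),
        _min_rel_vector(model, config), variant == "analytic",
        float(config.jitter_start), float(config.jitter_stop))
    if code == 1:
        raise np.linalg.LinAlgError(
            f"covariance is numerically indefinite at step {fail_step}")
    if code == 2:
        raise FloatingPointError(f"filter diverged at step {fail_step}")
    times = spec.delta * np.arange(1, ys.shape[0] + 1)
    return EstimationResult(variant=variant, times=times, means=means,
                            stds=stds, innovations=innovs, model=model)


def recommended_config(spec: NetworkSpec, tracking: bool = False,
                       **overrides) -> FilterConfig:
    """Filter configuration tuned per network topology.

    Multi-region (differential-montage) inversion carries less absolute-
    level information per channel, so it runs with the full input-synapse
    process noise and a tighter initial gain spread.  ``tracking=True``
    keeps a sustained inflation floor so gain estimates can follow slow
    parameter drift (seizure transitions).
    """
    kw = {}
    if spec.n_regions > 1:
        kw.update(q_zin_std=10.0, p0_param_frac=0.02)
    if tracking:
        kw.update(param_inflation_min_rel=1e-3)
    kw.update(overrides)
    return FilterConfig(**kw)


from sklearn.base import BaseEstimator


class NeuralMassKalmanFilter(BaseEstimator):
    """Joint state-parameter estimator with a scikit-learn interface.

    ``fit(y)`` runs the constrained Kalman filter over an ECoG recording
    ``y`` of shape (n_steps, n_channels) sampled at the model step and
    exposes the posterior trajectories as fitted attributes.  Hyper-
    parameters mirror :class:`FilterConfig`; those left ``None`` fall back
    to the topology-dependent recommended values.

    Parameters
    ----------
    spec : NetworkSpec or None
        Network description; a single cortical region by default.
    variant : {"analytic", "ukf"}
        Prior-mean prediction: closed-form sigmoid expectation or the
        weighted sigma-point mean.
    tracking : bool
        Keep a sustained parameter-drift inflation floor (for slowly
        varying gains such as seizure transitions).

    Attributes
    ----------
    gains_ : ndarray of shape (n_steps, n_connections)
        Posterior mean connectivity-gain trajectory.
    gain_stds_ : ndarray of shape (n_steps, n_connections)
        Posterior standard deviations of the gains.
    state_means_, state_stds_ : ndarray of shape (n_steps, n_augmented)
        Full augmented posterior summary.
    innovations_ : ndarray of shape (n_steps, n_channels)
        One-step-ahead measurement residuals.
    result_ : EstimationResult
        The underlying result object.
    """

    def __init__(self, spec=None, variant="analytic", tracking=False,
                 q_v_std=None, q_z_std=None, q_zin_std=None, r_std=None,
                 p0_param_frac=None, init_gain_frac=None,
                 param_inflation_rel=None, param_inflation_decay_s=None,
                 param_inflation_min_rel=None, ut_spread=None, backend=None):
        self.spec = spec
        self.variant = variant
        self.tracking = tracking
        self.q_v_std = q_v_std
        self.q_z_std = q_z_std
        self.q_zin_std = q_zin_std
        self.r_std = r_std
        self.p0_param_frac = p0_param_frac
        self.init_gain_frac = init_gain_frac
        self.param_inflation_rel = param_inflation_rel
        self.param_inflation_decay_s = param_inflation_decay_s
        self.param_inflation_min_rel = param_inflation_min_rel
        self.ut_spread = ut_spread
        self.backend = backend

    def _config(self, spec) -> FilterConfig:
        overrides = {}
        for k in ("q_v_std", "q_z_std", "q_zin_std", "r_std",
                  "p0_param_frac", "init_gain_frac", "param_inflation_rel",
                  "param_inflation_decay_s", "param_inflation_min_rel",
                  "backend"):
            v = getattr(self, k)
            if v is not None:
                overrides[k] = v
        if self.ut_spread is not None:
            overrides["ut"] = UTParams(spread=self.ut_spread)
        return recommended_config(spec, tracking=self.tracking, **overrides)

    # -- estimation --------------------------------------------------------
    def fit(self, y, u=None):
        """Filter a recording; ``u`` optionally overrides the mean drive."""
        from . import networks
        from .simulator import build_montage

        if self.variant not in ("analytic", "ukf"):
            raise ValueError("variant must be 'analytic' or 'ukf'")
        spec = networks.single_region() if self.spec is None else self.spec
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.ndim != 2 or y.shape[0] < y.shape[1]:
            raise ValueError("y must be (n_steps, n_channels)")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        model = build_state_space(spec)
        H = build_montage(spec)
        if y.shape[1] != H.shape[0]:
            raise ValueError(
                f"expected {H.shape[0]} channels for this network, "
                f"got {y.shape[1]}")
        config = self._config(spec)
        if u is not None:
            config = replace(config, input_value=float(u))
        res = run_filter(model, y, config, variant=self.variant, H=H)
        self.model_ = model
        self.result_ = res
        self.n_features_in_ = y.shape[1]
        self.state_means_ = res.means
        self.state_stds_ = res.stds
        self.innovations_ = res.innovations
        self.gains_ = res.gains()
        self.gain_stds_ = res.gain_stds()
        self.terminal_gains_ = res.terminal_gains()
        return self

    def predict(self, y=None):
        """Terminal connectivity-gain estimates of the fitted recording."""
        if not hasattr(self, "result_"):
            raise AttributeError("this estimator is not fitted yet; "
                                 "call fit first")
        return self.terminal_gains_

    def score(self, y=None, true_gains=None):
        """Negative mean terminal percent bias against known true gains."""
        from .metrics import percent_bias
        if true_gains is None:
            raise ValueError("score requires the true gains")
        return -float(np.mean(percent_bias(self.predict(), true_gains)))
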