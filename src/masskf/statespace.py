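"""Augmented state-space form of the neural mass network.

Every synaptic connection ``i`` contributes a post-synaptic potential
``v_i`` (mV) and its derivative ``z_i`` (mV/s) obeying the second-order
synaptic dynamics

    dv_i/dt = z_i
    dz_i/dt = (alpha_i / tau_i) * phi_src(i) - (2 / tau_i) z_i
              - (1 / tau_i**2) v_i,

where ``phi_src`` is the presynaptic firing rate: the external input ``u``
for input connections and ``g(v_source_population)`` otherwise, with ``g``
the error-function sigmoid.  Stacking all (v, z) pairs followed by the
connectivity gains ``alpha`` (which have trivial dynamics, d(alpha)/dt = 0)
yields the augmented vector ``xi`` of dimension ``3 (N + K)`` whose drift
factorizes into

    dxi/dt = A xi + (B xi) o g(C xi) + D(u) xi,

with ``o`` the elementwise product.  ``A`` carries the linear synaptic
relaxation, ``B`` routes ``alpha_i / tau_i`` into the matching ``z`` row,
the rows of ``C`` are population adjacency vectors ``gamma_j`` that sum the
incoming PSPs of the presynaptic population, and ``D(u) = u * D1`` routes
``alpha / tau`` of the input-driven connections.  Rows acting on parameter
entries are identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .networks import NetworkSpec


def postsynaptic_kernel(t, tau):
    """Second-order synaptic response kernel ``(t/tau) exp(-t/tau)`` for t>=0.

    Peaks at ``t = tau`` with amplitude ``1/e``; integrates to ``tau``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (t / tau) * np.exp(-np.clip(t, 0, None) / tau), 0.0)
    return out if out.ndim else float(out)


def mean_firing_rate(v, v0, sigma_slope):
    """Error-function sigmoid mapping membrane potential to normalized rate.

    Equals the Gaussian CDF with mean ``v0`` (firing threshold) and standard
    deviation ``sigma_slope``; strictly increasing, bounded in (0, 1).
    """
    if sigma_slope <= 0:
        raise ValueError("sigma_slope must be positive")
    v = np.asarray(v, dtype=float)
    out = 0.5 * (erf((v - v0) / (np.sqrt(2.0) * sigma_slope)) + 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StateIndexMap:
    """Positions of each connection's v, z and alpha inside ``xi``.

    Ordering: all (v, z) pairs in connection order (intra-region pathways
    first, then inter-region pathways), followed by all gains in the same
    connection order.
    """

    n_connections: int
    v: np.ndarray        # v position per connection
    z: np.ndarray        # z position per connection
    alpha: np.ndarray    # alpha position per connection
    incoming: dict       # population id -> array of incoming-PSP v positions

    @property
    def n_augmented(self) -> int:
        return 3 * self.n_connections

    @classmethod
    def build(cls, spec: NetworkSpec) -> "StateIndexMap":
        nc = spec.n_connections
        v = np.arange(nc) * 2
        z = v + 1
        alpha = 2 * nc + np.arange(nc)
        incoming: dict[str, list[int]] = {p.id: [] for p in spec.populations}
        for c in spec.connections:
            incoming[c.target].append(int(v[c.index]))
        return cls(nc, v, z, alpha,
                   {k: np.array(idx, dtype=int) for k, idx in incoming.items()})


@dataclass(frozen=True)
class StateSpaceModel:
    """Constructed matrices of the augmented model plus index bookkeeping.

    ``A``, ``B``, ``C``, ``D1`` are the continuous-time factors (with
    ``D(u) = u * D1``); ``A_delta = I + delta A`` etc. are their Euler
    discretizations.  ``gamma`` stacks one adjacency row per internal
    population (the rows of ``C`` that are actually passed through the
    sigmoid) and ``source_pop[i]`` gives the ``gamma`` row feeding
    connection ``i`` (-1 for input-driven connections).
    """

    spec: NetworkSpec
    index_map: StateIndexMap
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D1: np.ndarray
    A_delta: np.ndarray
    B_delta: np.ndarray
    D1_delta: np.ndarray
    gamma: np.ndarray
    source_pop: np.ndarray
    population_ids: tuple

    @property
    def n(self) -> int:
        return self.index_map.n_augmented

    def gamma_row(self, population_id: str) -> np.ndarray:
        return self.gamma[self.population_ids.index(population_id)]

    def pyramidal_rows(self) -> dict:
        """Adjacency rows of the pyramidal populations, keyed by region."""
        return {self.spec.population(pid).region: self.gamma[j]
                for j, pid in enumerate(self.population_ids)
                if self.spec.population(pid).kind == "pyramidal"}

    # -- dynamics ----------------------------------------------------------
    def firing_rates(self, xi: np.ndarray) -> np.ndarray:
        """g(gamma xi) for every internal population; works on point sets."""
        return mean_firing_rate(self.gamma @ xi, self.spec.v0,
                                self.spec.sigma_slope)

    def rhs(self, xi: np.ndarray, u: float) -> np.ndarray:
        """Continuous drift ``A xi + (B xi) o g(C xi) + u D1 xi``."""
        xi = np.asarray(xi, dtype=float)
        if xi.shape[0] != self.n:
            raise ValueError(f"xi must have leading dimension {self.n}")
        return (self.A @ xi + (self.B @ xi) * mean_firing_rate(
            self.C @ xi, self.spec.v0, self.spec.sigma_slope)
            + u * (self.D1 @ xi))

    def euler_step(self, xi: np.ndarray, u: float,
                   delta: float | None = None) -> np.ndarray:
        """One noise-free Euler step ``xi + delta F(xi, u)``.

        Parameter entries are returned unchanged (trivial gain dynamics).
        """
        delta = self.spec.delta if delta is None else delta
        if delta <= 0:
            raise ValueError("delta must be positive")
        return np.asarray(xi, dtype=float) + delta * self.rhs(xi, u)


def build_state_space(spec: NetworkSpec) -> StateSpaceModel:
    """Assemble the augmented state-space matrices from a network spec."""
    idx = StateIndexMap.build(spec)
    n = idx.n_augmented
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    C = np.zeros((n, n))
    D1 = np.zeros((n, n))

    internal = [p for p in spec.populations if p.kind != "external_input"]
    pop_ids = tuple(p.id for p in internal)
    gamma = np.zeros((len(internal), n))
    for j, p in enumerate(internal):
        gamma[j, idx.incoming[p.id]] = 1.0

    source_pop = np.full(spec.n_connections, -1, dtype=int)
    for c in spec.connections:
        vi, zi, ai = idx.v[c.index], idx.z[c.index], idx.alpha[c.index]
        A[vi, zi] = 1.0
        A[zi, zi] = -2.0 / c.tau
        A[zi, vi] = -1.0 / c.tau**2
        if c.kind == "input":
            D1[zi, ai] = 1.0 / c.tau
        else:
            j = pop_ids.index(c.source)
            source_pop[c.index] = j
            B[zi, ai] = 1.0 / c.tau
            C[zi] = gamma[j]

    d = spec.delta
    return StateSpaceModel(
        spec=spec, index_map=idx, A=A, B=B, C=C, D1=D1,
        A_delta=np.eye(n) + d * A, B_delta=d * B, D1_delta=d * D1,
        gamma=gamma, source_pop=source_pop, population_ids=pop_ids)


def steady_state(model: StateSpaceModel, gains=None,
                 u: float | None = None) -> np.ndarray:
    """Noise-free fixed point of the dynamics under constant input.

    Solves the self-consistent equations ``v_i = alpha_i tau_i phi_src(i)``
    with all derivatives zero, reducing the problem to one scalar
    root-find per region on the pyramidal potential (inter-region inputs
    are relaxed to self-consistency by fixed-point sweeps).  Used to
    initialize the filter; the fixed point may be dynamically unstable
    (the alpha rhythm is a limit cycle around it), which is irrelevant for
    initialization purposes.
    """
    spec = model.spec
    idx = model.index_map
    u = spec.input_mean if u is None else u
    gains = spec.true_gains() if gains is None else np.asarray(gains, float)
    g = lambda v: mean_firing_rate(v, spec.v0, spec.sigma_slope)

    regions = sorted({p.region for p in spec.populations})
    conns_by_region = {
        r: [c for c in spec.connections
            if c.kind != "inter" and spec.population(c.target).region == r]
        for r in regions}
    inter = [c for c in spec.connections if c.kind == "inter"]
    vp = {r: 0.0 for r in regions}

    def region_residual(v_p, r, inter_in):
        by_label = {c.label: c for c in conns_by_region[r]}
        contrib = gains[by_label["up"].index] * by_label["up"].tau * u
        v_e = gains[by_label["pe"].index] * by_label["pe"].tau * g(v_p)
        v_i = gains[by_label["pi"].index] * by_label["pi"].tau * g(v_p)
        contrib += gains[by_label["ep"].index] * by_label["ep"].tau * g(v_e)
        contrib += gains[by_label["ip"].index] * by_label["ip"].tau * g(v_i)
        return contrib + inter_in - v_p

    for _ in range(60):  # outer sweeps relax the inter-region coupling
        prev = dict(vp)
        for r in regions:
            inter_in = sum(
                gains[c.index] * c.tau * g(vp[spec.population(c.source).region])
                for c in inter if spec.population(c.target).region == r)
            f = lambda v: region_residual(v, r, inter_in)
            lo, hi = -500.0, 500.0
            if f(lo) * f(hi) > 0:      # saturated regime; pick nearer end
                vp[r] = lo if abs(f(lo)) < abs(f(hi)) else hi
            else:
                vp[r] = brentq(f, lo, hi, xtol=1e-10)
        if max(abs(vp[r] - prev[r]) for r in regions) < 1e-12:
            break

    xi = np.zeros(idx.n_augmented)
    xi[idx.alpha] = gains
    for c in spec.connections:
        if c.kind == "input":
            phi = u
        else:
            src = spec.population(c.source)
            if src.kind == "pyramidal":
                v_src = vp[src.region]
            else:
                r = src.region
                by_label = {cc.label: cc for cc in conns_by_region[r]}
                label = "pe" if src.kind == "spiny_stellate" else "pi"
                cc = by_label[label]
                v_src = gains[cc.index] * cc.tau * g(vp[r])
            phi = g(v_src)
        xi[idx.v[c.index]] = gains[c.index] * c.tau * phi
    return xi
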