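"""Forward simulation of multichannel ECoG from the neural mass network.

The simulator integrates the discretized augmented model at the model time
step (1 ms by default) under a white Gaussian firing-rate input, adds
process noise as an extra driving term on the input-driven synapses, and
reads the signal out through a measurement montage: for a single region
the ECoG channel is the pyramidal population's summed incoming PSPs; for
the four-region ring each channel is the difference of neighbouring
pyramidal potentials (a differential/bipolar montage that rejects common
mode), plus white measurement noise.

True connectivity gains follow a piecewise-linear schedule, constant for
the alpha-rhythm scenarios and ramped for the seizure-transition scenario
in which region 1's excitatory gains rise to epileptogenic values and
return to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import networks
from .networks import NetworkSpec
from .statespace import StateSpaceModel, build_state_space, steady_state

#: default sd of the process-noise drive on input-synapse derivatives, mV/s
DEFAULT_PROCESS_STD = 10.0
#: default sd of the additive ECoG measurement noise, mV
DEFAULT_MEAS_STD = 1.0

#: seizure-ramp timing within the 100 s run, seconds
SEIZURE_RAMP = dict(up_start=30.0, plateau_start=40.0,
                    plateau_end=60.0, down_end=70.0)


@dataclass(frozen=True)
class NoiseModel:
    """Process and measurement noise description for a forward run.

    ``process_cov`` is the full per-step process covariance Q (diagonal by
    construction: nonzero only on the z entries of input-driven synapses,
    where the unmodeled afferent drive enters).  Measurement noise is
    isotropic with standard deviation ``meas_std`` (mV).
    """

    process_cov: np.ndarray
    meas_std: float
    input_mean: float
    input_var: float

    def __post_init__(self):
        Q = self.process_cov
        if not np.allclose(Q, Q.T):
            raise ValueError("process covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(Q) < -1e-12 * max(1.0, Q.max())):
            raise ValueError("process covariance must be PSD")
        if self.meas_std < 0:
            raise ValueError("meas_std must be >= 0")


def default_noise(spec: NetworkSpec,
                  process_std: float = DEFAULT_PROCESS_STD,
                  meas_std: float = DEFAULT_MEAS_STD) -> NoiseModel:
    """Noise model with drive on the z entries of input synapses only."""
    from .statespace import StateIndexMap
    idx = StateIndexMap.build(spec)
    q = np.zeros(idx.n_augmented)
    for c in spec.connections:
        if c.kind == "input":
            q[idx.z[c.index]] = process_std**2
    return NoiseModel(process_cov=np.diag(q), meas_std=meas_std,
                      input_mean=spec.input_mean, input_var=spec.input_variance)


@dataclass(frozen=True)
class GainSchedule:
    """Piecewise-linear true-gain trajectories, one row per connection."""

    knot_times: np.ndarray          # (n_knots,), seconds, increasing
    knot_values: np.ndarray         # (n_connections, n_knots)

    def __call__(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.vstack([np.interp(times, self.knot_times, row)
                         for row in self.knot_values])
        return out

    @classmethod
    def constant(cls, gains: np.ndarray, duration: float) -> "GainSchedule":
        gains = np.asarray(gains, dtype=float)
        return cls(np.array([0.0, duration]),
                   np.column_stack([gains, gains]))


@dataclass(frozen=True)
class Scenario:
    """A reproducible forward-simulation setting."""

    name: str
    spec: NetworkSpec
    duration: float
    schedule: GainSchedule
    noise: NoiseModel

    def __post_init__(self):
        lo, hi = self.spec.gain_bounds()
        vals = self.schedule.knot_values
        if np.any(vals < lo[:, None]) or np.any(vals > hi[:, None]):
            raise ValueError("gain schedule leaves the physiological bounds")


@dataclass
class SimulationResult:
    """Ground-truth trajectories plus the simulated recording."""

    scenario: Scenario
    model: StateSpaceModel
    times: np.ndarray                # (n_steps,), seconds
    states: np.ndarray               # (n_steps, n_augmented), true xi_t
    ecog: np.ndarray                 # (n_steps, n_channels), y_t in mV
    input: np.ndarray                # (n_steps,), u_t realization
    meas_noise: np.ndarray           # (n_steps, n_channels)
    montage: np.ndarray              # H, (n_channels, n_augmented)
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def true_gains(self) -> np.ndarray:
        """(n_steps, n_connections) gain trajectory."""
        return self.states[:, self.model.index_map.alpha]

    def psp(self, connection_index: int) -> np.ndarray:
        return self.states[:, self.model.index_map.v[connection_index]]

    def pyramidal_potentials(self) -> dict:
        """Per-region pyramidal membrane potential (sum of incoming PSPs)."""
        return {r: self.states @ row
                for r, row in self.model.pyramidal_rows().items()}


def draw_input(n_steps: int, noise: NoiseModel,
               rng: np.random.Generator) -> np.ndarray:
    """White Gaussian firing-rate input, mean ``u_m``, variance ``sigma_u^2``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return rng.normal(noise.input_mean, np.sqrt(noise.input_var), size=n_steps)


def build_montage(spec: NetworkSpec) -> np.ndarray:
    """Measurement matrix H mapping ``xi`` to ECoG channels.

    Single region: one channel summing the pyramidal population's incoming
    PSPs.  Multi-region ring: channel j reads region j minus its ring
    successor (j mod J + 1), entries +/-1 on PSP positions only.
    """
    model = build_state_space(spec)
    rows = model.pyramidal_rows()
    J = spec.n_regions
    if J == 1:
        return rows[1][None, :].copy()
    H = np.zeros((J, model.n))
    for j in range(1, J + 1):
        H[j - 1] = rows[j] - rows[j % J + 1]
    return H


def simulate(scenario: Scenario, seed: int | None = None,
             model: StateSpaceModel | None = None) -> SimulationResult:
    """Run the stochastic forward model and record the ECoG.

    The state starts at the noise-free fixed point of the scheduled t=0
    gains; the true gain entries of ``xi`` follow the schedule exactly at
    every step (they are scenario inputs here, not dynamical variables).
    Raises ``FloatingPointError`` with the step index on divergence.
    """
    spec = scenario.spec
    model = build_state_space(spec) if model is None else model
    idx = model.index_map
    delta = spec.delta
    n_steps = int(round(scenario.duration / delta))
    rng = np.random.default_rng(seed)

    H = build_montage(spec)
    u = draw_input(n_steps, scenario.noise, rng)
    q_diag = np.diag(scenario.noise.process_cov)
    noisy = q_diag > 0
    times = delta * np.arange(1, n_steps + 1)
    gains = scenario.schedule(np.concatenate([[0.0], times]))  # (nc, T+1)

    xi = steady_state(model, gains=gains[:, 0])
    states = np.empty((n_steps, model.n))
    for t in range(n_steps):
        xi = model.euler_step(xi, u[t])
        if np.any(noisy):
            xi[noisy] += rng.normal(0.0, np.sqrt(q_diag[noisy]))
        xi[idx.alpha] = gains[:, t + 1]
        if not np.all(np.isfinite(xi)):
            raise FloatingPointError(
                f"forward simulation diverged at step {t + 1}")
        states[t] = xi

    meas_noise = rng.normal(0.0, scenario.noise.meas_std,
                            size=(n_steps, H.shape[0]))
    ecog = states @ H.T + meas_noise
    return SimulationResult(scenario=scenario, model=model, times=times,
                            states=states, ecog=ecog, input=u,
                            meas_noise=meas_noise, montage=H, seed=seed)


# --- benchmark scenarios ----------------------------------------------------

def alpha_single_scenario(duration: float = 60.0,
                          process_std: float = DEFAULT_PROCESS_STD,
                          meas_std: float = DEFAULT_MEAS_STD) -> Scenario:
    """Single cortical region generating an alpha rhythm."""
    spec = networks.single_region()
    return Scenario("alpha1", spec, duration,
                    GainSchedule.constant(spec.true_gains(), duration),
                    default_noise(spec, process_std, meas_std))


def alpha_four_scenario(duration: float = 100.0,
                        process_std: float = DEFAULT_PROCESS_STD,
                        meas_std: float = DEFAULT_MEAS_STD) -> Scenario:
    """Four ring-coupled regions generating alpha rhythms."""
    spec = networks.four_region()
    return Scenario("alpha4", spec, duration,
                    GainSchedule.constant(spec.true_gains(), duration),
                    default_noise(spec, process_std, meas_std))


def seizure_scenario(duration: float = 100.0,
                     process_std: float = DEFAULT_PROCESS_STD,
                     meas_std: float = DEFAULT_MEAS_STD) -> Scenario:
    """Four-region seizure transition.

    Region 1's input and excitatory gains (up, ep, pi, pe) ramp linearly
    from the alpha-rhythm values to the epileptogenic plateau and back
    (ramp 30-40 s, plateau 40-60 s, ramp down 60-70 s); its
    inhibitory-to-pyramidal gain stays at baseline.  Regions 2-4 keep the
    alpha-rhythm gains throughout.  Inter-region gains are fixed for the
    whole run at the seizure values: weakened into region 1, strengthened
    elsewhere, so that the discharge spreads around the ring.
    """
    spec = networks.four_region(inter_gains=networks.seizure_inter_gains())
    r = SEIZURE_RAMP
    knots = np.array([0.0, r["up_start"], r["plateau_start"],
                      r["plateau_end"], r["down_end"], duration])
    base = spec.true_gains()
    values = np.tile(base[:, None], (1, len(knots)))
    # ramp every region-1 intra/input gain except the inhibitory one, which
    # the seizure parameterization keeps at baseline
    seiz = networks.SEIZURE_REGION1_GAINS
    for c in spec.connections:
        if c.kind == "inter" or c.label == "ip":
            continue
        if spec.population(c.target).region == 1:
            values[c.index] = [base[c.index], base[c.index],
                               seiz[c.label], seiz[c.label],
                               base[c.index], base[c.index]]
    return Scenario("seizure", spec, duration,
                    GainSchedule(knots, values),
                    default_noise(spec, process_std, meas_std))


SCENARIOS = {"alpha1": alpha_single_scenario,
             "alpha4": alpha_four_scenario,
             "seizure": seizure_scenario}
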