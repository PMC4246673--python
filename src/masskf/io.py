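"""Run configuration and persistence (YAML config, HDF5/CSV/EDF artifacts).

HDF5 is the canonical container for simulation and estimation bundles
(multichannel float time series plus metadata, including a YAML snapshot
of the network spec so a bundle is self-describing); CSV and EDF are
interchange formats for the ECoG traces alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

import masskf.simulator as sim
from .experiments import BiasTable
from .kalman import EstimationResult, FilterConfig, UTParams
from .networks import NetworkSpec
from .statespace import build_state_space

log = logging.getLogger("masskf")

_SCENARIO_KEYS = {"name", "duration", "process_std", "meas_std"}
_FILTER_KEYS = {"variant", "q_v_std", "q_z_std", "q_zin_std", "r_std",
                "p0_v_std", "p0_z_std", "p0_param_frac", "init_gain_frac",
                "init_gain_frac_inter", "param_inflation_rel",
                "param_inflation_floor", "param_inflation_decay_s",
                "param_inflation_min_rel", "param_inflation_min_rel_input",
                "backend", "ut_alpha", "ut_beta", "ut_kappa", "ut_spread"}


@dataclass
class RunConfig:
    """Validated configuration of one simulate/estimate run."""

    scenario: str = "alpha1"
    duration: float | None = None
    process_std: float = sim.DEFAULT_PROCESS_STD
    meas_std: float = sim.DEFAULT_MEAS_STD
    variant: str = "analytic"
    filter: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 1
    out: str | None = None
    log_level: str = "INFO"

    def scenario_obj(self) -> sim.Scenario:
        factory = sim.SCENARIOS[self.scenario]
        kwargs = dict(process_std=self.process_std, meas_std=self.meas_std)
        if self.duration is not None:
            kwargs["duration"] = self.duration
        return factory(**kwargs)

    def to_dict(self) -> dict:
        f = self.filter
        return {
            "scenario": {"name": self.scenario, "duration": self.duration,
                         "process_std": self.process_std,
                         "meas_std": self.meas_std},
            "filter": {"variant": self.variant,
                       "q_v_std": f.q_v_std, "q_z_std": f.q_z_std,
                       "q_zin_std": f.q_zin_std, "r_std": f.r_std,
                       "p0_v_std": f.p0_v_std, "p0_z_std": f.p0_z_std,
                       "p0_param_frac": f.p0_param_frac,
                       "init_gain_frac": f.init_gain_frac,
                       "init_gain_frac_inter": f.init_gain_frac_inter,
                       "param_inflation_rel": f.param_inflation_rel,
                       "param_inflation_floor": f.param_inflation_floor,
                       "param_inflation_decay_s": f.param_inflation_decay_s,
                       "param_inflation_min_rel": f.param_inflation_min_rel,
                       "param_inflation_min_rel_input":
                           f.param_inflation_min_rel_input,
                       "backend": f.backend,
                       "ut_alpha": f.ut.alpha, "ut_beta": f.ut.beta,
                       "ut_kappa": f.ut.kappa, "ut_spread": f.ut.spread},
            "seed": self.seed,
            "out": self.out,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        known = {"scenario", "filter", "seed", "out", "log_level"}
        _reject_unknown(d, known, "")
        scen = dict(d.get("scenario") or {})
        _reject_unknown(scen, _SCENARIO_KEYS, "scenario.")
        filt = dict(d.get("filter") or {})
        _reject_unknown(filt, _FILTER_KEYS, "filter.")
        name = scen.get("name", "alpha1")
        if name not in sim.SCENARIOS:
            raise ValueError(f"scenario.name: unknown scenario {name!r}")
        variant = filt.pop("variant", "analytic")
        if variant not in ("analytic", "ukf"):
            raise ValueError(f"filter.variant: unknown variant {variant!r}")
        ut = UTParams(alpha=filt.pop("ut_alpha", None),
                      beta=filt.pop("ut_beta", 2.0),
                      kappa=filt.pop("ut_kappa", 0.0),
                      spread=filt.pop("ut_spread", 2.324))
        try:
            fc = FilterConfig(ut=ut, **filt)
        except (TypeError, ValueError) as err:
            raise ValueError(f"filter: {err}") from err
        return cls(scenario=name, duration=scen.get("duration"),
                   process_std=float(scen.get("process_std",
                                              sim.DEFAULT_PROCESS_STD)),
                   meas_std=float(scen.get("meas_std", sim.DEFAULT_MEAS_STD)),
                   variant=variant, filter=fc,
                   seed=int(d.get("seed", 1)), out=d.get("out"),
                   log_level=str(d.get("log_level", "INFO")))


def _reject_unknown(d: dict, known: set, prefix: str) -> None:
    extra = set(d) - known
    if extra:
        raise ValueError(
            f"unknown config keys: {sorted(prefix + k for k in extra)}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# --- HDF5 bundles -----------------------------------------------------------

def write_simulation(path, result: sim.SimulationResult) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = "simulation"
        fh.attrs["scenario"] = result.scenario.name
        if result.seed is not None:
            fh.attrs["seed"] = result.seed
        fh.attrs["spec_yaml"] = yaml.safe_dump(
            result.scenario.spec.to_dict(), sort_keys=False)
        for name, arr in [("times", result.times), ("states", result.states),
                          ("ecog", result.ecog), ("input", result.input),
                          ("meas_noise", result.meas_noise),
                          ("montage", result.montage)]:
            fh.create_dataset(name, data=arr)


def read_simulation(path) -> sim.SimulationResult:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("kind") != "simulation":
            raise ValueError(f"{path} is not a simulation bundle")
        spec = NetworkSpec.from_dict(yaml.safe_load(fh.attrs["spec_yaml"]))
        name = fh.attrs["scenario"]
        times = fh["times"][:]
        duration = float(times[-1])
        scenario = sim.Scenario(
            name, spec, duration,
            sim.GainSchedule.constant(spec.true_gains(), duration),
            sim.default_noise(spec))
        return sim.SimulationResult(
            scenario=scenario, model=build_state_space(spec), times=times,
            states=fh["states"][:], ecog=fh["ecog"][:],
            input=fh["input"][:], meas_noise=fh["meas_noise"][:],
            montage=fh["montage"][:],
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None)


def write_estimation(path, result: EstimationResult) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = "estimation"
        fh.attrs["variant"] = result.variant
        fh.attrs["spec_yaml"] = yaml.safe_dump(
            result.model.spec.to_dict(), sort_keys=False)
        for name, arr in [("times", result.times), ("means", result.means),
                          ("stds", result.stds),
                          ("innovations", result.innovations)]:
            fh.create_dataset(name, data=arr)


def read_estimation(path) -> EstimationResult:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("kind") != "estimation":
            raise ValueError(f"{path} is not an estimation bundle")
        spec = NetworkSpec.from_dict(yaml.safe_load(fh.attrs["spec_yaml"]))
        return EstimationResult(
            variant=str(fh.attrs["variant"]), times=fh["times"][:],
            means=fh["means"][:], stds=fh["stds"][:],
            innovations=fh["innovations"][:], model=build_state_space(spec))


def write_bias_table(path_csv, table: BiasTable) -> None:
    table.to_frame().to_csv(path_csv, index=False)


# --- ECoG interchange -------------------------------------------------------

def ecog_channel_labels(spec: NetworkSpec) -> list:
    if spec.n_regions == 1:
        return ["R1"]
    return [f"R{j}-R{j % spec.n_regions + 1}"
            for j in range(1, spec.n_regions + 1)]


def write_ecog_csv(path, result: sim.SimulationResult) -> None:
    labels = ecog_channel_labels(result.scenario.spec)
    df = pd.DataFrame(result.ecog, columns=labels)
    df.insert(0, "time_s", result.times)
    df.to_csv(path, index=False, float_format="%.6f")


def read_ecog_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "time_s"]
    return df[cols].to_numpy(dtype=float)


def write_ecog_edf(path, result: sim.SimulationResult) -> None:
    from .edf import write_edf
    rate = 1.0 / result.scenario.spec.delta
    write_edf(path, result.ecog, rate,
              channel_labels=ecog_channel_labels(result.scenario.spec))


def read_ecog_edf(path) -> np.ndarray:
    """Read an EDF recording back into an (n_samples, n_channels) array, mV.

    Uses MNE's native EDF reader (optional dependency); MNE rescales
    mV-dimension signals to volts, which is undone here.
    """
    try:
        import mne
    except ImportError as err:                        # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    return raw.get_data().T * 1e3
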