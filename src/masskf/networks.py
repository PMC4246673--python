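"""Declarative description of neural-mass network models.

A network is a set of neural populations (pyramidal cells, spiny stellate
excitatory interneurons, inhibitory interneurons, plus one external-input
pseudo-population per region) wired together by second-order synaptic
connections.  Each connection carries a lumped connectivity gain ``alpha``
(the product of average synaptic gain, connection count and maximum firing
rate — treated as a single dimensionless parameter) and a synaptic time
constant ``tau`` in seconds.

Two canonical topologies are provided: a single cortical region with five
connections (external input -> pyramidal, spiny stellate -> pyramidal,
pyramidal -> inhibitory, inhibitory -> pyramidal, pyramidal -> spiny
stellate) and a four-region ring in which each region couples to both of
its neighbours through delayed pyramidal-to-pyramidal pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

# --- fixed physiological constants (alpha-rhythm parameterization) ---------

SIGMOID_SLOPE_MV = 3.0      # sd of firing thresholds, mV
FIRING_THRESHOLD_MV = 6.0   # mean firing threshold relative to rest, mV
TAU_EXC_S = 0.010           # tau for u->p, p->e, p->i, e->p synapses, s
TAU_INHIB_S = 0.020         # tau for i->p synapses, s
TAU_DELAY_S = 0.0303        # inter-region delay-kernel time constant, s
INPUT_MEAN = 220.0          # mean of the external firing-rate input u
INPUT_VARIANCE = 5.74       # variance of u
TIME_STEP_S = 0.001         # discretization step delta, s

#: background (alpha rhythm) intra-region gains, keyed by connection label
ALPHA_GAINS = {
    "up": 3.2,
    "ep": 1755.0,
    "pi": 548.4,
    "ip": -3712.5,
    "pe": 2197.0,
}

#: excitatory gains of the seizure-generating region at the seizure plateau
SEIZURE_REGION1_GAINS = {
    "up": 8.1,
    "ep": 4387.0,
    "pi": 1370.9,
    "ip": -3712.5,
    "pe": 5483.7,
}

#: alpha-rhythm inter-region gains, keyed by target region (1-based)
ALPHA_INTER_GAINS = {1: 76.0, 2: 63.0, 3: 44.0, 4: 70.0}

#: seizure-scenario inter-region gains: pathways into region 1 are weakened,
#: every other pathway is strengthened, for the whole run
SEIZURE_INTER_GAIN_INTO_R1 = 1.6
SEIZURE_INTER_GAIN_OTHER = 162.5

#: physiological clipping bounds for each gain class
GAIN_BOUNDS = {
    "up": (0.0, 300.0),
    "ep": (0.0, 20000.0),
    "pi": (0.0, 20000.0),
    "pe": (0.0, 20000.0),
    "ip": (-40000.0, 0.0),
    "inter": (0.0, 5000.0),
}

POPULATION_KINDS = ("pyramidal", "spiny_stellate", "inhibitory_interneuron",
                    "external_input")

#: per-region connections in canonical order: (label, source kind, target kind)
_REGION_WIRING = (
    ("up", "external_input", "pyramidal"),
    ("ep", "spiny_stellate", "pyramidal"),
    ("pi", "pyramidal", "inhibitory_interneuron"),
    ("ip", "inhibitory_interneuron", "pyramidal"),
    ("pe", "pyramidal", "spiny_stellate"),
)

_KIND_CODE = {"pyramidal": "p", "spiny_stellate": "e",
              "inhibitory_interneuron": "i", "external_input": "u"}


@dataclass(frozen=True)
class PopulationSpec:
    """A neural population (or the external-input pseudo-population)."""

    id: str
    kind: str
    region: int

    def __post_init__(self):
        if self.kind not in POPULATION_KINDS:
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.region < 1:
            raise ValueError("region indices are 1-based")


@dataclass(frozen=True)
class SynapticConnection:
    """One second-order synaptic (or inter-region delay) pathway.

    ``kind`` is ``input`` for the external drive, ``intra`` for connections
    within a region and ``inter`` for delayed pyramidal-to-pyramidal
    pathways between regions.  ``label`` is the gain class (``up``, ``ep``,
    ``pi``, ``ip``, ``pe`` or ``inter``).
    """

    index: int
    source: str
    target: str
    kind: str
    label: str
    tau: float
    alpha_true: float
    bounds: tuple[float, float]

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"connection {self.index}: tau must be positive")
        lo, hi = self.bounds
        if lo > hi:
            raise ValueError(f"connection {self.index}: bounds out of order")
        if not (lo <= self.alpha_true <= hi):
            raise ValueError(
                f"connection {self.index}: alpha {self.alpha_true} outside "
                f"bounds [{lo}, {hi}]")
        if self.kind not in ("input", "intra", "inter"):
            raise ValueError(f"unknown connection kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Populations plus connections plus the shared model constants."""

    populations: tuple[PopulationSpec, ...]
    connections: tuple[SynapticConnection, ...]
    v0: float = FIRING_THRESHOLD_MV
    sigma_slope: float = SIGMOID_SLOPE_MV
    input_mean: float = INPUT_MEAN
    input_variance: float = INPUT_VARIANCE
    delta: float = TIME_STEP_S

    def __post_init__(self):
        self._validate()

    # -- derived counts ----------------------------------------------------
    @property
    def n_regions(self) -> int:
        return max(p.region for p in self.populations)

    @property
    def n_intra(self) -> int:
        """Number of intra-region connections N (external input included)."""
        return sum(1 for c in self.connections if c.kind != "inter")

    @property
    def n_inter(self) -> int:
        return sum(1 for c in self.connections if c.kind == "inter")

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    @property
    def n_augmented(self) -> int:
        """Dimension of the augmented state vector, 3 (N + K)."""
        return 3 * self.n_connections

    def population(self, pid: str) -> PopulationSpec:
        for p in self.populations:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def true_gains(self):
        import numpy as np
        return np.array([c.alpha_true for c in self.connections])

    def gain_bounds(self):
        import numpy as np
        lo = np.array([c.bounds[0] for c in self.connections])
        hi = np.array([c.bounds[1] for c in self.connections])
        return lo, hi

    def with_gains(self, gains: Sequence[float]) -> "NetworkSpec":
        """Copy of this spec with alpha_true replaced connection-wise."""
        if len(gains) != self.n_connections:
            raise ValueError("gain vector length mismatch")
        conns = tuple(replace(c, alpha_true=float(g))
                      for c, g in zip(self.connections, gains))
        return replace(self, connections=conns)

    # -- validation --------------------------------------------------------
    def _validate(self):
        ids = [p.id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate population ids")
        by_region: dict[int, list[str]] = {}
        for p in self.populations:
            by_region.setdefault(p.region, []).append(p.kind)
        for r, kinds in by_region.items():
            for kind in POPULATION_KINDS[:3]:
                if kinds.count(kind) != 1:
                    raise ValueError(
                        f"region {r} must hold exactly one {kind} population")
        if self.sigma_slope <= 0 or self.delta <= 0:
            raise ValueError("sigma_slope and delta must be positive")
        seen = set()
        for i, c in enumerate(self.connections):
            if c.index != i:
                raise ValueError("connection indices must be sequential")
            src = self.population(c.source)   # raises on dangling ids
            tgt = self.population(c.target)
            if (c.source, c.target) in seen:
                raise ValueError(f"duplicate connection {c.source}->{c.target}")
            seen.add((c.source, c.target))
            if tgt.kind == "external_input":
                raise ValueError("external input cannot receive connections")
            if c.kind == "input" and src.kind != "external_input":
                raise ValueError("input connections must originate from u")
            if c.kind == "inter":
                if src.kind != "pyramidal" or tgt.kind != "pyramidal":
                    raise ValueError("inter connections are pyramidal-to-pyramidal")
                if src.region == tgt.region:
                    raise ValueError("inter connections must span regions")
            elif src.region != tgt.region:
                raise ValueError("intra/input connections must stay in-region")
            if c.label == "ip":
                if c.alpha_true > 0:
                    raise ValueError("inhibitory-to-pyramidal gain must be <= 0")
            elif c.alpha_true < 0:
                raise ValueError("non-inhibitory gains must be >= 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "constants": {
                "v0": self.v0,
                "sigma_slope": self.sigma_slope,
                "input_mean": self.input_mean,
                "input_variance": self.input_variance,
                "delta": self.delta,
            },
            "populations": [
                {"id": p.id, "kind": p.kind, "region": p.region}
                for p in self.populations
            ],
            "connections": [
                {"source": c.source, "target": c.target, "kind": c.kind,
                 "label": c.label, "tau": c.tau, "alpha": c.alpha_true,
                 "bounds": list(c.bounds)}
                for c in self.connections
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkSpec":
        known = {"constants", "populations", "connections"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown network keys: {sorted(extra)}")
        consts = dict(d.get("constants", {}))
        pops = tuple(PopulationSpec(p["id"], p["kind"], int(p["region"]))
                     for p in d["populations"])
        conns = tuple(
            SynapticConnection(
                index=i, source=c["source"], target=c["target"],
                kind=c["kind"], label=c["label"], tau=float(c["tau"]),
                alpha_true=float(c["alpha"]),
                bounds=tuple(float(b) for b in c["bounds"]))
            for i, c in enumerate(d["connections"]))
        return cls(populations=pops, connections=conns, **consts)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --- canonical topologies ---------------------------------------------------

def _region_populations(region: int) -> list[PopulationSpec]:
    return [PopulationSpec(f"{_KIND_CODE[k]}{region}", k, region)
            for k in POPULATION_KINDS]


def _region_connections(region: int, gains: Mapping[str, float],
                        start_index: int) -> list[SynapticConnection]:
    conns = []
    for offset, (label, src_kind, tgt_kind) in enumerate(_REGION_WIRING):
        tau = TAU_INHIB_S if label == "ip" else TAU_EXC_S
        conns.append(SynapticConnection(
            index=start_index + offset,
            source=f"{_KIND_CODE[src_kind]}{region}",
            target=f"{_KIND_CODE[tgt_kind]}{region}",
            kind="input" if label == "up" else "intra",
            label=label, tau=tau, alpha_true=gains[label],
            bounds=GAIN_BOUNDS[label]))
    return conns


def single_region(gains: Mapping[str, float] | None = None) -> NetworkSpec:
    """One cortical region with its five canonical connections (N=5, K=0)."""
    gains = dict(ALPHA_GAINS if gains is None else gains)
    pops = tuple(_region_populations(1))
    conns = tuple(_region_connections(1, gains, 0))
    return NetworkSpec(populations=pops, connections=conns)


def ring_edges(n_regions: int = 4) -> list[tuple[int, int]]:
    """Directed edges of the bidirectional ring: forward j->j+1 then backward."""
    fwd = [(j, j % n_regions + 1) for j in range(1, n_regions + 1)]
    bwd = [(k, j) for j, k in fwd]
    return fwd + bwd


def four_region(intra_gains: Mapping[str, float] | None = None,
                inter_gains: Mapping[tuple[int, int], float] | None = None,
                region1_gains: Mapping[str, float] | None = None) -> NetworkSpec:
    """Four cortical regions on a bidirectional ring (N=20, K=8).

    ``inter_gains`` maps directed (source_region, target_region) edges to
    gains; by default every pathway into region ``k`` takes the alpha-rhythm
    value for that target.  ``region1_gains`` optionally overrides the
    intra-region gains of region 1 only (used by the seizure scenario).
    """
    intra = dict(ALPHA_GAINS if intra_gains is None else intra_gains)
    pops: list[PopulationSpec] = []
    conns: list[SynapticConnection] = []
    for r in range(1, 5):
        pops.extend(_region_populations(r))
        gains = dict(intra)
        if r == 1 and region1_gains is not None:
            gains.update(region1_gains)
        conns.extend(_region_connections(r, gains, len(conns)))
    for j, k in ring_edges(4):
        if inter_gains is None:
            g = ALPHA_INTER_GAINS[k]
        else:
            g = inter_gains[(j, k)]
        conns.append(SynapticConnection(
            index=len(conns), source=f"p{j}", target=f"p{k}",
            kind="inter", label="inter", tau=TAU_DELAY_S, alpha_true=g,
            bounds=GAIN_BOUNDS["inter"]))
    return NetworkSpec(populations=tuple(pops), connections=tuple(conns))


def seizure_inter_gains() -> dict[tuple[int, int], float]:
    """Inter-region gains of the seizure run (fixed over the whole run)."""
    return {(j, k): (SEIZURE_INTER_GAIN_INTO_R1 if k == 1
                     else SEIZURE_INTER_GAIN_OTHER)
            for j, k in ring_edges(4)}
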