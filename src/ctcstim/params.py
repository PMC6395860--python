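"""Parameter containers for QIF column networks.

All quantities are kept in SI units internally (volts, amperes, farads,
seconds).  Convenience constants carry the standard single-column values
used throughout: a column is 800 excitatory + 200 inhibitory conductance
-based quadratic integrate-and-fire neurons whose membrane potential obeys

    C_m dV/dt = p2 V^2 + p1 V + p0 + I_syn + I_noise + I_pulse

with a spike registered when V crosses ``V_thresh`` and V reset to
``V_reset``.  Synaptic input is conductance based, I = g(t)·(V_rev − V),
where g(t) is an exponential kernel sum: a single excitatory decay (tau_e)
and a fast/slow inhibitory mixture (tau_i1 / tau_i2 weighted chi1 / chi2),
scaled by the unitary conductance amplitudes w_e / w_i (siemens).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

# --- convenience unit multipliers -------------------------------------------
MS = 1e-3
MV = 1e-3
NA = 1e-9

#: specific membrane capacitance (F/cm^2); standard biophysical value
CM_SPECIFIC = 1e-6


class ConfigError(ValueError):
    """Raised for inconsistent network configuration parameters."""


@dataclass
class PopulationParams:
    """Size and membrane parameters of one column (E pool + I pool)."""

    n_exc: int = 800
    n_inh: int = 200
    area_exc: float = 2.88e-4       # cm^2
    area_inh: float = 1.2e-4        # cm^2
    cm_specific: float = CM_SPECIFIC
    p0: float = 3.89e-9             # A
    p1: float = 1.30e-7             # A/V
    p2: float = 1.08e-6             # A/V^2
    v_e: float = 0.0                # V, excitatory reversal
    v_i: float = -75 * MV           # V, inhibitory reversal
    v_thresh: float = -56.23 * MV   # V
    v_reset: float = -67 * MV       # V
    sigma_n: float = 0.0            # A, pink-noise magnitude

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ConfigError("population sizes must be positive")
        if self.area_exc <= 0 or self.area_inh <= 0:
            raise ConfigError("membrane areas must be positive")
        if self.v_reset >= self.v_thresh:
            raise ConfigError("V_reset must lie below V_thresh")
        if self.sigma_n < 0:
            raise ConfigError("sigma_n must be non-negative")

    @property
    def cm_exc(self) -> float:
        """Membrane capacitance of an excitatory neuron (F)."""
        return self.cm_specific * self.area_exc

    @property
    def cm_inh(self) -> float:
        return self.cm_specific * self.area_inh

    def quiescent_potential(self) -> float:
        """Stable root of p2 V^2 + p1 V + p0 = 0 (the resting fixed point)."""
        disc = self.p1 ** 2 - 4 * self.p2 * self.p0
        if disc < 0:
            raise ConfigError("membrane quadratic has no real fixed point")
        return (-self.p1 - disc ** 0.5) / (2 * self.p2)


NS = 1e-9  # siemens


@dataclass
class SynapseKernelParams:
    """Exponential synaptic kernels (unitary conductance amplitudes)."""

    w_e: float = 0.4 * NS
    w_i: float = 1.2 * NS
    tau_e: float = 3 * MS
    tau_i1: float = 1.2 * MS
    tau_i2: float = 8 * MS
    chi1: float = 0.9
    chi2: float = 0.1

    def __post_init__(self) -> None:
        if min(self.tau_e, self.tau_i1, self.tau_i2) <= 0:
            raise ConfigError("synaptic time constants must be positive")
        if abs(self.chi1 + self.chi2 - 1.0) > 1e-9:
            raise ConfigError("chi1 + chi2 must equal 1")
        if self.w_e <= 0 or self.w_i <= 0:
            raise ConfigError("synaptic weights must be positive")


@dataclass
class Projection:
    """A probabilistic all-to-all projection between two neuron pools.

    ``source``/``target`` are (population id, pool) pairs where pool is
    "exc" or "inh"; ``kind`` gives the postsynaptic kernel and must match
    the source pool (excitatory cells make excitatory synapses).
    """

    source: tuple[str, str]
    target: tuple[str, str]
    prob: float
    delay: float
    kind: str  # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ConfigError("projection probability outside [0, 1]")
        if self.delay < 0:
            raise ConfigError("projection delay must be non-negative")
        expected = "excitatory" if self.source[1] == "exc" else "inhibitory"
        if self.kind != expected:
            raise ConfigError(
                f"projection kind {self.kind!r} does not match source pool "
                f"{self.source[1]!r}"
            )


@dataclass
class FlickerSignal:
    """Piecewise-constant Uniform[-1, 1] amplitude modulation."""

    values: "list[float]"
    step: float = 10 * MS
    seed: int = 0

    def __post_init__(self) -> None:
        import numpy as np

        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < -1.0 or v.max() > 1.0):
            raise ConfigError("flicker values must lie in [-1, 1]")
        if self.step <= 0:
            raise ConfigError("flicker step must be positive")

    def at_dt(self, n_steps: int, dt: float):
        """Sample-and-hold expansion onto an integration grid."""
        import numpy as np

        v = np.asarray(self.values, dtype=float)
        idx = np.minimum((np.arange(n_steps) * dt / self.step).astype(np.int64),
                         len(v) - 1)
        return v[idx]


@dataclass
class DriveSpec:
    """Afferent Poisson drive S(t) = base_rate * (1 + sigma_f * F(t))."""

    base_rate: float               # events/s per neuron
    sigma_f: float = 0.10
    flicker: Optional[FlickerSignal] = None

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ConfigError("base_rate must be non-negative")
        if not 0 <= self.sigma_f <= 1:
            raise ConfigError("sigma_f outside [0, 1] can yield negative rates")


@dataclass
class StimulationPulse:
    """Square current pulse applied to every neuron of a column."""

    target: str
    amplitude: float               # A, signed (polarity)
    onset: float                   # s
    duration: float = 1 * MS

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("pulse duration must be positive")


@dataclass
class NetworkConfig:
    """Full description of a network: columns, wiring, drives, integration."""

    populations: "dict[str, PopulationParams]"
    synapses: SynapseKernelParams
    projections: "list[Projection]"
    drives: "dict[tuple[str, str], DriveSpec]" = field(default_factory=dict)
    dt: float = 0.1 * MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        for proj in self.projections:
            for pop, pool in (proj.source, proj.target):
                if pop not in self.populations:
                    raise ConfigError(f"projection endpoint {pop!r} missing")
                if pool not in ("exc", "inh"):
                    raise ConfigError(f"unknown pool {pool!r}")

    def delay_steps(self, delay: float) -> int:
        return int(round(delay / self.dt))

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                d = dataclasses.asdict(o)
                d["__type__"] = type(o).__name__
                return d
            raise TypeError(type(o))

        doc = {
            "populations": {k: dataclasses.asdict(v)
                            for k, v in self.populations.items()},
            "synapses": dataclasses.asdict(self.synapses),
            "projections": [dataclasses.asdict(p) for p in self.projections],
            "drives": {f"{pop}:{pool}": dataclasses.asdict(d)
                       for (pop, pool), d in self.drives.items()},
            "dt": self.dt,
            "seed": self.seed,
        }
        return json.dumps(doc, indent=2, default=enc)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        doc = json.loads(text)
        pops = {k: PopulationParams(**v) for k, v in doc["populations"].items()}
        syn = SynapseKernelParams(**doc["synapses"])
        projs = []
        for p in doc["projections"]:
            p = dict(p)
            p["source"] = tuple(p["source"])
            p["target"] = tuple(p["target"])
            projs.append(Projection(**p))
        drives = {}
        for key, d in doc.get("drives", {}).items():
            pop, pool = key.split(":")
            d = dict(d)
            fl = d.pop("flicker", None)
            if fl is not None:
                fl = FlickerSignal(**fl)
            drives[(pop, pool)] = DriveSpec(flicker=fl, **d)
        return cls(populations=pops, synapses=syn, projections=projs,
                   drives=drives, dt=doc.get("dt", 0.1 * MS),
                   seed=doc.get("seed", 0))

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]
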