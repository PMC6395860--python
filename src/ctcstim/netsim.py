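"""Construction and simulation of ING gamma-oscillator column networks.

A *column* is a recurrent network of 800 excitatory and 200 inhibitory
conductance-based QIF neurons.  Only the inhibitory pool projects locally
(I->I and I->E, probability 0.5, delay 5 ms); with calibrated afferent
Poisson drive the delayed mutual inhibition produces a gamma rhythm by the
ING mechanism that is imposed on the excitatory cells.

The three-column XYZ network couples two input columns X and Y through
weak crossed E->I projections (which locks them in antiphase) and feeds a
downstream readout column Z from both X_e and Y_e; Z sends no feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import Engine, IntegrationError, generate_pink_noise
from .params import (
    MS, NA, ConfigError, DriveSpec, FlickerSignal, NetworkConfig,
    PopulationParams, Projection, StimulationPulse, SynapseKernelParams,
)

__all__ = [
    "build_single_column", "build_xyz_network", "generate_pink_noise",
    "generate_flicker", "simulate", "extract_population_signal",
    "SimulationResult", "IntegrationError",
    "DEFAULT_BASE_RATE_EXC", "DEFAULT_BASE_RATE_INH",
]

# starting points for the afferent drive calibration (events/s per neuron);
# arbitrary round numbers in the regime where the column oscillates
DEFAULT_BASE_RATE_EXC = 4000.0
DEFAULT_BASE_RATE_INH = 4000.0

LOCAL_PROJ_PROB = 0.5
LOCAL_PROJ_DELAY = 5 * MS
XY_PROJ_PROB = 0.02
XY_PROJ_DELAY = 5 * MS
#: delay of the X_e/Y_e -> Z projections (same as every local delay)
Z_PROJ_DELAY = 5 * MS
FLICKER_STEP = 10 * MS
SIGMA_FLICKER = 0.10


@dataclass
class SimulationResult:
    """Spike raster plus 1 kHz per-population analysis signals."""

    spike_times: np.ndarray          # s
    spike_neuron: np.ndarray         # global neuron index
    spike_population: np.ndarray     # population label per spike
    spike_pool: np.ndarray           # "exc" | "inh" per spike
    signals_1khz: dict               # pop -> {component -> 1 kHz array}
    pulses_applied: list
    duration: float
    config: NetworkConfig = None
    pool_sizes: dict = field(default_factory=dict)

    def pool_rate(self, population: str, pool: str = "exc") -> float:
        """Time-averaged firing rate (Hz per neuron) of one pool."""
        sel = (self.spike_population == population) & (self.spike_pool == pool)
        n = self.pool_sizes[(population, pool)]
        return float(sel.sum()) / (n * self.duration)


def _local_projections(name: str) -> list:
    return [
        Projection(source=(name, "inh"), target=(name, "inh"),
                   prob=LOCAL_PROJ_PROB, delay=LOCAL_PROJ_DELAY,
                   kind="inhibitory"),
        Projection(source=(name, "inh"), target=(name, "exc"),
                   prob=LOCAL_PROJ_PROB, delay=LOCAL_PROJ_DELAY,
                   kind="inhibitory"),
    ]


def generate_flicker(duration: float, step: float = FLICKER_STEP,
                     seed: int = 0) -> FlickerSignal:
    """Uniform[-1, 1] draws held constant over consecutive ``step`` windows."""
    if not duration >= step > 0:
        raise ConfigError("require duration >= step > 0")
    n = int(np.ceil(duration / step))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0xF11C]))
    return FlickerSignal(values=rng.uniform(-1.0, 1.0, n).tolist(),
                         step=step, seed=seed)


def _drives(name: str, duration_hint: float, seed: int,
            rate_exc: float, rate_inh: float, sigma_f: float,
            flicker: FlickerSignal | None) -> dict:
    """Both pools of a column share one flicker-modulated drive signal."""
    if flicker is None and sigma_f > 0:
        flicker = generate_flicker(duration_hint, seed=seed)
    return {
        (name, "exc"): DriveSpec(base_rate=rate_exc, sigma_f=sigma_f,
                                 flicker=flicker),
        (name, "inh"): DriveSpec(base_rate=rate_inh, sigma_f=sigma_f,
                                 flicker=flicker),
    }


def build_single_column(params: PopulationParams | None = None,
                        synapses: SynapseKernelParams | None = None,
                        noise_level: float = 0.0,
                        seed: int = 0,
                        *,
                        name: str = "A",
                        rate_exc: float = DEFAULT_BASE_RATE_EXC,
                        rate_inh: float = DEFAULT_BASE_RATE_INH,
                        sigma_f: float = SIGMA_FLICKER,
                        flicker: FlickerSignal | None = None,
                        drive_duration: float = 10.0) -> NetworkConfig:
    """Single 800E/200I column with local I->I and I->E wiring."""
    if noise_level < 0:
        raise ConfigError("noise_level must be non-negative")
    import dataclasses as _dc
    params = params or PopulationParams()
    params = _dc.replace(params, sigma_n=noise_level)
    synapses = synapses or SynapseKernelParams()
    return NetworkConfig(
        populations={name: params},
        synapses=synapses,
        projections=_local_projections(name),
        drives=_drives(name, drive_duration, seed, rate_exc, rate_inh,
                       sigma_f, flicker),
        seed=seed,
    )


def build_xyz_network(column_params: PopulationParams | None = None,
                      p_ze: float = 0.06,
                      p_zi: float = 0.06,
                      seed: int = 0,
                      *,
                      synapses: SynapseKernelParams | None = None,
                      noise_level: float = 0.0,
                      rates: dict | None = None,
                      sigma_f: float = SIGMA_FLICKER,
                      drive_duration: float = 10.0,
                      z_delay: float = Z_PROJ_DELAY,
                      z_drive_scale: float = 0.5) -> NetworkConfig:
    """Bistable three-column network: X, Y antiphase senders, Z receiver.

    ``rates`` optionally maps population name -> (rate_exc, rate_inh);
    X and Y each receive their own independent flicker signal, Z is driven
    without flicker modulation.  Z keeps a reduced unmodulated afferent
    drive (``z_drive_scale`` of the X/Y rates) so that a substantial part
    of its excitation arrives gamma-modulated from X_e/Y_e — that input
    entrains Z and carries the routed signals.
    """
    if not (0 <= p_ze <= 1 and 0 <= p_zi <= 1):
        raise ConfigError("p_ze / p_zi must lie in [0, 1]")
    import dataclasses as _dc
    column_params = column_params or PopulationParams()
    column_params = _dc.replace(column_params, sigma_n=noise_level)
    synapses = synapses or SynapseKernelParams()
    rates = rates or {}

    populations = {n: _dc.replace(column_params) for n in "XYZ"}
    projections = []
    for n in "XYZ":
        projections += _local_projections(n)
    projections += [
        Projection(source=("X", "exc"), target=("Y", "inh"),
                   prob=XY_PROJ_PROB, delay=XY_PROJ_DELAY, kind="excitatory"),
        Projection(source=("Y", "exc"), target=("X", "inh"),
                   prob=XY_PROJ_PROB, delay=XY_PROJ_DELAY, kind="excitatory"),
    ]
    for src in ("X", "Y"):
        projections += [
            Projection(source=(src, "exc"), target=("Z", "exc"),
                       prob=p_ze, delay=z_delay, kind="excitatory"),
            Projection(source=(src, "exc"), target=("Z", "inh"),
                       prob=p_zi, delay=z_delay, kind="excitatory"),
        ]

    drives = {}
    for i, n in enumerate("XYZ"):
        re_, ri_ = rates.get(n, (DEFAULT_BASE_RATE_EXC, DEFAULT_BASE_RATE_INH))
        if n == "Z" and "Z" not in rates:
            re_, ri_ = re_ * z_drive_scale, ri_ * z_drive_scale
        sf = sigma_f if n in ("X", "Y") else 0.0
        drives.update(_drives(n, drive_duration, seed * 3 + i, re_, ri_,
                              sf, None))
    return NetworkConfig(populations=populations, synapses=synapses,
                         projections=projections, drives=drives, seed=seed)


def with_new_flicker(config: NetworkConfig, seed: int) -> NetworkConfig:
    """Config copy with fresh flicker realizations (same step/length).

    Populations sharing a flicker object keep sharing the new one; each
    population gets an independent draw derived from ``seed``.
    """
    import dataclasses as _dc

    new_for_pop: dict = {}
    drives = {}
    for (pop, pool), spec in config.drives.items():
        if spec.flicker is None:
            drives[(pop, pool)] = spec
            continue
        if pop not in new_for_pop:
            import zlib

            dur = len(spec.flicker.values) * spec.flicker.step
            tag = zlib.crc32(pop.encode()) & 0xFFFF  # process-independent
            sub = int(np.random.SeedSequence(
                [seed & 0x7FFFFFFF, tag]).generate_state(1)[0] & 0x7FFFFFFF)
            new_for_pop[pop] = generate_flicker(dur, spec.flicker.step, sub)
        drives[(pop, pool)] = _dc.replace(spec, flicker=new_for_pop[pop])
    return _dc.replace(config, drives=drives)


def simulate(config: NetworkConfig, duration: float,
             pulses: list | tuple = (), seed: int = 0,
             v_init: str = "random") -> SimulationResult:
    """Integrate the network with forward Euler at ``config.dt``.

    Spikes are registered at the V_thresh crossing, delivered to every
    synaptic target after the projection delay, and followed by a reset to
    V_reset (no explicit refractory period).  Stimulation pulses add their
    amplitude to the input current of every neuron of the target column
    for the pulse duration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    eng = Engine(config, duration, pulses=pulses, seed=seed, v_init=v_init)
    eng.run()
    return finalize(eng)


def finalize(eng: Engine) -> SimulationResult:
    """Package a (fully or partially) run engine into a result object."""
    n_spk = int(eng.spk_count[0])
    t = eng.spikes_t[:n_spk] * eng.dt
    g = eng.spikes_g[:n_spk].copy()
    pools = eng.pool_of_neuron[g]
    names = np.array([p for p, _ in eng.pool_group_names])
    kinds = np.array([q for _, q in eng.pool_group_names])
    pool_sizes = {pp: (r[1] - r[0]) for pp, r in eng.pool_ranges.items()}
    return SimulationResult(
        spike_times=t,
        spike_neuron=g,
        spike_population=names[pools],
        spike_pool=kinds[pools],
        signals_1khz=eng.signals_upto(),
        pulses_applied=list(eng.pulses),
        duration=eng.t_now,
        config=eng.config,
        pool_sizes=pool_sizes,
    )


def extract_population_signal(result: SimulationResult, population: str,
                              component: str = "exc_rate"):
    """One 1 kHz analysis trace of a population.

    ``component`` is ``exc_rate`` / ``inh_rate`` (per-ms spike counts of
    the pool divided by pool size and bin width, i.e. Hz per neuron) or
    ``current_from:<source>`` (mean synaptic current of that source into
    the population's excitatory pool, averaged per ms).
    """
    from .phase import AnalogTrace

    sig = result.signals_1khz.get(population)
    if sig is None:
        raise KeyError(f"unknown population {population!r}")
    if component not in sig:
        raise KeyError(
            f"unknown component {component!r}; available: {sorted(sig)}")
    return AnalogTrace(samples=np.asarray(sig[component], float),
                       fs=1000.0, t0=0.0)
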