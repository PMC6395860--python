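"""Drive-rate and Z-connectivity calibration.

Internal noise raises firing rates, and the recurrent coupling amplifies
any rate change, so every noise condition needs its own afferent drive.
The calibration runs short probe simulations and moves each pool's base
rate along the sign of its rate error (multiplicative steps, capped),
until the excitatory pools fire at 15 Hz and the inhibitory pools at
60 Hz.  In the XYZ network the same loop then adjusts the X_e/Y_e -> Z
connection probabilities so the readout column matches the same targets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import netsim
from .params import NetworkConfig


@dataclass
class CalibrationTarget:
    rate_exc: float = 15.0        # Hz
    rate_inh: float = 60.0        # Hz
    tol_exc: float = 1.0          # Hz
    tol_inh: float = 3.0          # Hz
    max_iter: int = 40
    probe_duration: float = 3.0   # s
    learning_rate: float = 0.02   # relative step per Hz of error
    max_step: float = 0.2         # cap on the relative step per iteration

    def __post_init__(self):
        if self.tol_exc <= 0 or self.tol_inh <= 0:
            raise ValueError("tolerances must be positive")
        if self.probe_duration < 2.0:
            raise ValueError("probe_duration must be at least 2 s")


@dataclass
class CalibrationResult:
    config: NetworkConfig
    rates: dict                   # (pop, pool) -> achieved rate (Hz)
    drives: dict                  # (pop, pool) -> calibrated base rate
    iterations: int
    converged: bool
    p_ze: Optional[float] = None
    p_zi: Optional[float] = None
    history: list = field(default_factory=list)


def _step(current: float, err_hz: float, target: CalibrationTarget) -> float:
    rel = np.clip(target.learning_rate * err_hz,
                  -target.max_step, target.max_step)
    return current * (1.0 + rel)


def _with_rates(config: NetworkConfig, updates: dict) -> NetworkConfig:
    drives = dict(config.drives)
    for key, rate in updates.items():
        drives[key] = dataclasses.replace(drives[key], base_rate=float(rate))
    return dataclasses.replace(config, drives=drives)


def calibrate_drives(config: NetworkConfig,
                     target: CalibrationTarget = None,
                     seed: int = 0,
                     populations=None) -> CalibrationResult:
    """Tune afferent base rates until pool rates hit the targets.

    For the XYZ network only the lower-layer columns (X, Y) are tuned;
    pass ``populations`` to override.  Probe runs use a fixed seed
    sequence so the loop is reproducible.
    """
    target = target or CalibrationTarget()
    if populations is None:
        pops = list(config.populations)
        populations = [p for p in pops if p in ("X", "Y")] or pops
    cfg = config
    history = []
    converged = False
    it = 0
    for it in range(1, target.max_iter + 1):
        probe_seed = (seed * 9973 + it) & 0x7FFFFFFF
        res = netsim.simulate(cfg, target.probe_duration, seed=probe_seed)
        errs = {}
        updates = {}
        for pop in populations:
            for pool, tgt, tol in (("exc", target.rate_exc, target.tol_exc),
                                   ("inh", target.rate_inh, target.tol_inh)):
                r = res.pool_rate(pop, pool)
                err = tgt - r
                errs[(pop, pool)] = (r, err, tol)
                if abs(err) > tol:
                    cur = cfg.drives[(pop, pool)].base_rate
                    updates[(pop, pool)] = _step(cur, err, target)
        history.append({k: v[0] for k, v in errs.items()})
        if not updates:
            converged = True
            break
        cfg = _with_rates(cfg, updates)
    rates = {k: v[0] for k, v in errs.items()}
    return CalibrationResult(
        config=cfg, rates=rates,
        drives={k: d.base_rate for k, d in cfg.drives.items()},
        iterations=it, converged=converged, history=history)


def _with_z_probs(config: NetworkConfig, p_ze: float,
                  p_zi: float) -> NetworkConfig:
    projs = []
    for p in config.projections:
        if p.target[0] == "Z" and p.source[0] in ("X", "Y"):
            prob = p_ze if p.target[1] == "exc" else p_zi
            projs.append(dataclasses.replace(p, prob=float(prob)))
        else:
            projs.append(p)
    return dataclasses.replace(config, projections=projs)


def calibrate_z_connectivity(config: NetworkConfig,
                             target: CalibrationTarget = None,
                             seed: int = 0) -> CalibrationResult:
    """Tune p_Ze / p_Zi so the Z pools match the firing-rate targets.

    Requires X and Y to be calibrated already.  Probabilities move along
    the sign of the corresponding Z pool's rate error and are clipped to
    [0, 1]; hitting a clip bound with a residual error flags the result
    as unconverged (target unreachable).
    """
    target = target or CalibrationTarget()
    p_ze = next(p.prob for p in config.projections
                if p.target == ("Z", "exc") and p.source[0] in ("X", "Y"))
    p_zi = next(p.prob for p in config.projections
                if p.target == ("Z", "inh") and p.source[0] in ("X", "Y"))
    cfg = config
    history = []
    converged = False
    clipped = False
    it = 0
    for it in range(1, target.max_iter + 1):
        probe_seed = (seed * 7121 + it) & 0x7FFFFFFF
        res = netsim.simulate(cfg, target.probe_duration, seed=probe_seed)
        r_e = res.pool_rate("Z", "exc")
        r_i = res.pool_rate("Z", "inh")
        history.append({("Z", "exc"): r_e, ("Z", "inh"): r_i})
        err_e = target.rate_exc - r_e
        err_i = target.rate_inh - r_i
        if abs(err_e) <= target.tol_exc and abs(err_i) <= target.tol_inh:
            converged = True
            break
        new_ze = float(np.clip(_step(p_ze, err_e, target), 0.0, 1.0))
        new_zi = float(np.clip(_step(p_zi, err_i, target), 0.0, 1.0))
        clipped = (new_ze in (0.0, 1.0)) or (new_zi in (0.0, 1.0))
        p_ze, p_zi = new_ze, new_zi
        cfg = _with_z_probs(cfg, p_ze, p_zi)
    return CalibrationResult(
        config=cfg,
        rates={("Z", "exc"): r_e, ("Z", "inh"): r_i},
        drives={k: d.base_rate for k, d in cfg.drives.items()},
        iterations=it, converged=converged and not clipped,
        p_ze=p_ze, p_zi=p_zi, history=history)


# ---------------------------------------------------------------------------
def save_result(result: CalibrationResult, path) -> None:
    doc = {
        "drives": {f"{p}:{q}": r for (p, q), r in result.drives.items()},
        "rates": {f"{p}:{q}": r for (p, q), r in result.rates.items()},
        "iterations": result.iterations,
        "converged": result.converged,
        "p_ze": result.p_ze,
        "p_zi": result.p_zi,
        "config_hash": result.config.config_hash(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_drives(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {tuple(k.split(":")): v for k, v in doc["drives"].items()}
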