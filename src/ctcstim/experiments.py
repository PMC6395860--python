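"""Experiment suites reproducing the study's figures at configurable scale.

Each suite is a function returning plain dicts / DataFrames; the
``run_experiment`` dispatcher executes a named suite, writes its tables
(CSV/JSON) into an output directory together with a manifest, and
``summarize`` renders a compact report.  ``scale='desk'`` uses reduced
run counts/durations chosen for a single CPU; ``'full'`` restores the
study-scale numbers.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, coherence, control, netsim, phase, prc
from .params import NA

NOISE_GRID_DESK = (0.0, 0.075e-9, 0.15e-9)
NOISE_GRID_FULL = (0.0, 0.025e-9, 0.05e-9, 0.075e-9, 0.1e-9,
                   0.125e-9, 0.15e-9, 0.175e-9)
AMP_GRID_DESK = (-4e-9, -1e-9, 1e-9, 4e-9)
AMP_GRID_FULL = (-4e-9, -2e-9, -1e-9, -0.5e-9, -0.25e-9,
                 0.25e-9, 0.5e-9, 1e-9, 2e-9, 4e-9)

SCALES = {
    "desk": dict(noise_grid=NOISE_GRID_DESK, amp_grid=AMP_GRID_DESK,
                 prc_runs=300, routing_runs=20, run_seconds=10.0,
                 n_surrogates=100),
    "full": dict(noise_grid=NOISE_GRID_FULL, amp_grid=AMP_GRID_FULL,
                 prc_runs=2500, routing_runs=100, run_seconds=10.0,
                 n_surrogates=200),
}

EXPERIMENTS = ("single_column_noise_sweep", "phase_error", "prc_grid",
               "sync_task", "xyz_characterization", "switch_maps",
               "time_in_state", "routing")


@dataclasses.dataclass
class ExperimentSpec:
    name: str
    scale: str = "desk"
    seed: int = 0
    overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {EXPERIMENTS}")
        if self.scale not in SCALES:
            raise ValueError("scale must be 'desk' or 'full'")

    def params(self):
        p = dict(SCALES[self.scale])
        p.update(self.overrides)
        return p


# ---------------------------------------------------------------------------
# calibration caches (per process)
_COLUMN_CACHE: dict = {}
_XYZ_CACHE: dict = {}


def calibrated_column(noise: float, seed: int = 0,
                      target: calibrate.CalibrationTarget = None):
    """Single column with drives calibrated for this noise level."""
    key = (round(noise * 1e12), seed)
    if key not in _COLUMN_CACHE:
        cfg = netsim.build_single_column(noise_level=noise, seed=seed)
        _COLUMN_CACHE[key] = calibrate.calibrate_drives(
            cfg, target=target, seed=seed)
    return _COLUMN_CACHE[key]


def calibrated_xyz(noise: float, seed: int = 0,
                   target: calibrate.CalibrationTarget = None):
    """XYZ network with lower-layer drives and Z connectivity calibrated.

    The lower layer starts from the single-column calibration at the same
    noise level, then is re-calibrated inside the coupled network; the Z
    connection probabilities are tuned last.
    """
    key = (round(noise * 1e12), seed)
    if key not in _XYZ_CACHE:
        col = calibrated_column(noise, seed=seed, target=target)
        r = {p: (col.drives[("A", "exc")], col.drives[("A", "inh")])
             for p in ("X", "Y")}
        cfg = netsim.build_xyz_network(noise_level=noise, seed=seed, rates=r)
        cal = calibrate.calibrate_drives(cfg, target=target, seed=seed + 1)
        calz = calibrate.calibrate_z_connectivity(cal.config, target=target,
                                                  seed=seed + 2)
        _XYZ_CACHE[key] = calz
    return _XYZ_CACHE[key]


def xyz_state_machinery(config, seed: int = 0, train_duration: float = 10.0):
    """Bands, AR models and the empirical state frame for an XYZ config."""
    res = netsim.simulate(config, train_duration, seed=seed ^ 0x5EED)
    state_ctx = {}
    for key in [("Z", "current_from:X_e"), ("Z", "current_from:Y_e"),
                ("Z", "current_from:Z_i")]:
        tr = prc.analysis_trace(res, key[0], key[1])
        state_ctx[key] = prc.PhaseContext(
            band=phase.estimate_gamma_band(tr),
            model=phase.fit_ar(tr), component=key[1])
    bands = {k: c.band for k, c in state_ctx.items()}
    frame = control.fit_state_frame(res, bands)
    return state_ctx, bands, frame


# ---------------------------------------------------------------------------
def single_column_noise_sweep(spec: ExperimentSpec) -> dict:
    """Firing rates, spectral peak and SC̄ across internal noise levels."""
    p = spec.params()
    rows = []
    for noise in p["noise_grid"]:
        cal = calibrated_column(noise, seed=spec.seed)
        res = netsim.simulate(cal.config, p["run_seconds"],
                              seed=spec.seed + 17)
        tr = prc.analysis_trace(res, "A")
        band = phase.estimate_gamma_band(tr)
        fl = cal.config.drives[("A", "exc")].flicker
        sc = coherence.sc_score(
            coherence.flicker_trace(fl, res.duration), tr).sc_bar
        rows.append(dict(noise_nA=noise / NA,
                         rate_exc=res.pool_rate("A", "exc"),
                         rate_inh=res.pool_rate("A", "inh"),
                         f_peak=band.f_peak, f_lo=band.f_lo, f_hi=band.f_hi,
                         sc_bar=sc, converged=cal.converged,
                         s_e=cal.drives[("A", "exc")],
                         s_i=cal.drives[("A", "inh")]))
    return {"table": pd.DataFrame(rows)}


def phase_error(spec: ExperimentSpec) -> dict:
    """Real-time (AR-forecast) vs offline phase agreement per noise level."""
    p = spec.params()
    rows = []
    for noise in p["noise_grid"]:
        cal = calibrated_column(noise, seed=spec.seed)
        ctx = prc.train_phase_model(cal.config, "A", seed=spec.seed + 23)
        res = netsim.simulate(cal.config, p["run_seconds"],
                              seed=spec.seed + 29)
        tr = prc.analysis_trace(res, "A")
        pt = phase.offline_phase(tr, ctx.band)
        diffs = []
        for ms in range(1000, tr.samples.size - 100, 50):
            t = ms / 1000
            try:
                rp = phase.realtime_phase(ctx.model, tr.slice(0, t), t,
                                          band=ctx.band)
            except Exception:
                continue
            diffs.append(phase.wrap(rp - pt.phase[ms - 1]))
        cs = phase.circular_stats(np.asarray(diffs))
        circ_std = float(np.sqrt(-2 * np.log(max(cs.resultant, 1e-12))))
        rows.append(dict(noise_nA=noise / NA, mode=cs.mean,
                         circ_std=circ_std, n=len(diffs)))
    return {"table": pd.DataFrame(rows)}


def prc_batch(config, amplitudes, n_runs, seed, target=None, ctx=None,
              state_ctx=None, tau_grid=prc.DEFAULT_TAU_GRID):
    """One PRC collection: trials, shift data and mean PRCs per amplitude."""
    trials = prc.run_pulse_experiment(config, amplitudes, n_runs,
                                      seed=seed, target=target, ctx=ctx,
                                      state_ctx=state_ctx)
    out = {}
    for amp in amplitudes:
        sd = prc.pair_and_shift(trials[amp], trials[0.0], tau_grid=tau_grid)
        out[amp] = sd
    return trials, out


def prc_grid(spec: ExperimentSpec) -> dict:
    """Mean PRCs across pulse amplitudes and noise levels."""
    p = spec.params()
    tables = []
    for noise in p["noise_grid"]:
        cal = calibrated_column(noise, seed=spec.seed)
        ctx = prc.train_phase_model(cal.config, "A", seed=spec.seed + 23)
        trials, shifts = prc_batch(cal.config, list(p["amp_grid"]),
                                   p["prc_runs"], spec.seed + 31,
                                   target="A", ctx=ctx)
        for amp, sd in shifts.items():
            for tau in (0.03, 0.1):
                _, mprc = prc.estimate_prc_density(sd, tau)
                df = pd.DataFrame(dict(
                    phi=mprc.phi_grid, mean_shift=mprc.mean_shift,
                    q25=mprc.q25, q75=mprc.q75, resultant=mprc.resultant,
                    n=mprc.n))
                df["amp_nA"] = amp / NA
                df["noise_nA"] = noise / NA
                df["tau"] = mprc.tau
                tables.append(df)
    return {"table": pd.concat(tables, ignore_index=True)}


def sync_task(spec: ExperimentSpec) -> dict:
    """Closed-loop synchronization of two independent columns."""
    p = spec.params()
    noise = p.get("noise", 0.075e-9)
    amp = p.get("amp", 1e-9)
    cal = calibrated_column(noise, seed=spec.seed)
    # two-column network: duplicate the calibrated column, no coupling
    col = cal.config
    two = netsim.NetworkConfig(
        populations={n: dataclasses.replace(col.populations["A"])
                     for n in ("X", "Y")},
        synapses=col.synapses,
        projections=[dataclasses.replace(pr, source=(n, pr.source[1]),
                                         target=(n, pr.target[1]))
                     for n in ("X", "Y") for pr in col.projections],
        drives={(n, pool): dataclasses.replace(
                    col.drives[("A", pool)],
                    flicker=netsim.generate_flicker(
                        p["run_seconds"] + 1,
                        seed=spec.seed * 7 + (0 if n == "X" else 1)))
                for n in ("X", "Y") for pool in ("exc", "inh")},
        seed=col.seed)
    ctx_x = prc.train_phase_model(two, "X", seed=spec.seed + 41)
    ctx_y = prc.train_phase_model(two, "Y", seed=spec.seed + 43)
    # PRC of the column for the pulse amplitude in use (precomputed maps
    # can be injected through the overrides)
    mprc = p.get("mean_prc")
    if mprc is None:
        trials, shifts = prc_batch(col, [amp],
                                   p.get("sync_prc_runs", 300),
                                   spec.seed + 47, target="A")
        _, mprc = prc.estimate_prc_density(shifts[amp], 0.1, n_bins=12)
    cc = control.ControllerConfig(mode="sync", pulse_target="X",
                                  pulse_amplitude=amp, prc=mprc)
    log, res = control.run_sync_task(two, ctx_x, ctx_y, cc,
                                     p["run_seconds"], seed=spec.seed + 53)
    # passive comparison
    log_p, res_p = control.run_sync_task(
        two, ctx_x, ctx_y,
        dataclasses.replace(cc, threshold=np.pi - 1e-9), p["run_seconds"],
        seed=spec.seed + 59)
    return {"log": log, "result": res, "passive_log": log_p,
            "passive_result": res_p, "mean_prc": mprc,
            "table": pd.DataFrame([dict(
                noise_nA=noise / NA, amp_nA=amp / NA,
                time_in_target=log.time_in_target,
                time_in_target_passive=log_p.time_in_target,
                n_pulses=len(log.pulses))])}


def xyz_characterization(spec: ExperimentSpec) -> dict:
    """Passive XYZ statistics: states, phase distributions, routing."""
    p = spec.params()
    rows = []
    for noise in p["noise_grid"]:
        cal = calibrated_xyz(noise, seed=spec.seed)
        state_ctx, bands, frame = xyz_state_machinery(cal.config,
                                                      seed=spec.seed)
        res = netsim.simulate(netsim.with_new_flicker(cal.config,
                                                      spec.seed + 61),
                              p["run_seconds"], seed=spec.seed + 61)
        codes, pzx, pzy = control.classify_states_offline(res, bands, frame)
        act = codes >= 0
        sc = control.routing_scores(res)
        rows.append(dict(
            noise_nA=noise / NA,
            frac_trx=float(np.mean(codes[act] == 1)),
            frac_try=float(np.mean(codes[act] == 2)),
            frac_transition=float(np.mean(codes[act] == 0)),
            sc_x_to_z=sc["X"], sc_y_to_z=sc["Y"],
            rate_z_exc=res.pool_rate("Z", "exc"),
            p_ze=cal.p_ze, p_zi=cal.p_zi))
    return {"table": pd.DataFrame(rows)}


def switch_maps(spec: ExperimentSpec) -> dict:
    """State-switch probability maps for pulses into X, Y or Z."""
    p = spec.params()
    noise = p.get("noise", 0.075e-9)
    targets = p.get("targets", ("X", "Z"))
    cal = calibrated_xyz(noise, seed=spec.seed)
    state_ctx, bands, frame = xyz_state_machinery(cal.config, seed=spec.seed)
    maps = {}
    rows = []
    for target in targets:
        ctx = prc.train_phase_model(cal.config, target, seed=spec.seed + 67)
        trials = prc.run_pulse_experiment(
            cal.config, list(p["amp_grid"]), p.get("switch_runs", 150),
            seed=spec.seed + 71, target=target, ctx=ctx, state_ctx=state_ctx)
        passive = prc.control_self_shift(trials[0.0], state_key=True)
        for amp in p["amp_grid"]:
            sd = prc.pair_and_shift(trials[amp], trials[0.0],
                                    state_key=True)
            sm = prc.build_switch_map(sd, passive,
                                      condition=dict(target=target,
                                                     amp_nA=amp / NA,
                                                     noise_nA=noise / NA))
            maps[(target, amp)] = sm
            ti = int(np.argmin(np.abs(sm.tau_grid - 0.1)))
            for b in range(sm.phi_grid.size):
                rows.append(dict(target=target, amp_nA=amp / NA,
                                 noise_nA=noise / NA,
                                 phi=sm.phi_grid[b],
                                 p_sw=sm.p_sw[b, ti],
                                 delta_p_sw=sm.delta_p_sw[b, ti],
                                 p_passive=sm.p_passive[ti],
                                 n=int(sm.n[b, ti])))
    return {"maps": maps, "frame": frame, "state_ctx": state_ctx,
            "table": pd.DataFrame(rows)}


def time_in_state(spec: ExperimentSpec) -> dict:
    """Closed-loop switch controller: occupancy of the target state.

    The switch map is conditioned on trials whose onset state was the
    *wrong* (source) state when enough such trials exist — the onset
    phase that best flips a TrY-origin network is what the controller
    needs — falling back to the pooled map for sparse batches.  Occupancy
    of both the controlled and the passive run is measured offline with
    the same bands and state frame.
    """
    p = spec.params()
    noise = p.get("noise", 0.075e-9)
    target_pop = p.get("pulse_target", "X")
    amp = p.get("amp", 1e-9)
    target_state = p.get("target_state", "TrX")
    wrong_state = {"TrX": "TrY", "TrY": "TrX"}[target_state]
    duration = p.get("control_seconds", p["run_seconds"])
    cal = calibrated_xyz(noise, seed=spec.seed)
    state_ctx, bands, frame = xyz_state_machinery(cal.config, seed=spec.seed)
    pulse_ctx = prc.train_phase_model(cal.config, target_pop,
                                      seed=spec.seed + 67)
    sm = p.get("switch_map")
    if sm is None:
        trials = prc.run_pulse_experiment(
            cal.config, [amp], p.get("switch_runs", 150),
            seed=spec.seed + 71, target=target_pop, ctx=pulse_ctx,
            state_ctx=state_ctx)
        passive = prc.control_self_shift(trials[0.0], state_key=True)
        pulsed_src = [t for t in trials[amp]
                      if control.trial_state_label(t, frame) == wrong_state]
        ctrl_src = [t for t in trials[0.0]
                    if control.trial_state_label(t, frame) == wrong_state]
        if min(len(pulsed_src), len(ctrl_src)) >= 40:
            sd = prc.pair_and_shift(pulsed_src, ctrl_src, state_key=True)
        else:
            sd = prc.pair_and_shift(trials[amp], trials[0.0],
                                    state_key=True)
        sm = prc.build_switch_map(sd, passive, n_bins=8)
    ti = int(np.argmin(np.abs(sm.tau_grid - 0.1)))
    col = sm.delta_p_sw[:, ti]
    best = int(np.nanargmax(col))
    cc = control.ControllerConfig(
        mode="switch", pulse_target=target_pop, pulse_amplitude=amp,
        target_state=target_state, optimal_onset=float(sm.phi_grid[best]),
        frame=frame)
    log, res = control.run_switch_task(
        netsim.with_new_flicker(cal.config, spec.seed + 73), state_ctx,
        pulse_ctx, cc, duration, seed=spec.seed + 73)
    target_code = control.STATE_CODES[target_state]

    def occupancy(result):
        codes, _, _ = control.classify_states_offline(result, bands, frame)
        act = codes >= 0
        return float(np.mean(codes[act] == target_code)) if act.any() \
            else np.nan

    # passive baseline from an unpulsed run of equal duration
    res_p = netsim.simulate(netsim.with_new_flicker(cal.config,
                                                    spec.seed + 79),
                            duration, seed=spec.seed + 79)
    baseline = occupancy(res_p)
    tit = occupancy(res)
    return {"log": log, "result": res, "switch_map": sm, "frame": frame,
            "baseline": baseline,
            "table": pd.DataFrame([dict(
                noise_nA=noise / NA, amp_nA=amp / NA, target=target_pop,
                time_in_target=tit,
                time_in_target_online=log.time_in_target,
                baseline_passive=baseline,
                optimal_onset=cc.optimal_onset,
                max_delta_p_sw=float(np.nanmax(col)),
                n_pulses=len(log.pulses))])}


def routing(spec: ExperimentSpec) -> dict:
    """State-conditioned signal routing in passive runs (CTC property).

    Pools SC̄(S_X→Z) over the TrX-state and TrY-state time masks of
    ``routing_runs`` independent runs.
    """
    p = spec.params()
    noise = p.get("noise", 0.075e-9)
    cal = calibrated_xyz(noise, seed=spec.seed)
    state_ctx, bands, frame = xyz_state_machinery(cal.config, seed=spec.seed)
    freqs = coherence.DEFAULT_FREQS
    sources = p.get("sources", ("X", "Y"))
    per_run = []
    for r in range(p["routing_runs"]):
        cfg = netsim.with_new_flicker(cal.config, spec.seed + 1000 + r)
        res = netsim.simulate(cfg, p["run_seconds"],
                              seed=spec.seed + 1000 + r)
        codes, _, _ = control.classify_states_offline(res, bands, frame)
        out_tr = prc.analysis_trace(res, "Z")
        sy = coherence.morlet_spectrogram(out_tr, freqs)
        row = {}
        for src in sources:
            fl = cfg.drives[(src, "exc")].flicker
            sx = coherence.morlet_spectrogram(
                coherence.flicker_trace(fl, res.duration), freqs)
            for state, code in (("trx", 1), ("try", 2)):
                cmap = masked_coherence(sx, sy, codes == code)
                cone = coherence.ConeOfInterest(
                    tau_center=coherence.estimate_tau_xy(cmap))
                row[f"sc_{src.lower()}_{state}"] = coherence.pool_sc(
                    cmap, cone)
        per_run.append(row)
    df = pd.DataFrame(per_run)
    return {"table": df, "per_run": per_run}


def masked_coherence(spec_x, spec_y, time_mask, lags=None):
    """Spectral coherence restricted to a boolean time mask on x-samples."""
    n = spec_x.coeffs.shape[1]
    dt = float(np.mean(np.diff(spec_x.times))) if n > 1 else 1e-3
    if lags is None:
        m = int(round(coherence.DEFAULT_LAG_RANGE / dt))
        lag_samples = np.arange(-m, m + 1)
    else:
        lag_samples = np.round(np.asarray(lags, float) / dt).astype(int)
    Wx, Wy = spec_x.coeffs, spec_y.coeffs
    ax2, ay2 = np.abs(Wx) ** 2, np.abs(Wy) ** 2
    idx_all = np.nonzero(time_mask)[0]
    out = np.zeros((Wx.shape[0], lag_samples.size))
    for li, L in enumerate(lag_samples):
        idx = idx_all[(idx_all + L >= 0) & (idx_all + L < n)]
        if idx.size == 0:
            continue
        num = np.abs(np.sum(np.conj(Wx[:, idx]) * Wy[:, idx + L], axis=1))
        den = np.sqrt(np.sum(ax2[:, idx], axis=1)
                      * np.sum(ay2[:, idx + L], axis=1))
        good = den > 0
        out[good, li] = num[good] / den[good]
    return coherence.CoherenceMap(values=np.clip(out, 0, 1),
                                  freqs=spec_x.freqs,
                                  lags=lag_samples * dt)


# ---------------------------------------------------------------------------
_SUITES = {
    "single_column_noise_sweep": single_column_noise_sweep,
    "phase_error": phase_error,
    "prc_grid": prc_grid,
    "sync_task": sync_task,
    "xyz_characterization": xyz_characterization,
    "switch_maps": switch_maps,
    "time_in_state": time_in_state,
    "routing": routing,
}


def run_experiment(spec: ExperimentSpec, out_dir=None) -> dict:
    """Execute a named suite; optionally write its tables + manifest."""
    t0 = time.time()
    result = _SUITES[spec.name](spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, val in result.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{spec.name}_{key}.csv", index=False)
        manifest = dict(name=spec.name, scale=spec.scale, seed=spec.seed,
                        overrides={k: str(v)
                                   for k, v in spec.overrides.items()},
                        wall_seconds=round(time.time() - t0, 1),
                        outputs=sorted(f.name for f in out.iterdir()))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def summarize(bundle_dir) -> pd.DataFrame:
    """Concatenate the CSV tables of a results bundle into one report."""
    out = Path(bundle_dir)
    frames = []
    for f in sorted(out.glob("*_table.csv")):
        df = pd.read_csv(f)
        df.insert(0, "experiment", f.stem.replace("_table", ""))
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
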