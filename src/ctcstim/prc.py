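"""Stochastic phase-response curves and state-switch probability maps.

The network is a noisy oscillator, so a PRC cannot be read off a single
perturbed run.  Instead many short runs are simulated with a 1 ms current
pulse at a fixed time (plus a no-pulse control group sharing the
generator), the phase at pulse onset is estimated causally with the AR
forecaster, pulsed and control trials are paired by minimal circular
onset-phase distance (and, in the three-column network, by network
state), and the induced shift at delay tau is the circular difference of
the two offline phase traces read tau after the onset.  Binning the
shifts by onset phase gives the phase-response density rho_tau(dphi|phi),
condensed to a mean PRC via circular means per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import netsim
from .params import StimulationPulse
from .phase import (
    AnalogTrace, ARModel, BandpassSpec, PhaseTrace, RATE_SMOOTH,
    circular_stats, circdist, estimate_gamma_band, fit_ar, offline_phase,
    realtime_phase, wrap,
)

#: raw signal zeroed from pulse onset to onset + duration + this margin (s)
ARTIFACT_MARGIN = 0.010
DEFAULT_TAU_GRID = np.arange(0.0, 0.1501, 0.005)
DEFAULT_N_BINS = 36
MIN_BIN_SAMPLES = 10


def analysis_trace(result, population: str,
                   component: str = "exc_rate") -> AnalogTrace:
    """Default phase-analysis signal: boxcar-smoothed population signal."""
    tr = netsim.extract_population_signal(result, population, component)
    if component.endswith("_rate"):
        tr = tr.smoothed(RATE_SMOOTH)
    return tr


@dataclass
class PhaseContext:
    """Band + AR model trained on unperturbed activity for one signal."""

    band: BandpassSpec
    model: ARModel
    component: str = "exc_rate"


def train_phase_model(config, population: str, seed: int,
                      component: str = "exc_rate",
                      train_duration: float = 10.0,
                      order: int = 15) -> PhaseContext:
    """Fit the gamma band and the Burg AR forecaster on a clean run."""
    res = netsim.simulate(config, train_duration, seed=seed)
    tr = analysis_trace(res, population, component)
    band = estimate_gamma_band(tr)
    model = fit_ar(tr, order=order)
    return PhaseContext(band=band, model=model, component=component)


@dataclass
class PulseTrial:
    onset_time: float
    onset_phase: float
    amplitude: float
    target: str
    phase_traces: dict                      # key -> PhaseTrace
    state_at_onset: Optional[tuple] = None  # (phi_zx, phi_zy) for XYZ
    seed: int = 0


@dataclass
class ShiftData:
    """Paired phase shifts Delta-phi(phi; tau) on a tau grid."""

    onset_phases: np.ndarray     # (n_pairs,)
    shifts: np.ndarray           # (n_pairs, n_tau), NaN where masked
    tau_grid: np.ndarray
    onset_states: Optional[np.ndarray] = None
    unmatched_fraction: float = 0.0
    #: circular onset-phase distance of each matched pair; residual
    #: mismatch propagates into the shifts as a per-pair bias
    onset_mismatch: Optional[np.ndarray] = None


@dataclass
class PRCDensity:
    phi_edges: np.ndarray
    shift_edges: np.ndarray
    density: np.ndarray          # (n_phi, n_shift); columns sum to 1 or 0
    n_per_bin: np.ndarray
    tau: float


@dataclass
class MeanPRC:
    phi_grid: np.ndarray         # bin centers
    mean_shift: np.ndarray       # NaN where undefined
    q25: np.ndarray
    q75: np.ndarray
    resultant: np.ndarray
    n: np.ndarray
    tau: float


@dataclass
class SwitchMap:
    phi_grid: np.ndarray
    tau_grid: np.ndarray
    p_sw: np.ndarray             # (n_phi, n_tau)
    p_passive: np.ndarray        # (n_tau,)
    delta_p_sw: np.ndarray       # (n_phi, n_tau)
    n: np.ndarray
    condition: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
def _phase_signal_keys(config, target):
    """Signals whose offline phase each trial records (kept minimal)."""
    keys = [(target, "exc_rate")]
    if set(config.populations) >= {"X", "Y", "Z"}:
        keys += [("Z", "current_from:X_e"), ("Z", "current_from:Y_e"),
                 ("Z", "current_from:Z_i")]
    return keys


def state_phases(phase_traces: dict, t: float):
    """(Phi_ZX, Phi_ZY) from the current-component phases at time t."""
    px = phase_traces[("Z", "current_from:X_e")].at_time(t)
    py = phase_traces[("Z", "current_from:Y_e")].at_time(t)
    pz = phase_traces[("Z", "current_from:Z_i")].at_time(t)
    return wrap(px - pz), wrap(py - pz)


def run_pulse_experiment(config, amplitudes: Sequence[float], n_runs,
                         run_length: float = 1.0, pulse_time: float = 0.5,
                         seed: int = 0, target: Optional[str] = None,
                         ctx: Optional[PhaseContext] = None,
                         state_ctx: Optional[dict] = None,
                         pulse_jitter: float = 0.020) -> dict:
    """Simulate pulsed runs plus delta-I = 0 controls.

    Returns {amplitude: [PulseTrial, ...]}; amplitude 0.0 is always
    included as the control group.  ``n_runs`` may be a mapping
    {amplitude: count} for unequal group sizes.  The onset phase is AR-forecast from
    pre-pulse data only; trials whose onset phase cannot be estimated are
    discarded.  Each run's pulse (and each control's reference time) is
    jittered uniformly by up to ``pulse_jitter`` (at least one gamma
    cycle) so pulses land at random points of the cycle: the startup
    transient is stereotyped enough that a fixed pulse time would sample
    onset phases very unevenly.
    """
    if not (pulse_time >= 0.4 and run_length - pulse_time >= 0.4):
        raise ValueError("pulse must leave >= 0.4 s of signal on each side")
    pops = list(config.populations)
    target = target or pops[0]
    is_xyz = set(pops) >= {"X", "Y", "Z"}
    if ctx is None:
        ctx = train_phase_model(config, target, seed=seed ^ 0x5EED)
    if is_xyz and state_ctx is None:
        state_ctx = {}
        res = netsim.simulate(config, 10.0, seed=seed ^ 0x5EED)
        for key in [("Z", "current_from:X_e"), ("Z", "current_from:Y_e"),
                    ("Z", "current_from:Z_i")]:
            tr = analysis_trace(res, key[0], key[1])
            state_ctx[key] = PhaseContext(band=estimate_gamma_band(tr),
                                          model=fit_ar(tr), component=key[1])

    amps = list(dict.fromkeys([0.0] + [float(a) for a in amplitudes]))
    sig_keys = _phase_signal_keys(config, target)
    if isinstance(n_runs, dict):
        counts = {a: int(n_runs.get(a, max(n_runs.values()))) for a in amps}
    else:
        counts = {a: int(n_runs) for a in amps}
    out = {a: [] for a in amps}
    for ai, amp in enumerate(amps):
        for run in range(counts[amp]):
            run_seed = (seed * 1_000_003 + ai * 7919 + run) & 0x7FFFFFFF
            jit = np.random.default_rng(
                np.random.SeedSequence([run_seed, 0x71]))
            t_on = pulse_time + float(jit.uniform(0.0, pulse_jitter))
            pulses = []
            windows = []
            if amp != 0.0:
                p = StimulationPulse(target=target, amplitude=amp,
                                     onset=t_on)
                pulses.append(p)
                # start early: the centered rate boxcar smears the evoked
                # burst one sample backward
                windows.append((t_on - 0.002,
                                t_on + p.duration + ARTIFACT_MARGIN))
            run_cfg = netsim.with_new_flicker(config, run_seed)
            res = netsim.simulate(run_cfg, run_length, pulses=pulses,
                                  seed=run_seed)
            traces = {}
            for key in sig_keys:
                tr = analysis_trace(res, key[0], key[1])
                band = (state_ctx[key].band if state_ctx and key in state_ctx
                        else ctx.band)
                # artifact_guard=0: the blanked pulse window is smoothly
                # interpolated by the zero-phase filter, so early-tau
                # shifts stay readable (only the blank itself is masked)
                traces[key] = offline_phase(tr, band,
                                            artifact_windows=windows,
                                            artifact_guard=0.0)
            # causal onset-phase estimate from pre-pulse data only
            # history must end strictly before the pulse: slice the *raw*
            # signal (centered smoothing would leak the evoked burst
            # backward), drop the bin containing the onset, then smooth
            t_clean = np.floor(t_on * 1000 - 1e-6) / 1000
            raw = netsim.extract_population_signal(res, target,
                                                   ctx.component)
            hist = raw.slice(0.0, t_clean)
            if ctx.component.endswith("_rate"):
                hist = hist.smoothed(RATE_SMOOTH)
            try:
                onset_phase = realtime_phase(ctx.model, hist, t_clean,
                                             band=ctx.band, read_at=t_on)
            except Exception:
                continue  # discarded trial
            state = None
            if is_xyz:
                sx = {}
                for key, c in state_ctx.items():
                    h = netsim.extract_population_signal(
                        res, key[0], key[1]).slice(0.0, t_clean)
                    sx[key] = realtime_phase(c.model, h, t_clean,
                                             band=c.band, read_at=t_on)
                pzx = wrap(sx[("Z", "current_from:X_e")]
                           - sx[("Z", "current_from:Z_i")])
                pzy = wrap(sx[("Z", "current_from:Y_e")]
                           - sx[("Z", "current_from:Z_i")])
                state = (pzx, pzy)
            out[amp].append(PulseTrial(
                onset_time=t_on, onset_phase=onset_phase,
                amplitude=amp, target=target, phase_traces=traces,
                state_at_onset=state, seed=run_seed))
    return out


# ---------------------------------------------------------------------------
def _greedy_pairs(pulsed, controls, state_tol):
    np_, nc = len(pulsed), len(controls)
    dist = np.empty((np_, nc))
    for i, p in enumerate(pulsed):
        for j, c in enumerate(controls):
            d = circdist(p.onset_phase, c.onset_phase)
            if state_tol is not None and p.state_at_onset is not None:
                dzx = circdist(p.state_at_onset[0], c.state_at_onset[0])
                dzy = circdist(p.state_at_onset[1], c.state_at_onset[1])
                if dzx > state_tol or dzy > state_tol:
                    d = np.inf
            dist[i, j] = d
    pairs = []
    used_p = np.zeros(np_, bool)
    used_c = np.zeros(nc, bool)
    order = np.argsort(dist, axis=None, kind="stable")
    for flat in order:
        i, j = divmod(int(flat), nc)
        if used_p[i] or used_c[j] or not np.isfinite(dist[i, j]):
            continue
        used_p[i] = used_c[j] = True
        pairs.append((i, j))
        if len(pairs) == min(np_, nc):
            break
    return pairs


def _read_shift(trace_p: PhaseTrace, trace_c: PhaseTrace, t: float) -> float:
    try:
        return wrap(trace_p.at_time(t) - trace_c.at_time(t))
    except Exception:
        return np.nan


def pair_and_shift(pulsed_trials, control_trials,
                   tau_grid=DEFAULT_TAU_GRID,
                   signal_key=None, state_key: bool = False,
                   state_tol: float = 0.2) -> ShiftData:
    """Greedy onset-phase matching and circular shift computation.

    ``signal_key`` selects which recorded phase trace the shift is read
    from (default: the pulsed target's rate phase).  With
    ``state_key=True`` the shift is computed on the phase *difference*
    Phi_ZX instead (state-switch analysis).
    """
    if not pulsed_trials or not control_trials:
        raise ValueError("both trial groups must be nonempty")
    tau_grid = np.asarray(tau_grid, float)
    tol = state_tol if pulsed_trials[0].state_at_onset is not None else None
    pairs = _greedy_pairs(pulsed_trials, control_trials, tol)
    n_unmatched = min(len(pulsed_trials), len(control_trials)) - len(pairs)
    frac_unmatched = n_unmatched / max(1, min(len(pulsed_trials),
                                              len(control_trials)))
    if frac_unmatched > 0.2:
        import warnings
        warnings.warn(f"{frac_unmatched:.0%} of trials unmatched "
                      f"(onset-phase/state coverage too sparse)")

    if signal_key is None:
        p0 = pulsed_trials[0]
        signal_key = (p0.target, "exc_rate")

    onset_phases = np.empty(len(pairs))
    onset_states = (np.empty((len(pairs), 2))
                    if pulsed_trials[0].state_at_onset is not None else None)
    shifts = np.full((len(pairs), tau_grid.size), np.nan)
    mismatch = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        p, c = pulsed_trials[i], control_trials[j]
        onset_phases[k] = p.onset_phase
        mismatch[k] = float(circdist(p.onset_phase, c.onset_phase))
        if onset_states is not None:
            onset_states[k] = p.state_at_onset
        for ti, tau in enumerate(tau_grid):
            tp = p.onset_time + tau
            tc = c.onset_time + tau
            if state_key:
                try:
                    zx_p = state_phases(p.phase_traces, tp)[0]
                    zx_c = state_phases(c.phase_traces, tc)[0]
                    shifts[k, ti] = wrap(zx_p - zx_c)
                except Exception:
                    shifts[k, ti] = np.nan
            else:
                try:
                    shifts[k, ti] = wrap(
                        p.phase_traces[signal_key].at_time(tp)
                        - c.phase_traces[signal_key].at_time(tc))
                except Exception:
                    shifts[k, ti] = np.nan
    return ShiftData(onset_phases=onset_phases, shifts=shifts,
                     tau_grid=tau_grid, onset_states=onset_states,
                     unmatched_fraction=frac_unmatched,
                     onset_mismatch=mismatch)


# ---------------------------------------------------------------------------
def estimate_prc_density(shift_data: ShiftData, tau: float,
                         n_bins: int = DEFAULT_N_BINS,
                         min_bin_samples: int = MIN_BIN_SAMPLES):
    """Binned conditional density rho_tau(dphi|phi) and its mean PRC."""
    ti = int(np.argmin(np.abs(shift_data.tau_grid - tau)))
    phi = shift_data.onset_phases
    dphi = shift_data.shifts[:, ti]
    ok = np.isfinite(dphi)
    phi, dphi = phi[ok], dphi[ok]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    phi_idx = np.clip(np.digitize(phi, edges) - 1, 0, n_bins - 1)

    density = np.zeros((n_bins, n_bins))
    counts = np.zeros(n_bins, int)
    mean = np.full(n_bins, np.nan)
    q25 = np.full(n_bins, np.nan)
    q75 = np.full(n_bins, np.nan)
    res = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = phi_idx == b
        counts[b] = sel.sum()
        if counts[b] == 0:
            continue
        h, _ = np.histogram(dphi[sel], bins=edges)
        density[b] = h / counts[b]
        if counts[b] >= min_bin_samples:
            cs = circular_stats(dphi[sel])
            res[b] = cs.resultant
            if cs.defined:
                mean[b] = cs.mean
                q25[b] = cs.q25
                q75[b] = cs.q75
    centers = 0.5 * (edges[:-1] + edges[1:])
    tau_actual = float(shift_data.tau_grid[ti])
    return (PRCDensity(phi_edges=edges, shift_edges=edges, density=density,
                       n_per_bin=counts, tau=tau_actual),
            MeanPRC(phi_grid=centers, mean_shift=mean, q25=q25, q75=q75,
                    resultant=res, n=counts, tau=tau_actual))


def switch_probability(density: np.ndarray, edges: np.ndarray = None) -> float:
    """p_sw = 1 - integral of rho(dPhi) over (-pi/2, pi/2).

    ``density`` is a normalized histogram over shift bins; bins are
    attributed to the stay interval by their center.
    """
    density = np.asarray(density, float)
    if edges is None:
        edges = np.linspace(-np.pi, np.pi, density.size + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    stay = np.abs(centers) < np.pi / 2
    total = density.sum()
    if total <= 0:
        return np.nan
    return float(1.0 - density[stay].sum() / total)


def switch_probability_samples(dphi: np.ndarray) -> float:
    d = np.asarray(dphi, float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return np.nan
    return float(np.mean(np.abs(wrap(d)) >= np.pi / 2))


def build_switch_map(pulsed_shift: ShiftData, passive_shift: ShiftData,
                     n_bins: int = 12, condition: dict = None) -> SwitchMap:
    """Per-onset-phase switch probabilities versus the passive chance.

    ``passive_shift`` is the control-vs-control shift data (delta-I = 0
    paired against itself) providing p_passive(tau).
    """
    tau_grid = pulsed_shift.tau_grid
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    phi_idx = np.clip(np.digitize(pulsed_shift.onset_phases, edges) - 1,
                      0, n_bins - 1)
    p_sw = np.full((n_bins, tau_grid.size), np.nan)
    n = np.zeros((n_bins, tau_grid.size), int)
    for b in range(n_bins):
        sel = phi_idx == b
        if not sel.any():
            continue
        for ti in range(tau_grid.size):
            d = pulsed_shift.shifts[sel, ti]
            d = d[np.isfinite(d)]
            n[b, ti] = d.size
            if d.size:
                p_sw[b, ti] = switch_probability_samples(d)
    p_passive = np.array([
        switch_probability_samples(passive_shift.shifts[:, ti])
        for ti in range(tau_grid.size)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SwitchMap(phi_grid=centers, tau_grid=tau_grid, p_sw=p_sw,
                     p_passive=p_passive, delta_p_sw=p_sw - p_passive[None, :],
                     n=n, condition=condition or {})


def control_self_shift(control_trials, tau_grid=DEFAULT_TAU_GRID,
                       **kwargs) -> ShiftData:
    """Pair the control group against itself (disjoint halves)."""
    half = len(control_trials) // 2
    return pair_and_shift(control_trials[:half], control_trials[half:],
                          tau_grid=tau_grid, **kwargs)


# ---------------------------------------------------------------------------
def settle_time(mean_prcs: Sequence[MeanPRC], tolerance: float = 0.15):
    """Smallest tau after which consecutive mean PRCs stop changing.

    Returns the tau of the first curve such that every subsequent
    consecutive pair differs by less than ``tolerance`` radians (circular
    distance averaged over onset-phase bins defined in both curves), or
    ``None`` if the sequence never settles.
    """
    taus = np.array([m.tau for m in mean_prcs])
    if np.any(np.diff(taus) <= 0):
        raise ValueError("mean PRCs must be ordered by increasing tau")
    dists = []
    for a, b in zip(mean_prcs[:-1], mean_prcs[1:]):
        ok = np.isfinite(a.mean_shift) & np.isfinite(b.mean_shift)
        if not ok.any():
            dists.append(np.inf)
        else:
            dists.append(float(np.mean(circdist(a.mean_shift[ok],
                                                b.mean_shift[ok]))))
    dists = np.asarray(dists)
    for i in range(dists.size):
        if np.all(dists[i:] < tolerance):
            return float(taus[i])
    return None


# ---------------------------------------------------------------------------
def export_mean_prc(mprc: MeanPRC, path, condition: dict = None) -> None:
    """CSV export (phi_bin, tau, mean_shift, q25, q75, resultant, n)."""
    import pandas as pd

    df = pd.DataFrame({
        "phi_bin": mprc.phi_grid, "tau": mprc.tau,
        "mean_shift": mprc.mean_shift, "q25": mprc.q25, "q75": mprc.q75,
        "resultant": mprc.resultant, "n": mprc.n,
    })
    for k, v in (condition or {}).items():
        df[k] = v
    df.to_csv(path, index=False)


def export_switch_map(sm: SwitchMap, path) -> None:
    """Long-format CSV export of a switch-probability map."""
    import pandas as pd

    rows = []
    for b, phi in enumerate(sm.phi_grid):
        for ti, tau in enumerate(sm.tau_grid):
            rows.append(dict(phi_bin=phi, tau=tau, p_sw=sm.p_sw[b, ti],
                             delta_p_sw=sm.delta_p_sw[b, ti],
                             p_passive=sm.p_passive[ti],
                             n=int(sm.n[b, ti]), **sm.condition))
    pd.DataFrame(rows).to_csv(path, index=False)
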