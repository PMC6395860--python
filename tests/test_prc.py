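"""PRC estimation machinery on constructed phase traces (no simulation)."""

import numpy as np
import pytest

from ctcstim import prc
from ctcstim.phase import PhaseTrace, wrap

TAU = np.arange(0.0, 0.101, 0.005)


def _trial(onset_phase, amplitude=1e-9, f=65.0, trace_offset=0.0,
           fs=1000.0, duration=1.0, onset_time=0.5, state=None):
    """Trial with an ideal constant-frequency phase trace.

    ``trace_offset`` shifts the recorded trace relative to the reported
    onset phase — emulating a pulse-induced shift of known size while the
    pre-pulse (onset) phase stays what it was.
    """
    t = np.arange(int(duration * fs)) / fs
    ph = wrap(2 * np.pi * f * (t - onset_time) + onset_phase + trace_offset)
    pt = PhaseTrace(phase=ph, fs=fs, valid_mask=np.ones(t.size, bool))
    return prc.PulseTrial(onset_time=onset_time,
                          onset_phase=wrap(onset_phase),
                          amplitude=amplitude, target="A",
                          phase_traces={("A", "exc_rate"): pt},
                          state_at_onset=state)


def _grid_trials(n=40, **kw):
    phases = np.linspace(-np.pi, np.pi, n, endpoint=False)
    return [_trial(p, **kw) for p in phases]


def test_identical_groups_give_zero_shifts():
    trials = _grid_trials()
    sd = prc.pair_and_shift(trials, list(trials), tau_grid=TAU)
    assert np.allclose(sd.shifts, 0.0, atol=1e-9)
    assert sd.unmatched_fraction == 0.0


def test_constant_offset_recovered():
    pulsed = _grid_trials(trace_offset=np.pi / 4)
    controls = _grid_trials()
    sd = prc.pair_and_shift(pulsed, controls, tau_grid=TAU)
    assert np.allclose(wrap(sd.shifts), np.pi / 4, atol=1e-6)


def test_shift_wraps_correctly_near_pi():
    # control at pi - 0.1, pulsed at -pi + 0.1 -> shift +0.2, not -2pi + 0.2
    pulsed = [_trial(-np.pi + 0.1)]
    control = [_trial(np.pi - 0.1)]
    sd = prc.pair_and_shift(pulsed, control, tau_grid=TAU)
    assert np.allclose(sd.shifts, 0.2, atol=1e-6)


def test_masked_samples_yield_nan_not_values():
    pulsed = _grid_trials()
    controls = _grid_trials()
    for tr in pulsed:
        tr.phase_traces[("A", "exc_rate")].valid_mask[550:] = False
    sd = prc.pair_and_shift(pulsed, controls, tau_grid=TAU)
    late = TAU > 0.049
    assert np.all(np.isnan(sd.shifts[:, late]))
    assert np.all(np.isfinite(sd.shifts[:, ~late]))


def test_density_columns_normalize():
    rng = np.random.default_rng(3)
    pulsed = [_trial(p, trace_offset=rng.normal(0, 0.5))
              for p in rng.uniform(-np.pi, np.pi, 400)]
    controls = [_trial(p) for p in rng.uniform(-np.pi, np.pi, 400)]
    sd = prc.pair_and_shift(pulsed, controls, tau_grid=TAU)
    dens, _ = prc.estimate_prc_density(sd, 0.05)
    sums = dens.density.sum(axis=1)
    occupied = dens.n_per_bin > 0
    assert np.allclose(sums[occupied], 1.0, atol=1e-12)
    assert np.allclose(sums[~occupied], 0.0)


def test_full_reset_gives_slope_minus_one_line():
    # closed-form oracle: if the final phase c is independent of the onset
    # phase phi, the shift is wrap(c - phi)
    c = 0.7
    rng = np.random.default_rng(8)
    phases = rng.uniform(-np.pi, np.pi, 600)
    pulsed = [_trial(ph, trace_offset=wrap(c - ph)) for ph in phases]
    controls = [_trial(ph) for ph in rng.uniform(-np.pi, np.pi, 600)]
    sd = prc.pair_and_shift(pulsed, controls, tau_grid=TAU)
    _, mprc = prc.estimate_prc_density(sd, 0.05, n_bins=12)
    ok = np.isfinite(mprc.mean_shift)
    expect = wrap(c - mprc.phi_grid[ok])
    assert np.max(np.abs(wrap(mprc.mean_shift[ok] - expect))) < 0.3


def test_all_zero_shifts_give_flat_mean_prc():
    trials = _grid_trials(n=200)
    sd = prc.pair_and_shift(trials, list(trials), tau_grid=TAU)
    _, mprc = prc.estimate_prc_density(sd, 0.05, n_bins=8)
    ok = np.isfinite(mprc.mean_shift)
    assert ok.any()
    assert np.allclose(mprc.mean_shift[ok], 0.0, atol=1e-9)
    assert np.allclose(mprc.resultant[ok], 1.0, atol=1e-9)


def test_state_matching_constrains_pairs():
    pulsed = [_trial(0.0, state=(0.0, np.pi))]
    controls = [_trial(0.01, state=(np.pi, 0.0)),
                _trial(1.5, state=(0.05, np.pi - 0.05))]
    sd = prc.pair_and_shift(pulsed, controls, tau_grid=TAU, state_tol=0.2)
    # the phase-closer control has an incompatible state; the state-matched
    # one must win despite the larger onset-phase distance
    assert sd.onset_phases.size == 1
    assert np.allclose(wrap(sd.shifts[0]), wrap(0.0 - 1.5), atol=1e-6)


# --- switch probability -----------------------------------------------------
def test_switch_probability_point_masses_and_uniform():
    edges = np.linspace(-np.pi, np.pi, 37)
    dens = np.zeros(36)
    dens[18] = 1.0                     # point mass at ~0
    assert prc.switch_probability(dens, edges) == 0.0
    dens = np.zeros(36)
    dens[0] = 1.0                      # point mass at ~-pi
    assert prc.switch_probability(dens, edges) == 1.0
    uniform = np.full(36, 1 / 36)
    # analytic integral: half the mass lies outside (-pi/2, pi/2)
    assert prc.switch_probability(uniform, edges) == pytest.approx(0.5)


def test_switch_probability_samples():
    assert prc.switch_probability_samples(np.zeros(50)) == 0.0
    assert prc.switch_probability_samples(np.full(50, np.pi)) == 1.0
    d = np.concatenate([np.zeros(30), np.full(10, 3.0), [np.nan] * 5])
    assert prc.switch_probability_samples(d) == pytest.approx(0.25)


# --- settle time ------------------------------------------------------------
def _mean_prc(tau, shift_fn):
    phi = np.linspace(-np.pi, np.pi, 12, endpoint=False) + np.pi / 12
    m = shift_fn(phi, tau)
    return prc.MeanPRC(phi_grid=phi, mean_shift=m, q25=m, q75=m,
                       resultant=np.ones_like(phi),
                       n=np.full(phi.size, 100), tau=tau)


def test_settle_time_constant_curves():
    taus = np.arange(0.0, 0.1, 0.005)
    curves = [_mean_prc(t, lambda p, t: np.sin(p)) for t in taus]
    assert prc.settle_time(curves) == 0.0


def test_settle_time_converging_sequence():
    taus = np.arange(0.0, 0.1, 0.005)
    # curve drifts until tau = 30 ms, then freezes
    curves = [_mean_prc(t, lambda p, t: np.sin(p) + 100 * max(0.03 - t, 0.0))
              for t in taus]
    assert prc.settle_time(curves) == pytest.approx(0.03, abs=1e-9)


def test_settle_time_never_converges():
    taus = np.arange(0.0, 0.1, 0.005)
    curves = [_mean_prc(t, lambda p, t: np.sin(p) + 100 * t) for t in taus]
    assert prc.settle_time(curves) is None


def test_settle_time_requires_increasing_taus():
    curves = [_mean_prc(t, lambda p, t: np.sin(p)) for t in (0.01, 0.01)]
    with pytest.raises(ValueError):
        prc.settle_time(curves)
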