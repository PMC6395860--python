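"""Network construction, noise/flicker generators, and integration."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

from ctcstim import netsim
from ctcstim.params import (DriveSpec, NA, NetworkConfig, PopulationParams,
                            Projection, StimulationPulse,
                            SynapseKernelParams)


# --- builders ---------------------------------------------------------------
def test_single_column_structure():
    cfg = netsim.build_single_column(seed=0, drive_duration=0.5)
    pp = cfg.populations["A"]
    assert (pp.n_exc, pp.n_inh) == (800, 200)
    assert len(cfg.projections) == 2
    for proj in cfg.projections:
        assert proj.kind == "inhibitory"
        assert proj.prob == 0.5
        assert proj.delay == pytest.approx(5e-3)
        assert proj.source == ("A", "inh")
    assert {p.target for p in cfg.projections} == {("A", "exc"), ("A", "inh")}
    assert set(cfg.drives) == {("A", "exc"), ("A", "inh")}


def test_single_column_zero_noise_means_silent_noise_term():
    cfg = netsim.build_single_column(noise_level=0.0, seed=0,
                                     drive_duration=0.2)
    from ctcstim._engine import Engine
    eng = Engine(cfg, 0.1, seed=4)
    assert not eng.has_noise
    assert np.all(eng.sigma_vec == 0.0)


def test_xyz_structure_and_no_feedback_from_z():
    cfg = netsim.build_xyz_network(seed=0, drive_duration=0.5)
    assert set(cfg.populations) == {"X", "Y", "Z"}
    from_z = [p for p in cfg.projections
              if p.source[0] == "Z" and p.target[0] != "Z"]
    assert from_z == []
    cross = {(p.source, p.target) for p in cfg.projections
             if p.source[0] != p.target[0]}
    assert (("X", "exc"), ("Y", "inh")) in cross
    assert (("Y", "exc"), ("X", "inh")) in cross
    assert (("X", "exc"), ("Z", "exc")) in cross
    assert (("Y", "exc"), ("Z", "inh")) in cross


def test_xyz_cross_synapse_count_within_binomial_interval():
    # oracle: X_e -> Y_i sampling is Binomial(800*200, 0.02)
    cfg = netsim.build_xyz_network(seed=11, drive_duration=0.2)
    from ctcstim._engine import Engine
    eng = Engine(cfg, 0.05, seed=1)
    ch = eng.channels[("Y", "inh", ("X", "exc"))]
    sl = range(ch["off"], ch["off"] + ch["n"])
    x0, x1 = eng.pool_ranges[("X", "exc")]
    count = sum(
        1
        for g in range(x0, x1)
        for s in range(eng.syn_ptr[g], eng.syn_ptr[g + 1])
        if eng.syn_flat[s] in sl)
    n, p = 800 * 200, 0.02
    lo, hi = scipy.stats.binom.ppf([0.005, 0.995], n, p)
    assert lo <= count <= hi


def test_decoupled_z_receives_only_afferent_drive():
    cfg = netsim.build_xyz_network(p_ze=0.0, p_zi=0.0, seed=0,
                                   drive_duration=0.2)
    z_in = [p for p in cfg.projections
            if p.target[0] == "Z" and p.source[0] != "Z" and p.prob > 0]
    assert z_in == []


def test_same_seed_gives_identical_adjacency():
    from ctcstim._engine import Engine, _CONN_CACHE
    cfg = netsim.build_single_column(seed=7, drive_duration=0.2)
    e1 = Engine(cfg, 0.05, seed=1)
    _CONN_CACHE.clear()
    e2 = Engine(cfg, 0.05, seed=2)   # different run seed, same config seed
    assert np.array_equal(e1.syn_ptr, e2.syn_ptr)
    assert np.array_equal(e1.syn_flat, e2.syn_flat)


# --- generators -------------------------------------------------------------
def test_pink_noise_statistics():
    x = netsim.generate_pink_noise(2 ** 17, 1e-4, seed=5)
    assert x.std() == pytest.approx(1.0, abs=0.02)
    assert abs(x.mean()) < 1e-9
    # log-log PSD slope over 1-500 Hz
    freqs = np.fft.rfftfreq(x.size, 1e-4)
    psd = np.abs(np.fft.rfft(x)) ** 2
    sel = (freqs >= 1) & (freqs <= 500)
    # average in log-spaced bins before fitting to tame periodogram noise
    edges = np.geomspace(1, 500, 25)
    idx = np.digitize(freqs[sel], edges)
    lf, lp = [], []
    for b in range(1, 25):
        m = idx == b
        if m.any():
            lf.append(np.log10(freqs[sel][m].mean()))
            lp.append(np.log10(psd[sel][m].mean()))
    slope = np.polyfit(lf, lp, 1)[0]
    assert -1.2 <= slope <= -0.8


def test_pink_noise_determinism_and_validation():
    a = netsim.generate_pink_noise(4096, 1e-3, seed=9)
    b = netsim.generate_pink_noise(4096, 1e-3, seed=9)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        netsim.generate_pink_noise(1, 1e-3, seed=0)


def test_flicker_held_values_and_moments():
    fl = netsim.generate_flicker(0.1, 0.01, seed=2)
    assert len(fl.values) == 10
    expanded = fl.at_dt(1000, 1e-4)
    # each draw held for one 10 ms window
    assert len(np.unique(expanded)) == 10
    for k in range(10):
        assert np.all(expanded[k * 100:(k + 1) * 100] == fl.values[k])
    big = netsim.generate_flicker(10_000.0, 0.01, seed=3)
    v = np.asarray(big.values)
    assert v.mean() == pytest.approx(0.0, abs=0.01)
    assert v.var() == pytest.approx(1 / 3, abs=0.01)   # Var(U[-1,1]) = 1/3


# --- integration ------------------------------------------------------------
def _quiet_column(**kw):
    return netsim.build_single_column(
        noise_level=0.0, seed=0, rate_exc=0.0, rate_inh=0.0,
        sigma_f=0.0, drive_duration=0.2, **kw)


def test_quiescent_membrane_converges_to_stable_fixed_point():
    cfg = _quiet_column()
    from ctcstim._engine import Engine
    eng = Engine(cfg, 1.0, seed=0, v_init="reset")
    eng.run()
    vstar = cfg.populations["A"].quiescent_potential()
    assert np.allclose(eng.V, vstar, atol=5e-5)      # within 0.05 mV
    assert eng.spk_count[0] == 0


def test_zero_weight_trajectory_matches_scalar_euler():
    # oracle: independent 1-D forward-Euler integration of the quadratic
    syn = SynapseKernelParams(w_e=1e-30, w_i=1e-30)
    cfg = _quiet_column(synapses=syn)
    from ctcstim._engine import Engine
    eng = Engine(cfg, 0.05, seed=0, v_init="reset")
    eng.run()
    pp = cfg.populations["A"]
    v = pp.v_reset
    dt = cfg.dt
    for _ in range(eng.n_steps):
        v = v + dt / pp.cm_exc * (pp.p2 * v * v + pp.p1 * v + pp.p0)
    assert eng.V[0] == pytest.approx(v, abs=1e-12)


def test_spike_delivery_delay_on_toy_circuit():
    # a pulse-evoked burst in the I pool must reach the E pool's
    # inhibitory current exactly one 5 ms delay later
    cfg = netsim.build_single_column(noise_level=0.0, seed=0, rate_exc=0.0,
                                     rate_inh=0.0, sigma_f=0.0,
                                     drive_duration=0.2)
    pulse = StimulationPulse(target="A", amplitude=4 * NA, onset=0.020)
    res = netsim.simulate(cfg, 0.1, pulses=[pulse], seed=0, v_init="reset")
    cur = res.signals_1khz["A"]["current_from:A_i"]
    first_spike_ms = int(np.floor(res.spike_times.min() * 1000))
    nz = np.nonzero(cur != 0)[0]
    assert nz.size > 0
    assert nz[0] == first_spike_ms + 5
    assert np.all(cur <= 0)                      # inhibitory current sign


def test_simulation_determinism():
    cfg = netsim.build_single_column(noise_level=0.05 * NA, seed=3,
                                     rate_exc=3000., rate_inh=3000.,
                                     drive_duration=0.5)
    r1 = netsim.simulate(cfg, 0.4, seed=12)
    r2 = netsim.simulate(cfg, 0.4, seed=12)
    assert np.array_equal(r1.spike_times, r2.spike_times)
    assert np.array_equal(r1.spike_neuron, r2.spike_neuron)
    r3 = netsim.simulate(cfg, 0.4, seed=13)
    assert not np.array_equal(r1.spike_times, r3.spike_times)


def test_rate_components_definition():
    cfg = netsim.build_single_column(noise_level=0.0, seed=0, rate_exc=0.0,
                                     rate_inh=0.0, sigma_f=0.0,
                                     drive_duration=0.2)
    res = netsim.simulate(cfg, 0.05, seed=0, v_init="reset")
    tr = netsim.extract_population_signal(res, "A", "exc_rate")
    assert np.all(tr.samples == 0.0)             # empty raster
    assert tr.samples.size == 50
    with pytest.raises(KeyError):
        netsim.extract_population_signal(res, "A", "bogus")
    with pytest.raises(KeyError):
        netsim.extract_population_signal(res, "B", "exc_rate")


def test_pulse_validation():
    cfg = netsim.build_single_column(seed=0, drive_duration=0.2)
    bad = StimulationPulse(target="A", amplitude=1 * NA, onset=1.5)
    with pytest.raises(ValueError):
        netsim.simulate(cfg, 1.0, pulses=[bad], seed=0)


def test_firing_rate_monotone_in_drive():
    # bracketing oracle for the calibration direction checks
    lo = netsim.build_single_column(noise_level=0.0, seed=2,
                                    rate_exc=2500., rate_inh=3000.,
                                    drive_duration=1.0)
    hi = netsim.build_single_column(noise_level=0.0, seed=2,
                                    rate_exc=3500., rate_inh=3000.,
                                    drive_duration=1.0)
    r_lo = netsim.simulate(lo, 1.0, seed=6).pool_rate("A", "exc")
    r_hi = netsim.simulate(hi, 1.0, seed=6).pool_rate("A", "exc")
    assert r_hi > r_lo
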