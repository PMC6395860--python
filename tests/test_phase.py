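"""Offline and real-time phase measurement."""

import numpy as np
import pytest

from ctcstim import phase
from ctcstim.phase import (AnalogTrace, BandpassSpec, MaskedPhaseError,
                           NoGammaPeakError, circular_stats, wrap)

FS = 1000.0
BAND65 = BandpassSpec(f_peak=65.0, f_lo=55.0, f_hi=75.0)


def _tone(freq, duration=3.0, fs=FS, kind=np.cos, noise=0.0, seed=0):
    t = np.arange(0, duration, 1 / fs)
    x = kind(2 * np.pi * freq * t)
    if noise:
        x = x + noise * np.random.default_rng(seed).standard_normal(t.size)
    return AnalogTrace(x, fs), t


def test_wrap_range_and_identity():
    a = np.linspace(-10, 10, 1001)
    w = wrap(a)
    assert np.all(w > -np.pi - 1e-12) and np.all(w <= np.pi + 1e-12)
    assert np.allclose(np.exp(1j * w), np.exp(1j * a))


# --- offline phase ----------------------------------------------------------
def test_cosine_phase_matches_analytic():
    tr, t = _tone(65.0)
    pt = phase.offline_phase(tr, BAND65)
    expect = wrap(2 * np.pi * 65 * t)
    sel = pt.valid_mask
    err = wrap(pt.phase[sel] - expect[sel])
    assert np.max(np.abs(err)) < 0.05


def test_sin_vs_cos_quadrature_offset():
    trc, _ = _tone(65.0)
    trs, _ = _tone(65.0, kind=np.sin)
    pc = phase.offline_phase(trc, BAND65)
    ps = phase.offline_phase(trs, BAND65)
    sel = pc.valid_mask & ps.valid_mask
    d = wrap(ps.phase[sel] - pc.phase[sel])
    assert np.allclose(d, -np.pi / 2, atol=0.05)


def test_phase_invariant_under_rescaling_and_shift():
    tr, _ = _tone(65.0, noise=0.3)
    p1 = phase.offline_phase(tr, BAND65)
    tr2 = AnalogTrace(5.0 * tr.samples + 11.0, tr.fs)
    p2 = phase.offline_phase(tr2, BAND65)
    sel = p1.valid_mask
    assert np.allclose(wrap(p1.phase[sel] - p2.phase[sel]), 0.0, atol=1e-9)


def test_zero_phase_filter_preserves_tone_phase():
    tr, t = _tone(65.0)
    pt = phase.offline_phase(tr, BandpassSpec(65.0, 50.0, 80.0))
    sel = pt.valid_mask
    err = wrap(pt.phase[sel] - wrap(2 * np.pi * 65 * t[sel]))
    assert np.max(np.abs(err)) < 0.05


def test_artifact_windows_masked_with_guard():
    tr, _ = _tone(65.0, duration=2.0)
    pt = phase.offline_phase(tr, BAND65, artifact_windows=[(1.0, 1.01)])
    assert not pt.valid_mask[1000:1010].any()
    assert not pt.valid_mask[975]          # within 30 ms guard
    assert not pt.valid_mask[1035]
    assert pt.valid_mask[1945]
    with pytest.raises(MaskedPhaseError):
        pt.at_time(1.005)


def test_band_above_nyquist_rejected():
    tr, _ = _tone(65.0)
    with pytest.raises(ValueError):
        phase.offline_phase(tr, BandpassSpec(400.0, 300.0, 600.0))


# --- gamma band estimation --------------------------------------------------
def test_estimate_gamma_band_single_tone():
    tr, _ = _tone(65.0, noise=0.05)
    band = phase.estimate_gamma_band(tr)
    assert band.f_peak == pytest.approx(65.0, abs=1.0)
    assert band.f_lo < 65.0 < band.f_hi


@pytest.mark.parametrize("strong, weak", [(40.0, 80.0), (80.0, 40.0)])
def test_estimate_gamma_band_picks_higher_power_tone(strong, weak):
    # oracle: direct spectrum inspection of the two-tone mixture
    t = np.arange(0, 3.0, 1 / FS)
    x = (1.2 * np.cos(2 * np.pi * strong * t)
         + 0.8 * np.cos(2 * np.pi * weak * t))
    tr = AnalogTrace(x, FS)
    band = phase.estimate_gamma_band(tr)
    freqs = np.arange(20.0, 121.0, 1.0)
    spec = phase.morlet_power_spectrum(tr, freqs)
    assert band.f_peak == freqs[np.argmax(spec)]
    assert band.f_peak == pytest.approx(strong, abs=2.0)


def test_no_gamma_peak_error():
    rng = np.random.default_rng(0)
    # 10 Hz tone: spectrum is monotone decreasing inside 20-120 Hz
    t = np.arange(0, 2.0, 1 / FS)
    x = np.cos(2 * np.pi * 10 * t) + 0.001 * rng.standard_normal(t.size)
    with pytest.raises(NoGammaPeakError):
        phase.estimate_gamma_band(AnalogTrace(x, FS))


# --- AR model ---------------------------------------------------------------
def test_burg_recovers_ar2_coefficients():
    # generate-and-refit consistency oracle
    rng = np.random.default_rng(42)
    a1, a2 = 1.5, -0.8
    n = 100_000
    x = np.zeros(n)
    eps = rng.standard_normal(n)
    for i in range(2, n):
        x[i] = a1 * x[i - 1] + a2 * x[i - 2] + eps[i]
    model = phase.fit_ar(AnalogTrace(x, FS), order=2)
    assert model.coeffs[0] == pytest.approx(a1, abs=0.02)
    assert model.coeffs[1] == pytest.approx(a2, abs=0.02)
    assert model.noise_std == pytest.approx(1.0, abs=0.02)


def test_ar_forecast_of_sinusoid_is_accurate():
    tr, t = _tone(65.0, duration=2.0)
    model = phase.fit_ar(tr, order=15)
    hist = tr.samples[:1000]
    fc = model.forecast(hist, 100)   # the default real-time horizon
    expect = np.cos(2 * np.pi * 65 * t[1000:1100])
    assert abs(fc[0] - expect[0]) < 1e-4          # one-step error
    assert np.max(np.abs(fc - expect)) < 2e-3     # full horizon


def test_white_noise_has_no_ar_structure():
    rng = np.random.default_rng(7)
    model = phase.fit_ar(AnalogTrace(rng.standard_normal(100_000), FS),
                         order=15)
    assert np.all(np.abs(model.coeffs) < 0.05)


def test_ar_order_validation():
    tr, _ = _tone(65.0, duration=0.05)
    with pytest.raises(ValueError):
        phase.fit_ar(tr, order=100)


# --- real-time phase --------------------------------------------------------
def test_realtime_matches_offline_for_sinusoid():
    tr, _ = _tone(65.0, duration=3.0)
    model = phase.fit_ar(tr, order=15)
    pt = phase.offline_phase(tr, BAND65)
    for ms in (1000, 1500, 2222):
        rp = phase.realtime_phase(model, tr.slice(0, ms / 1000), ms / 1000,
                                  band=BAND65)
        assert abs(wrap(rp - pt.phase[ms - 1])) < 0.02


def test_realtime_phase_is_causal():
    # truncation equivalence: samples after t cannot change the estimate
    tr, _ = _tone(65.0, duration=3.0, noise=0.2, seed=3)
    model = phase.fit_ar(tr, order=15)
    t = 1.5
    hist = tr.slice(0, t)
    r1 = phase.realtime_phase(model, hist, t, band=BAND65)
    corrupted = tr.samples.copy()
    corrupted[1500:] = 99.0
    hist2 = AnalogTrace(corrupted, FS).slice(0, t)
    r2 = phase.realtime_phase(model, hist2, t, band=BAND65)
    assert r1 == r2


def test_realtime_history_shorter_than_order_errors():
    tr, _ = _tone(65.0)
    model = phase.fit_ar(tr, order=15)
    with pytest.raises(ValueError):
        phase.realtime_phase(model, tr.slice(0, 0.005), 0.005, band=BAND65)


def test_forecast_divergence_detected():
    bad = phase.ARModel(order=2, coeffs=np.array([2.2, 0.0]),
                        intercept=0.0, noise_std=0.1)
    tr, _ = _tone(65.0, duration=1.0)
    with pytest.raises(phase.ForecastDivergedError):
        phase.realtime_phase(bad, tr.slice(0, 0.5), 0.5, band=BAND65)


# --- circular statistics ----------------------------------------------------
def test_circular_stats_basic():
    cs = circular_stats([0.1, -0.1])
    assert cs.mean == pytest.approx(0.0, abs=1e-12)
    assert cs.resultant == pytest.approx(np.cos(0.1), abs=1e-6)


def test_circular_stats_wraparound():
    cs = circular_stats([np.pi - 0.1, -np.pi + 0.1])
    assert abs(wrap(cs.mean - np.pi)) < 1e-9


def test_circular_stats_zero_resultant_flagged():
    # oracle: the four unit vectors sum exactly to zero
    cs = circular_stats([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    assert not cs.defined
    assert np.isnan(cs.mean)


def test_circular_stats_empty_rejected():
    with pytest.raises(ValueError):
        circular_stats([])
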