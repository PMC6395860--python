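"""Morlet spectrograms and spectral-coherence signal-content scoring."""

import numpy as np
import pytest

from ctcstim import coherence, netsim
from ctcstim.coherence import (AnalogTrace, ConeOfInterest, morlet_spectrogram,
                               pool_sc, spectral_coherence)

FS = 1000.0


def _trace(x):
    return AnalogTrace(np.asarray(x, float), FS)


# --- spectrogram ------------------------------------------------------------
def test_unit_sinusoid_amplitude_flat_and_near_one():
    t = np.arange(0, 4.0, 1 / FS)
    spec = morlet_spectrogram(_trace(np.sin(2 * np.pi * 30 * t)),
                              np.array([30.0]))
    amp = np.abs(spec.coeffs[0, 500:-500])
    assert np.ptp(amp) / amp.mean() < 0.01
    assert amp.mean() == pytest.approx(1.0, rel=0.02)


def test_dc_signal_has_no_wavelet_power():
    spec = morlet_spectrogram(_trace(np.ones(2000) * 3.0),
                              np.arange(4.0, 46.0, 2.0))
    assert np.max(np.abs(spec.coeffs)) < 1e-9


def test_chirp_ridge_tracks_instantaneous_frequency():
    # oracle: analytic instantaneous frequency of a linear chirp
    t = np.arange(0, 10.0, 1 / FS)
    f0, f1 = 20.0, 40.0
    k = (f1 - f0) / t[-1]
    x = np.cos(2 * np.pi * (f0 * t + 0.5 * k * t ** 2))
    freqs = np.arange(15.0, 46.0, 1.0)
    spec = morlet_spectrogram(_trace(x), freqs)
    for ms in range(2000, 9000, 1000):
        ridge = freqs[np.argmax(np.abs(spec.coeffs[:, ms]))]
        f_inst = f0 + k * t[ms]
        assert abs(ridge - f_inst) <= 2.0


def test_empty_frequency_grid_rejected():
    with pytest.raises(ValueError):
        morlet_spectrogram(_trace(np.zeros(100)), np.array([]))


# --- coherence --------------------------------------------------------------
@pytest.fixture(scope="module")
def noise_pair():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(6000)
    return x, rng.standard_normal(6000)


def test_self_coherence_is_one(noise_pair):
    x, _ = noise_pair
    freqs = np.arange(5.0, 41.0, 5.0)
    s = morlet_spectrogram(_trace(x), freqs)
    cmap = spectral_coherence(s, s, lags=[0.0])
    assert np.allclose(cmap.values[:, 0], 1.0, atol=1e-9)


def test_pure_delay_peaks_at_the_delay(noise_pair):
    x, _ = noise_pair
    d = 25  # ms
    y = np.roll(x, d)
    freqs = np.arange(5.0, 41.0, 5.0)
    sx = morlet_spectrogram(_trace(x), freqs)
    sy = morlet_spectrogram(_trace(y), freqs)
    cmap = spectral_coherence(sx, sy)
    for fi in range(freqs.size):
        best = cmap.lags[np.argmax(cmap.values[fi])]
        assert best == pytest.approx(d * 1e-3, abs=1.5e-3)


def test_matches_direct_definition_on_small_input():
    # brute-force oracle: evaluate the normalized lagged cross-correlation
    # definition directly with python loops
    rng = np.random.default_rng(5)
    x, y = rng.standard_normal(300), rng.standard_normal(300)
    freqs = np.array([10.0, 20.0])
    sx = morlet_spectrogram(_trace(x), freqs)
    sy = morlet_spectrogram(_trace(y), freqs)
    lags = [-0.01, 0.0, 0.007]
    cmap = spectral_coherence(sx, sy, lags=lags)
    n = 300
    for li, lag in enumerate(lags):
        L = int(round(lag * FS))
        for fi in range(2):
            num = 0.0j
            dx = dy = 0.0
            for i in range(n):
                if 0 <= i + L < n:
                    num += (np.conj(sx.coeffs[fi, i])
                            * sy.coeffs[fi, i + L])
                    dx += abs(sx.coeffs[fi, i]) ** 2
                    dy += abs(sy.coeffs[fi, i + L]) ** 2
            expect = abs(num) / np.sqrt(dx * dy)
            assert cmap.values[fi, li] == pytest.approx(expect, abs=1e-12)


def test_independent_noise_coherence_below_bias_floor(noise_pair):
    # Monte-Carlo-motivated bound: the finite-sample bias floor of the
    # coherence magnitude scales like 1/sqrt(n_independent_samples)
    x, y = noise_pair
    freqs = np.arange(10.0, 41.0, 10.0)
    sx = morlet_spectrogram(_trace(x), freqs)
    sy = morlet_spectrogram(_trace(y), freqs)
    cmap = spectral_coherence(sx, sy, lags=np.arange(-0.05, 0.051, 0.01))
    # ~6 cycles of smoothing -> n_eff ~ duration * f / 6 independent samples
    n_eff = 6.0 * freqs / 6.0
    floor = 3.0 / np.sqrt(n_eff)
    assert np.all(cmap.values.max(axis=1) < floor)


def test_amplitude_normalization_strictly_smaller(noise_pair):
    x, _ = noise_pair
    freqs = np.array([20.0])
    s = morlet_spectrogram(_trace(x), freqs)
    c_amp = spectral_coherence(s, s, lags=[0.0],
                               normalization="amplitude")
    assert c_amp.values[0, 0] < 1.0


# --- pooling ----------------------------------------------------------------
def test_pool_sc_constant_maps():
    freqs = np.arange(4.0, 46.0, 2.0)
    lags = np.arange(-0.3, 0.301, 0.001)
    ones = coherence.CoherenceMap(
        values=np.ones((freqs.size, lags.size)), freqs=freqs, lags=lags)
    zeros = coherence.CoherenceMap(
        values=np.zeros((freqs.size, lags.size)), freqs=freqs, lags=lags)
    cone = ConeOfInterest(tau_center=0.0)
    assert pool_sc(ones, cone) == pytest.approx(1.0)
    assert pool_sc(zeros, cone) == pytest.approx(0.0)


def test_cone_half_width_decreases_with_frequency():
    cone = ConeOfInterest()
    f = np.arange(4.0, 46.0)
    hw = cone.half_width(f)
    assert np.all(np.diff(hw) < 0)
    assert hw[0] == pytest.approx(7.0 / 24.0)


def test_empty_cone_rejected():
    freqs = np.arange(4.0, 46.0, 2.0)
    lags = np.array([0.0])
    cmap = coherence.CoherenceMap(
        values=np.ones((freqs.size, 1)), freqs=freqs, lags=lags)
    with pytest.raises(ValueError):
        pool_sc(cmap, ConeOfInterest(tau_center=5.0))


def test_sc_score_requires_equal_durations():
    a = _trace(np.random.default_rng(0).standard_normal(1000))
    b = _trace(np.random.default_rng(1).standard_normal(900))
    with pytest.raises(ValueError):
        coherence.sc_score(a, b)


# --- chance level -----------------------------------------------------------
def test_chance_level_percentile_monotone_and_detects_signal():
    rng = np.random.default_rng(33)
    fl = netsim.generate_flicker(4.0, seed=77)
    inp = coherence.flicker_trace(fl, 4.0)
    # output = noisy copy of the input modulation
    out = AnalogTrace(inp.samples + 0.5 * rng.standard_normal(4000), FS)
    freqs = np.arange(6.0, 46.0, 6.0)
    true_sc = coherence.sc_score(inp, out, freqs=freqs).sc_bar

    def gen(i):
        return coherence.flicker_trace(
            netsim.generate_flicker(4.0, seed=10_000 + i), 4.0)

    c95 = coherence.chance_level(out, gen, n_surrogates=100, freqs=freqs)
    c50 = coherence.chance_level(out, gen, n_surrogates=100,
                                 percentile=50.0, freqs=freqs)
    assert c50 <= c95
    assert true_sc > c95

    with pytest.raises(ValueError):
        coherence.chance_level(out, gen, n_surrogates=10, freqs=freqs)
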