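"""Wavelet spectral coherence between input flicker and network output.

The signal-content score SC̄ is the mean of the normalized lagged
cross-correlation between the Morlet spectrograms of the input amplitude
modulation and a population output signal, pooled over a cone of interest
(frequencies up to 45 Hz, lags within ±7/(6f) of the input→output delay).
Chance levels come from re-pairing the output with independently drawn
surrogate flicker signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.signal

from .phase import AnalogTrace

#: Morlet width: cycles of the carrier inside one Gaussian std (2*sigma_t*f)
DEFAULT_N_CYCLES = 6.0
CONE_F_MAX = 45.0
CONE_F_MIN = 4.0
DEFAULT_FREQS = np.arange(CONE_F_MIN, CONE_F_MAX + 0.5, 1.0)
DEFAULT_LAG_RANGE = 0.320  # s; covers the cone half-width 7/(6*4 Hz)


@dataclass
class Spectrogram:
    coeffs: np.ndarray   # complex, shape (n_freqs, n_times)
    freqs: np.ndarray    # Hz
    times: np.ndarray    # s

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        if self.freqs.size == 0:
            raise ValueError("empty frequency grid")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class CoherenceMap:
    values: np.ndarray   # (n_freqs, n_lags) in [0, 1]
    freqs: np.ndarray
    lags: np.ndarray     # s; positive lag = y later than x


@dataclass
class ConeOfInterest:
    f_max: float = CONE_F_MAX
    f_min: float = CONE_F_MIN
    tau_center: float = 0.0

    def half_width(self, f):
        return 7.0 / (6.0 * np.asarray(f, float))


@dataclass
class SCScore:
    sc_bar: float
    tau_xy: float
    chance_95: Optional[float] = None
    n_surrogates: int = 0


def morlet_spectrogram(trace: AnalogTrace, freqs,
                       n_cycles: float = DEFAULT_N_CYCLES) -> Spectrogram:
    """Complex Morlet transform; |W| of a unit sinusoid at f is ~1."""
    freqs = np.asarray(freqs, float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    x = trace.samples - trace.samples.mean()
    fs = trace.fs
    coeffs = np.empty((freqs.size, x.size), complex)
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(4 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        env = np.exp(-t * t / (2 * sigma_t * sigma_t))
        kern = env * np.exp(-2j * np.pi * f * t)
        kern *= 2.0 / env.sum()
        coeffs[i] = scipy.signal.fftconvolve(x, kern, mode="same")
    return Spectrogram(coeffs=coeffs, freqs=freqs,
                       times=trace.t0 + np.arange(x.size) / fs)


def spectral_coherence(spec_x: Spectrogram, spec_y: Spectrogram,
                       lags=None, normalization: str = "energy"
                       ) -> CoherenceMap:
    """Normalized lagged cross-correlation of two spectrograms.

    ``normalization='energy'`` (default) uses
    sqrt(sum|Wx|^2 * sum|Wy|^2), which makes self-coherence exactly 1;
    ``'amplitude'`` uses the plain amplitude-sum product
    (sum|Wx|)*(sum|Wy|), a strictly smaller-than-one variant.
    Positive lag means y is delayed relative to x.
    """
    if spec_x.freqs.shape != spec_y.freqs.shape or \
            not np.allclose(spec_x.freqs, spec_y.freqs):
        raise ValueError("spectrograms must share one frequency grid")
    n = spec_x.coeffs.shape[1]
    if spec_y.coeffs.shape[1] != n:
        raise ValueError("spectrograms must have equal length")
    dt = float(np.mean(np.diff(spec_x.times))) if n > 1 else 1e-3
    if lags is None:
        m = int(round(DEFAULT_LAG_RANGE / dt))
        lag_samples = np.arange(-m, m + 1)
    else:
        lag_samples = np.round(np.asarray(lags, float) / dt).astype(int)

    Wx = spec_x.coeffs
    Wy = spec_y.coeffs
    ax2 = np.abs(Wx) ** 2
    ay2 = np.abs(Wy) ** 2
    ax1 = np.abs(Wx)
    ay1 = np.abs(Wy)

    nf = Wx.shape[0]
    out = np.zeros((nf, lag_samples.size))
    for li, L in enumerate(lag_samples):
        if abs(L) >= n:
            continue
        if L >= 0:
            xs, ys = slice(0, n - L), slice(L, n)
        else:
            xs, ys = slice(-L, n), slice(0, n + L)
        num = np.abs(np.sum(np.conj(Wx[:, xs]) * Wy[:, ys], axis=1))
        if normalization == "energy":
            den = np.sqrt(np.sum(ax2[:, xs], axis=1)
                          * np.sum(ay2[:, ys], axis=1))
        elif normalization == "amplitude":
            den = np.sum(ax1[:, xs], axis=1) * np.sum(ay1[:, ys], axis=1)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        good = den > 0
        out[good, li] = num[good] / den[good]
    return CoherenceMap(values=np.clip(out, 0.0, 1.0),
                        freqs=spec_x.freqs, lags=lag_samples * dt)


def estimate_tau_xy(cmap: CoherenceMap, cone: ConeOfInterest = None) -> float:
    """Delay between the signals: coherence-mass-weighted peak lag.

    The coherence is averaged over the cone's frequency band; the lag
    estimate is the center of mass of the fourth power of that curve
    (emphasizing the peak while staying smooth under noise).
    """
    cone = cone or ConeOfInterest()
    fsel = (cmap.freqs >= cone.f_min) & (cmap.freqs <= cone.f_max)
    if not fsel.any():
        raise ValueError("cone frequency band outside the map grid")
    c = cmap.values[fsel].mean(axis=0)
    w = c ** 4
    if w.sum() <= 0:
        return 0.0
    return float(np.sum(cmap.lags * w) / np.sum(w))


def pool_sc(cmap: CoherenceMap, cone: ConeOfInterest = None) -> float:
    """Unweighted mean of C(f, tau) over the cone of interest."""
    if cone is None:
        cone = ConeOfInterest(tau_center=estimate_tau_xy(cmap))
    fsel = (cmap.freqs >= cone.f_min) & (cmap.freqs <= cone.f_max)
    total, count = 0.0, 0
    for fi in np.nonzero(fsel)[0]:
        hw = cone.half_width(cmap.freqs[fi])
        tsel = np.abs(cmap.lags - cone.tau_center) <= hw
        total += cmap.values[fi, tsel].sum()
        count += int(tsel.sum())
    if count == 0:
        raise ValueError("empty cone of interest")
    return total / count


def flicker_trace(flicker, duration: float, fs: float = 1000.0) -> AnalogTrace:
    """Expand a piecewise-constant flicker signal onto a 1 kHz grid."""
    n = int(round(duration * fs))
    return AnalogTrace(flicker.at_dt(n, 1.0 / fs), fs, 0.0)


def sc_score(input_trace: AnalogTrace, output_trace: AnalogTrace,
             freqs=None, cone: ConeOfInterest = None,
             normalization: str = "energy") -> SCScore:
    """End-to-end SC̄ between an input modulation and an output signal."""
    if input_trace.samples.size != output_trace.samples.size:
        raise ValueError(
            "SC̄ comparisons require equal-duration signals "
            "(spectral coherence is sample-size biased)")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    sx = morlet_spectrogram(input_trace, freqs)
    sy = morlet_spectrogram(output_trace, freqs)
    cmap = spectral_coherence(sx, sy, normalization=normalization)
    if cone is None:
        tau = estimate_tau_xy(cmap)
        cone = ConeOfInterest(tau_center=tau)
    else:
        tau = cone.tau_center
    return SCScore(sc_bar=pool_sc(cmap, cone), tau_xy=tau)


def chance_level(output_trace: AnalogTrace,
                 flicker_generator: Callable[[int], AnalogTrace],
                 n_surrogates: int = 100, percentile: float = 95.0,
                 freqs=None) -> float:
    """Surrogate-input chance level for SC̄.

    ``flicker_generator(i)`` must return the i-th independent surrogate
    input as an AnalogTrace of the same duration as ``output_trace``.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for a stable "
                         "95th percentile")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    sy = morlet_spectrogram(output_trace, freqs)
    scores = np.empty(n_surrogates)
    for i in range(n_surrogates):
        sx = morlet_spectrogram(flicker_generator(i), freqs)
        cmap = spectral_coherence(sx, sy)
        cone = ConeOfInterest(tau_center=estimate_tau_xy(cmap))
        scores[i] = pool_sc(cmap, cone)
    return float(np.percentile(scores, percentile))


def save_coherence_map(cmap: CoherenceMap, path) -> None:
    """Array-container export (npz) with frequency and lag axes."""
    np.savez_compressed(path, values=cmap.values, freqs=cmap.freqs,
                        lags=cmap.lags)


def load_coherence_map(path) -> CoherenceMap:
    with np.load(path) as d:
        return CoherenceMap(values=d["values"], freqs=d["freqs"],
                            lags=d["lags"])
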