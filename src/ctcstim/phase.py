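"""Instantaneous gamma-phase measurement, offline and in real time.

Offline: the 1 kHz analysis signal is z-scored, artifact windows are
zeroed, a narrow zero-phase FIR bandpass around the gamma peak is applied
forward-backward, and the phase is the argument of the analytic (Hilbert)
signal.  Real time: an autoregressive model fitted to unperturbed activity
(Burg method) forecasts the signal ~100 ms past the current sample so the
Hilbert edge distortion (about two gamma cycles) never reaches the sample
being read; only data up to the current time enters the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.signal

TWO_PI = 2 * np.pi

#: guard band applied around trace edges and artifact windows (s);
#: about two gamma cycles, where Hilbert/filter edge effects matter
EDGE_GUARD = 0.030
#: default AR forecast horizon (s)
DEFAULT_HORIZON = 0.100
#: boxcar applied to spike-rate signals before normalization (s)
RATE_SMOOTH = 0.003


def wrap(angle):
    """Wrap angles onto (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    out = -((-a + np.pi) % TWO_PI - np.pi)
    return out if out.ndim else float(out)


def circdist(a, b):
    """Absolute circular distance between angles."""
    return np.abs(wrap(np.asarray(a) - np.asarray(b)))


@dataclass
class AnalogTrace:
    """A uniformly sampled real-valued signal."""

    samples: np.ndarray
    fs: float = 1000.0
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, t_start: float, t_stop: float) -> "AnalogTrace":
        i0 = max(0, int(round((t_start - self.t0) * self.fs)))
        i1 = min(self.samples.size, int(round((t_stop - self.t0) * self.fs)))
        return AnalogTrace(self.samples[i0:i1], self.fs, self.t0 + i0 / self.fs)

    def smoothed(self, width: float = RATE_SMOOTH) -> "AnalogTrace":
        """Boxcar smoothing (width in seconds, rounded to odd samples)."""
        w = max(1, int(round(width * self.fs)))
        if w % 2 == 0:
            w += 1
        if w == 1:
            return AnalogTrace(self.samples.copy(), self.fs, self.t0)
        kern = np.ones(w) / w
        sm = np.convolve(np.pad(self.samples, w // 2, mode="edge"),
                         kern, mode="valid")
        return AnalogTrace(sm, self.fs, self.t0)


@dataclass
class BandpassSpec:
    f_peak: float
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_peak < self.f_hi:
            raise ValueError("require 0 < f_lo < f_peak < f_hi")


@dataclass
class PhaseTrace:
    """Instantaneous phase with a validity mask (guard bands invalid)."""

    phase: np.ndarray
    fs: float
    valid_mask: np.ndarray
    t0: float = 0.0

    def at_time(self, t: float, require_valid: bool = True) -> float:
        i = int(round((t - self.t0) * self.fs))
        if not 0 <= i < self.phase.size:
            raise IndexError("time outside phase trace")
        if require_valid and not self.valid_mask[i]:
            raise MaskedPhaseError(f"phase at t={t:.4f}s is masked invalid")
        return float(self.phase[i])


class MaskedPhaseError(RuntimeError):
    """Requested phase sample lies inside an artifact/edge guard band."""


class NoGammaPeakError(RuntimeError):
    """Power spectrum has no local maximum inside the gamma search band."""


# ---------------------------------------------------------------------------
def morlet_power_spectrum(trace: AnalogTrace, freqs: np.ndarray,
                          n_cycles: float = 6.0) -> np.ndarray:
    """Time-averaged Morlet wavelet power at the requested frequencies."""
    from .coherence import morlet_spectrogram

    spec = morlet_spectrogram(trace, freqs, n_cycles=n_cycles)
    return np.mean(np.abs(spec.coeffs) ** 2, axis=1)


def estimate_gamma_band(trace: AnalogTrace, f_min: float = 20.0,
                        f_max: float = 120.0, df: float = 1.0) -> BandpassSpec:
    """Locate the gamma peak and its half-power points.

    The spectrum is the time-averaged Morlet wavelet power on a ``df``
    grid; ``f_peak`` is its argmax (ties broken toward the lower
    frequency), ``f_lo``/``f_hi`` the nearest frequencies on each side
    where power first drops to half the peak (clamped to the search band
    if it never does).
    """
    if trace.duration < 1.0:
        raise ValueError("need at least 1 s of signal to estimate the band")
    freqs = np.arange(f_min, f_max + df / 2, df)
    power = morlet_power_spectrum(trace, freqs)
    ipk = int(np.argmax(power))
    if ipk == 0 or ipk == freqs.size - 1:
        raise NoGammaPeakError("no gamma peak inside the search band")
    half = power[ipk] / 2.0
    lo = freqs[0]
    for i in range(ipk, -1, -1):
        if power[i] <= half:
            lo = freqs[i]
            break
    hi = freqs[-1]
    for i in range(ipk, freqs.size):
        if power[i] <= half:
            hi = freqs[i]
            break
    return BandpassSpec(f_peak=float(freqs[ipk]), f_lo=float(lo), f_hi=float(hi))


# ---------------------------------------------------------------------------
def _design_fir(band: BandpassSpec, fs: float) -> np.ndarray:
    if band.f_hi >= fs / 2:
        raise ValueError("bandpass upper edge at or above Nyquist")
    numtaps = int(round(3 * fs / band.f_lo))
    if numtaps % 2 == 0:
        numtaps += 1
    return scipy.signal.firwin(numtaps, [band.f_lo, band.f_hi],
                               pass_zero=False, window="hamming", fs=fs)


_FIR_CACHE: dict = {}


def _fir_for(band: BandpassSpec, fs: float) -> np.ndarray:
    key = (round(band.f_lo, 3), round(band.f_hi, 3), fs)
    h = _FIR_CACHE.get(key)
    if h is None:
        h = _design_fir(band, fs)
        if len(_FIR_CACHE) > 64:
            _FIR_CACHE.clear()
        _FIR_CACHE[key] = h
    return h


def _to_1khz(trace: AnalogTrace) -> AnalogTrace:
    if abs(trace.fs - 1000.0) < 1e-9:
        return trace
    from fractions import Fraction

    frac = Fraction(1000 / trace.fs).limit_denominator(1000)
    y = scipy.signal.resample_poly(trace.samples, frac.numerator,
                                   frac.denominator)
    return AnalogTrace(y, 1000.0, trace.t0)


def offline_phase(trace: AnalogTrace, band: BandpassSpec,
                  artifact_windows: Sequence[tuple] = (),
                  guard: float = EDGE_GUARD,
                  artifact_guard: Optional[float] = None) -> PhaseTrace:
    """Hilbert phase of the band-passed, normalized 1 kHz signal.

    ``artifact_windows`` are (t_start, t_stop) pairs in trace time; the
    raw normalized signal is zeroed there before filtering and the phase
    is masked invalid within ``artifact_guard`` seconds of each window
    (default: ``guard``) and within ``guard`` seconds of the trace edges.
    A zero ``artifact_guard`` keeps the phase defined across the blanked
    window, where the narrow-band filter interpolates smoothly — how
    early post-pulse phase shifts are read.
    """
    tr = _to_1khz(trace)
    x = tr.samples.astype(float).copy()
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    n = x.size
    fs = tr.fs
    valid = np.ones(n, dtype=bool)
    g = int(round(guard * fs))
    ga = g if artifact_guard is None else int(round(artifact_guard * fs))
    for (a, b) in artifact_windows:
        i0 = max(0, int(np.floor((a - tr.t0) * fs)))
        i1 = min(n, int(np.ceil((b - tr.t0) * fs)))
        if i1 > i0:
            x[i0:i1] = 0.0
            valid[max(0, i0 - ga):min(n, i1 + ga)] = False
    valid[:g] = False
    valid[n - g:] = False

    h = _fir_for(band, fs)
    if x.size <= 3 * len(h):
        padlen = max(1, x.size - 2)
    else:
        padlen = 3 * len(h)
    y = scipy.signal.filtfilt(h, [1.0], x, padlen=padlen)
    analytic = scipy.signal.hilbert(y)
    return PhaseTrace(phase=np.angle(analytic), fs=fs, valid_mask=valid,
                      t0=tr.t0)


# ---------------------------------------------------------------------------
@dataclass
class ARModel:
    """Autoregressive forecaster X_t = c + sum_i a_i X_{t-i} + eps."""

    order: int
    coeffs: np.ndarray
    intercept: float
    noise_std: float
    fs: float = 1000.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.order < 1 or self.coeffs.size != self.order:
            raise ValueError("coefficient vector must have length `order`")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite AR coefficients")

    def forecast(self, history: np.ndarray, n_ahead: int) -> np.ndarray:
        """Iterated one-step prediction (noise-free)."""
        p = self.order
        if history.size < p:
            raise ValueError("history shorter than AR order")
        buf = np.concatenate([history[-p:].astype(float),
                              np.empty(n_ahead)])
        a = self.coeffs[::-1]  # align a_p .. a_1 with window order
        for i in range(n_ahead):
            buf[p + i] = self.intercept + np.dot(a, buf[i:i + p])
        return buf[p:]


def fit_ar(trace: AnalogTrace, order: int = 15) -> ARModel:
    """Burg-method AR fit on an unperturbed training signal.

    Default order 15 corresponds to one gamma cycle at 1 kHz sampling.
    """
    from statsmodels.regression.linear_model import burg

    x = np.asarray(trace.samples, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= x.size:
        raise ValueError("order must be smaller than the trace length")
    mu = x.mean()
    rho, sigma2 = burg(x - mu, order=order, demean=False)
    coeffs = _stabilize(np.asarray(rho, dtype=float))
    intercept = mu * (1.0 - coeffs.sum())
    return ARModel(order=order, coeffs=coeffs, intercept=intercept,
                   noise_std=float(np.sqrt(max(sigma2, 0.0))), fs=trace.fs)


def _stabilize(coeffs: np.ndarray) -> np.ndarray:
    """Reflect explosive AR roots into the unit circle.

    Burg fits on nearly deterministic signals (e.g. noiseless sinusoids
    with order > 2) can place characteristic roots far outside the unit
    circle; reflecting them preserves the spectral shape while making
    iterated forecasts bounded.
    """
    poly = np.concatenate([[1.0], -coeffs])
    roots = np.roots(poly)
    mag = np.abs(roots)
    if np.all(mag <= 1.0 + 1e-12):
        return coeffs
    roots = np.where(mag > 1.0, 1.0 / np.conj(roots), roots)
    new = np.real(np.poly(roots))
    return -new[1:]


class ForecastDivergedError(RuntimeError):
    """AR forecast left the amplitude range of its history (model mismatch)."""


def realtime_phase(model: ARModel, history: AnalogTrace, t_now: float,
                   horizon: float = DEFAULT_HORIZON,
                   band: Optional[BandpassSpec] = None,
                   artifact_windows: Sequence[tuple] = (),
                   read_at: Optional[float] = None) -> float:
    """Phase at ``t_now`` using only samples up to ``t_now``.

    The AR model extends the history ``horizon`` seconds into the future;
    the offline pipeline is then applied to the extended signal and the
    phase is read at ``t_now``, which is ``horizon`` away from the
    forecast edge (the edge guard never reaches it).  ``read_at`` reads
    the phase slightly *ahead* of the last observed sample instead (still
    causal — that part of the signal is pure forecast); used to estimate
    the phase at a pulse onset that falls inside a partially recorded
    sampling bin.
    """
    if band is None:
        raise ValueError("a BandpassSpec is required")
    if horizon < 0.05:
        raise ValueError("horizon must be at least 50 ms (~3 gamma cycles)")
    fs = history.fs
    n_ahead = int(round(horizon * fs))
    x = history.samples
    if x.size < model.order:
        raise ValueError("history shorter than AR order")
    fc = model.forecast(x, n_ahead)
    span = np.abs(x - x.mean()).max()
    if span > 0 and np.abs(fc - x.mean()).max() > 10 * span:
        raise ForecastDivergedError("AR forecast diverged from history range")
    ext = AnalogTrace(np.concatenate([x, fc]), fs, history.t0)
    pt = offline_phase(ext, band, artifact_windows=artifact_windows)
    i = x.size - 1
    if read_at is not None:
        i += int(round((read_at - t_now) * fs))
        if not x.size - 1 <= i < x.size + n_ahead - int(0.05 * fs):
            raise ValueError("read_at must lie just ahead of the history")
    return float(pt.phase[i])


# ---------------------------------------------------------------------------
@dataclass
class CircularStats:
    mean: float
    resultant: float
    q25: float
    q75: float
    defined: bool = True
    n: int = 0


def circular_stats(angles, weights=None,
                   resultant_floor: float = 1e-9) -> CircularStats:
    """Circular mean, resultant length, and quartiles about the mean."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle set")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(1j * a)) / np.sum(w)
    r = float(np.abs(z))
    if r < resultant_floor:
        return CircularStats(mean=np.nan, resultant=r, q25=np.nan,
                             q75=np.nan, defined=False, n=a.size)
    mean = float(np.angle(z))
    centered = wrap(a - mean)
    order = np.argsort(centered)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    q25 = float(np.interp(0.25, cw, centered[order]))
    q75 = float(np.interp(0.75, cw, centered[order]))
    return CircularStats(mean=mean, resultant=r, q25=wrap(mean + q25),
                         q75=wrap(mean + q75), defined=True, n=a.size)


def ar_to_json(model: ARModel, training_hash: str = "") -> str:
    import json

    return json.dumps({"order": model.order,
                       "coeffs": model.coeffs.tolist(),
                       "intercept": model.intercept,
                       "noise_std": model.noise_std,
                       "fs": model.fs,
                       "training_config_hash": training_hash}, indent=2)


def ar_from_json(text: str) -> ARModel:
    import json

    d = json.loads(text)
    return ARModel(order=d["order"], coeffs=np.asarray(d["coeffs"]),
                   intercept=d["intercept"], noise_std=d["noise_std"],
                   fs=d.get("fs", 1000.0))


def export_phase_trace(pt: PhaseTrace, path) -> None:
    """Tabular text export: time_ms, phase_rad, valid."""
    import pandas as pd

    t = (pt.t0 + np.arange(pt.phase.size) / pt.fs) * 1e3
    pd.DataFrame({"time_ms": t, "phase_rad": pt.phase,
                  "valid": pt.valid_mask.astype(int)}).to_csv(path,
                                                              index=False)
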