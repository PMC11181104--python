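"""Spectral analysis: multitaper spectrograms, IAF estimation, Morlet
wavelets, instantaneous frequency, and prestimulus power spectra.

The Morlet transform uses the study's grid — 140 linearly spaced center
frequencies from 1 to 70 Hz with cycle counts linearly spaced 5 to 12 — where
each wavelet is phi(t) = exp(-i 2 pi f t) exp(-t^2 / (2 sigma^2)) with
sigma = c / (2 pi f). Kernels are normalized so a unit-amplitude in-band
cosine yields unit envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .echt import FilterSpec, track_phase
from .synthgen import Recording


class NoAlphaPeakError(ValueError):
    """Raised when the detrended spectrum has no local maximum in the search band."""


# ---------------------------------------------------------------------------
# Multitaper


def multitaper_spectrogram(rec, fs: float | None = None, *,
                           window: float = 6.0, step: float = 0.15,
                           n_tapers: int = 4):
    """Slepian-taper-averaged sliding power spectrogram.

    Uses ``n_tapers`` DPSS tapers (time-bandwidth NW = (n_tapers + 1) / 2)
    over a ``window``-second analysis window advanced by ``step`` seconds.

    Returns ``(freqs, times, power)`` with power in µV²/Hz, shaped
    (n_freqs, n_times); ``times`` are window centers.
    """
    if isinstance(rec, Recording):
        sig, fs = rec.signal[0], rec.fs
    else:
        sig = np.asarray(rec, dtype=float)
        if fs is None:
            raise ValueError("fs required for array input")
    win_n = int(round(window * fs))
    if sig.size < win_n:
        raise ValueError(
            f"recording of {sig.size / fs:.2f} s is shorter than the "
            f"{window} s analysis window")
    step_n = max(1, int(round(step * fs)))
    nw = (n_tapers + 1) / 2.0
    tapers = scipy.signal.windows.dpss(win_n, nw, Kmax=n_tapers)  # (K, win_n)
    frames = np.lib.stride_tricks.sliding_window_view(sig, win_n)[::step_n]
    freqs = np.fft.rfftfreq(win_n, d=1.0 / fs)
    power = np.zeros((freqs.size, frames.shape[0]))
    for tap in tapers:
        spec = np.fft.rfft(frames * tap, axis=-1)
        power += (np.abs(spec) ** 2).T
    power /= n_tapers * fs  # tapers have unit energy -> µV²/Hz
    times = (np.arange(frames.shape[0]) * step_n + win_n / 2.0) / fs
    return freqs, times, power


def multitaper_psd(rec, fs: float | None = None, **kwargs):
    """Time-averaged multitaper PSD; see :func:`multitaper_spectrogram`."""
    freqs, _, power = multitaper_spectrogram(rec, fs, **kwargs)
    return freqs, power.mean(axis=1)


# ---------------------------------------------------------------------------
# Aperiodic detrending and IAF


@dataclass
class PsdCurve:
    """Power spectral density with a method-tagged aperiodic-detrended copy.

    ``detrended_power`` is log10(power) minus the fitted aperiodic trend (a
    dimensionless log-ratio), tagged by ``method``.
    """

    freqs: np.ndarray
    power: np.ndarray
    detrended_power: np.ndarray | None = None
    method: str | None = None


def detrend_psd(freqs, power, method: str = "polynomial", *,
                fit_range: tuple = (1.0, 40.0),
                exclude: tuple = (7.0, 14.0)) -> PsdCurve:
    """Remove the aperiodic 1/f trend from a PSD.

    method "polynomial": third-order polynomial fit to log10(power) over
    ``fit_range`` (Hz), excluding the ``exclude`` band so the alpha bump does
    not pull the trend. method "aperiodic": straight-line fit of log10(power)
    against log10(f) over the same points — a minimal aperiodic (offset +
    exponent) model. The detrended curve is log10(power) minus the fit.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("power must be non-negative before detrending")
    logp = np.log10(np.maximum(power, 1e-30))
    fit_mask = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & \
               ~((freqs > exclude[0]) & (freqs < exclude[1])) & (freqs > 0)
    if fit_mask.sum() < 5:
        raise ValueError("too few points to fit the aperiodic trend")
    if method == "polynomial":
        coefs = np.polyfit(freqs[fit_mask], logp[fit_mask], deg=3)
        trend = np.polyval(coefs, freqs)
    elif method == "aperiodic":
        lf = np.log10(np.maximum(freqs, 1e-12))
        coefs = np.polyfit(lf[fit_mask], logp[fit_mask], deg=1)
        trend = np.polyval(coefs, lf)
    else:
        raise ValueError(f"unknown detrending method {method!r}")
    return PsdCurve(freqs=freqs, power=power, detrended_power=logp - trend,
                    method=method)


def estimate_iaf(psd, power=None, *, search: tuple = (7.5, 16.0),
                 method: str = "polynomial", interpolate: bool = True) -> float:
    """Individual alpha frequency: largest local maximum of the detrended PSD
    within the search band.

    ``psd`` may be a :class:`PsdCurve` (detrended if needed) or a frequency
    array paired with ``power``. Because the multitaper main lobe is wider
    than a frequency bin (a narrow peak appears as a flat-topped plateau),
    the peak-bin location is refined to the power-weighted centroid of the
    contiguous half-power extent around the detected maximum
    (``interpolate=False`` returns the raw bin center). Raises
    :class:`NoAlphaPeakError` when the band contains no local maximum (e.g. a
    pure aperiodic spectrum); callers may widen the band.
    """
    if isinstance(psd, PsdCurve):
        curve = psd if psd.detrended_power is not None else \
            detrend_psd(psd.freqs, psd.power, method)
    else:
        curve = detrend_psd(np.asarray(psd), np.asarray(power), method)
    band = (curve.freqs >= search[0]) & (curve.freqs <= search[1])
    if band.sum() < 3:
        raise ValueError("search band too narrow for the frequency grid")
    y = curve.detrended_power[band]
    f = curve.freqs[band]
    peaks, props = scipy.signal.find_peaks(y, height=-np.inf)
    if peaks.size == 0:
        raise NoAlphaPeakError(
            f"no alpha peak found in {search[0]}-{search[1]} Hz")
    best = int(peaks[np.argmax(props["peak_heights"])])
    if not interpolate:
        return float(f[best])
    # contiguous bins within half power (log10 2) of the peak
    above = y >= y[best] - np.log10(2.0)
    lo = best
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = best
    while hi < y.size - 1 and above[hi + 1]:
        hi += 1
    w = 10.0 ** y[lo:hi + 1]
    return float(np.sum(f[lo:hi + 1] * w) / np.sum(w))


# ---------------------------------------------------------------------------
# Morlet wavelet transform


def default_grid(n: int = 140, fmin: float = 1.0, fmax: float = 70.0,
                 cmin: float = 5.0, cmax: float = 12.0):
    """The study's frequency/cycle grid: n points, fmin-fmax Hz, cycles
    linearly spaced cmin-cmax aligned to the frequencies."""
    return np.linspace(fmin, fmax, n), np.linspace(cmin, cmax, n)


@dataclass
class SpectralTensor:
    """Complex wavelet coefficients indexed (trial, frequency, time)."""

    coeffs: np.ndarray
    freqs: np.ndarray
    cycles: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.coeffs)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.coeffs)) % 360.0

    def nearest_freq(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))


def _morlet_kernel(f: float, c: float, fs: float) -> np.ndarray:
    """Convolution kernel implementing correlation with the complex Morlet
    wavelet exp(-i 2 pi f t) exp(-t^2/(2 sigma^2)).

    The wavelet transform is the inner product of the signal with the
    wavelet; since the Gaussian is even, correlating with exp(-i 2 pi f t) g
    equals convolving with its conjugate exp(+i 2 pi f t) g. The resulting
    coefficients carry analytic-signal phase (advancing with time, 0 deg at a
    cosine peak).
    """
    sigma = c / (2.0 * np.pi * f)
    half = int(np.ceil(3.5 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(1j * 2.0 * np.pi * f * t) * np.exp(-t**2 / (2.0 * sigma**2))
    # unit envelope for a unit in-band cosine: response = 0.5 * sum(gaussian)
    k *= 2.0 / np.exp(-t**2 / (2.0 * sigma**2)).sum()
    return k


def morlet_transform(epochs, fs: float, freqs=None, cycles=None, *,
                     times=None, chunk: int = 16) -> SpectralTensor:
    """Complex Morlet wavelet transform of (n_trials, n_times) epochs.

    Epochs are reflect-padded by half the longest kernel support (capped at
    the epoch length, with a warning when the cap bites) and the padded output
    discarded, so edge ramps do not contaminate the window of interest.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if freqs is None or cycles is None:
        dflt_f, dflt_c = default_grid()
        freqs = dflt_f if freqs is None else np.asarray(freqs, dtype=float)
        cycles = (np.interp(freqs, dflt_f, dflt_c) if cycles is None
                  else np.asarray(cycles, dtype=float))
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    cycles = np.atleast_1d(np.asarray(cycles, dtype=float))
    if np.any(freqs >= fs / 2.0):
        raise ValueError("requested frequency at or above Nyquist")
    n_trials, n_times = epochs.shape
    kernels = [_morlet_kernel(f, c, fs) for f, c in zip(freqs, cycles)]
    max_half = max(k.size // 2 for k in kernels)
    pad = min(max_half, n_times - 1)
    if pad < max_half:
        warnings.warn("epoch shorter than half the longest wavelet support; "
                      "reflect padding truncated to the epoch length")
    padded = np.pad(epochs, ((0, 0), (pad, pad)), mode="reflect")
    coeffs = np.empty((n_trials, freqs.size, n_times), dtype=complex)
    for i, k in enumerate(kernels):
        out = scipy.signal.fftconvolve(padded, k[None, :], mode="same",
                                       axes=-1)
        coeffs[:, i, :] = out[:, pad:pad + n_times]
    if times is None:
        times = np.arange(n_times) / fs
    return SpectralTensor(coeffs=coeffs, freqs=freqs, cycles=cycles,
                          times=np.asarray(times, dtype=float))


# ---------------------------------------------------------------------------
# Instantaneous frequency


def instantaneous_frequency(sig, spec: FilterSpec, method: str = "sht", *,
                            envelope_floor: float = 1e-6,
                            median_ms: float = 0.0):
    """Instantaneous frequency of the narrowband (IAF +/- 25%) signal in Hz.

    The signal is causally bandpassed per ``spec``; phase comes either from
    the standard analytic construction over the whole record (``sht``) or the
    per-sample ecHT endpoint tracker (``echt``). The phase is unwrapped,
    differenced, and scaled by fs / (2 pi) (in degrees: fs / 360). Samples in
    the tracker warm-up or where the envelope falls below ``envelope_floor``
    (in µV) are nan in the returned series; the accompanying mask marks valid
    samples. The estimate is unsmoothed by default; ``median_ms`` > 0 applies
    an optional median filter of that width to suppress sample-level phase
    jitter. 2-D input is processed row-wise.
    """
    arr = np.asarray(sig.signal[0] if isinstance(sig, Recording) else sig,
                     dtype=float)
    if arr.ndim == 2:
        rows = [instantaneous_frequency(row, spec, method,
                                        envelope_floor=envelope_floor,
                                        median_ms=median_ms)
                for row in arr]
        return np.vstack([r[0] for r in rows]), np.vstack([r[1] for r in rows])
    fs = spec.fs
    if method == "sht":
        b, a = spec.ba()
        analytic = scipy.signal.hilbert(scipy.signal.lfilter(b, a, arr))
        phase_deg = np.degrees(np.angle(analytic)) % 360.0
        env = np.abs(analytic)
        warm = np.zeros(arr.size, dtype=bool)
        # causal filter transient: one default window flagged as warm-up
        warm[:min(arr.size, spec.default_window() - 1)] = True
    elif method == "echt":
        series = track_phase(arr, spec, method="echt")
        phase_deg, env, warm = series.phase, series.envelope, series.warmup
    else:
        raise ValueError("method must be 'sht' or 'echt'")
    freq = np.full(arr.size, np.nan)
    finite = np.isfinite(phase_deg)
    if finite.any():
        start = int(np.argmax(finite))  # nan warm-up would poison unwrap
        unwrapped = np.unwrap(np.radians(phase_deg[start:]))
        freq[start + 1:] = np.diff(unwrapped) * fs / (2.0 * np.pi)
    valid = ~warm & (env >= envelope_floor) & np.isfinite(freq)
    valid[0] = False
    freq[~valid] = np.nan
    if median_ms > 0 and valid.any():
        size = max(3, int(round(median_ms * 1e-3 * fs)) | 1)  # odd width
        idx = np.flatnonzero(valid)
        seg = freq[idx[0]:idx[-1] + 1].copy()
        bad = ~np.isfinite(seg)
        if bad.any():  # bridge interior gaps so the median window is full
            good = np.flatnonzero(~bad)
            seg[bad] = np.interp(np.flatnonzero(bad), good, seg[good])
        freq[idx[0]:idx[-1] + 1] = scipy.signal.medfilt(seg, kernel_size=size)
        freq[~valid] = np.nan
    return freq, valid


# ---------------------------------------------------------------------------
# Prestimulus spectra


def _slice_window(times, window):
    times = np.asarray(times, dtype=float)
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"window {window} extends beyond the epoch "
                         f"[{times[0]:.3f}, {times[-1]:.3f}] s")
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def prestim_psd(epochs, times, fs: float, *, window=(-0.5, 0.0),
                detrend: str | None = "polynomial",
                fit_range=(1.0, 40.0)) -> PsdCurve:
    """Trial-averaged prestimulus PSD with aperiodic detrending.

    Per-trial periodograms over the prestimulus window are averaged, then the
    aperiodic component is removed with :func:`detrend_psd` (method-tagged;
    ``detrend=None`` skips it, leaving raw power only).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    mask = _slice_window(times, window)
    seg = epochs[:, mask]
    freqs, pxx = scipy.signal.periodogram(seg, fs=fs, axis=-1)
    power = pxx.mean(axis=0)
    if detrend is None:
        return PsdCurve(freqs=freqs, power=power)
    if not np.any(power > 0):
        return PsdCurve(freqs=freqs, power=power,
                        detrended_power=np.zeros_like(power), method=detrend)
    return detrend_psd(freqs, power, detrend, fit_range=fit_range)


def evoked_spectrum(epochs, times, fs: float, *,
                    window=(-0.7, 0.0)) -> PsdCurve:
    """Spectrum of the trial-averaged (evoked) prestimulus activity.

    Averaging before the Fourier transform cancels activity that is not both
    time- and phase-locked to stimulus onset, so phase-locked delivery leaves
    an alpha peak while random-phase delivery attenuates it by ~1/sqrt(n).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 2:
        warnings.warn("evoked spectrum of a single trial has no averaging "
                      "benefit")
    mask = _slice_window(times, window)
    mean = epochs[:, mask].mean(axis=0)
    freqs, pxx = scipy.signal.periodogram(mean, fs=fs)
    return PsdCurve(freqs=freqs, power=pxx, method="evoked")
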