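"""Intertrial phase coherence and the evoked/total/induced power decomposition.

For complex wavelet coefficients phi_i per trial:

    ITPC          = | mean_i exp(i * angle(phi_i)) |
    total power   = mean_i |phi_i|^2
    evoked power  = | mean_i phi_i |^2
    induced power = mean_i |phi_hat_i|^2

where phi_hat_i are coefficients of the trials after subtracting the
subject's trial-average (evoked) signal in the time domain, before the
wavelet transform. Evoked power never exceeds total power (triangle
inequality on complex means); identical trials give ITPC = 1 and zero induced
power. Baseline normalization subtracts the per-frequency mean over a
prestimulus window, after which negative values read as desynchronization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import SpectralTensor, default_grid, morlet_transform

log = logging.getLogger(__name__)

BASELINE_WINDOW = (-0.25, -0.05)


def _coeffs(tensor):
    return tensor.coeffs if isinstance(tensor, SpectralTensor) else \
        np.asarray(tensor)


def itpc(tensor) -> np.ndarray:
    """Intertrial phase clustering per (frequency, time) point, in [0, 1].

    Zero-amplitude coefficients carry no phase; they are excluded from the
    circular mean (logged).
    """
    coeffs = _coeffs(tensor)
    if coeffs.shape[0] < 2:
        raise ValueError("ITPC requires at least two trials")
    mag = np.abs(coeffs)
    undefined = mag == 0
    if undefined.any():
        log.info("itpc: excluded %d zero-amplitude coefficient(s)",
                 int(undefined.sum()))
    unit = np.where(undefined, np.nan + 0j, coeffs / np.where(mag == 0, 1, mag))
    with np.errstate(invalid="ignore"):
        out = np.abs(np.nanmean(unit, axis=0))
    return np.clip(np.nan_to_num(out), 0.0, 1.0)


def itpc_group(subject_maps) -> np.ndarray:
    """Group-average ITPC: per-subject maps are Fisher z-transformed,
    averaged, and transformed back (per-subject map first, any band averaging
    after)."""
    maps = np.clip(np.asarray(subject_maps, dtype=float), 0.0, 1.0 - 1e-12)
    return np.tanh(np.arctanh(maps).mean(axis=0))


@dataclass
class PowerDecomposition:
    itpc: np.ndarray
    total_power: np.ndarray
    evoked_power: np.ndarray
    induced_power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_window: tuple | None = None
    normalized: bool = False


def power_decomposition(tensor: SpectralTensor,
                        erp_subtracted: SpectralTensor) -> PowerDecomposition:
    """Total/evoked/induced power plus ITPC from matched wavelet tensors.

    ``erp_subtracted`` must be the transform of the same trials after
    removing the trial-average signal in the time domain (see
    :func:`decompose_epochs` for the one-step path from epochs).
    """
    if tensor.coeffs.shape != erp_subtracted.coeffs.shape:
        raise ValueError("tensors must share shape")
    coeffs = tensor.coeffs
    total = (np.abs(coeffs) ** 2).mean(axis=0)
    evoked = np.abs(coeffs.mean(axis=0)) ** 2
    induced = (np.abs(erp_subtracted.coeffs) ** 2).mean(axis=0)
    return PowerDecomposition(
        itpc=itpc(tensor), total_power=total, evoked_power=evoked,
        induced_power=induced, freqs=tensor.freqs, times=tensor.times)


def decompose_epochs(epochs, times, fs, freqs=None, cycles=None,
                     normalize: bool = False) -> PowerDecomposition:
    """Wavelet-transform epochs and their ERP-subtracted copies, then
    decompose; optional baseline normalization of total and induced power."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    tensor = morlet_transform(epochs, fs, freqs, cycles, times=times)
    resid = epochs - epochs.mean(axis=0, keepdims=True)
    resid_tensor = morlet_transform(resid, fs, freqs, cycles, times=times)
    dec = power_decomposition(tensor, resid_tensor)
    if normalize:
        dec = baseline_normalize(dec)
    return dec


def baseline_normalize(powermap, times=None,
                       window=BASELINE_WINDOW):
    """Subtract the per-frequency mean power over the prestimulus window.

    Accepts a (n_freqs, n_times) array with explicit ``times``, or a
    :class:`PowerDecomposition` (total and induced power are normalized, per
    the direct-comparison convention; ITPC and evoked power are untouched).
    """
    if isinstance(powermap, PowerDecomposition):
        total = baseline_normalize(powermap.total_power, powermap.times, window)
        induced = baseline_normalize(powermap.induced_power, powermap.times,
                                     window)
        return PowerDecomposition(
            itpc=powermap.itpc, total_power=total,
            evoked_power=powermap.evoked_power, induced_power=induced,
            freqs=powermap.freqs, times=powermap.times,
            baseline_window=tuple(window), normalized=True)
    powermap = np.asarray(powermap, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the map times")
    return powermap - powermap[..., mask].mean(axis=-1, keepdims=True)


@dataclass
class AlphaEro:
    """Trial-averaged IAF-wavelet coefficient: the alpha evoked response
    oscillation."""

    times: np.ndarray
    ero: np.ndarray          # complex mean coefficient over trials
    envelope: np.ndarray     # |ero|
    freq_used: float

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.ero)) % 360.0


def alpha_ero(epochs, times, fs, iaf: float, freqs=None,
              cycles=None) -> AlphaEro:
    """Alpha-band evoked response oscillation at the wavelet nearest the IAF.

    The requested IAF is snapped to the nearest frequency on the wavelet grid
    (logged); trials are averaged as complex coefficients, so phase-consistent
    alpha survives and phase-random alpha cancels.
    """
    if freqs is None or cycles is None:
        gf, gc = default_grid()
        freqs = gf if freqs is None else np.asarray(freqs, dtype=float)
        cycles = np.interp(freqs, gf, gc) if cycles is None else \
            np.asarray(cycles, dtype=float)
    i = int(np.argmin(np.abs(np.asarray(freqs) - iaf)))
    f_used = float(np.asarray(freqs)[i])
    if abs(f_used - iaf) > 0.5:
        log.info("alpha_ero: using grid frequency %.2f Hz for IAF %.2f Hz",
                 f_used, iaf)
    tensor = morlet_transform(epochs, fs, [f_used],
                              [float(np.asarray(cycles)[i])], times=times)
    mean = tensor.coeffs.mean(axis=0)[0]
    return AlphaEro(times=np.asarray(times, dtype=float), ero=mean,
                    envelope=np.abs(mean), freq_used=f_used)
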