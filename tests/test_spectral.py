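"""Spectral module tests: multitaper, IAF, Morlet wavelets, instantaneous
frequency, prestimulus spectra."""

import numpy as np
import pytest
import scipy.signal

from alphalock.echt import FilterSpec
from alphalock.spectral import (NoAlphaPeakError, default_grid, detrend_psd,
                                estimate_iaf, evoked_spectrum,
                                instantaneous_frequency, morlet_transform,
                                multitaper_psd, multitaper_spectrogram,
                                prestim_psd)

FS = 501.0


class TestMultitaper:
    def test_single_tone_peaks_at_every_time_step(self):
        t = np.arange(int(20 * FS)) / FS
        f, times, power = multitaper_spectrogram(np.cos(2 * np.pi * 10 * t),
                                                 FS)
        keep = (f >= 1) & (f <= 70)
        peak_f = f[keep][np.argmax(power[keep], axis=0)]
        assert np.all(np.abs(peak_f - 10.0) <= 0.5)

    def test_white_noise_spectrum_flat_within_factor_two(self):
        # 240 s gives ~160 independent taper-window estimates per bin,
        # enough that the extreme bins stay within a factor two
        rng = np.random.default_rng(3)
        f, p = multitaper_psd(rng.standard_normal(int(240 * FS)), FS)
        band = p[(f >= 1) & (f <= 70)]
        assert band.max() / band.min() < 2.0

    def test_two_tones_resolved(self):
        t = np.arange(int(30 * FS)) / FS
        sig = np.cos(2 * np.pi * 8 * t) + np.cos(2 * np.pi * 13 * t)
        f, p = multitaper_psd(sig, FS)
        peaks, _ = scipy.signal.find_peaks(p[(f >= 6) & (f <= 15)])
        freqs = f[(f >= 6) & (f <= 15)][peaks]
        assert np.any(np.abs(freqs - 8) < 0.5)
        assert np.any(np.abs(freqs - 13) < 0.5)

    def test_recording_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            multitaper_spectrogram(np.zeros(int(2 * FS)), FS)


class TestEstimateIaf:
    def test_recovers_gaussian_bump_frequency(self):
        rng = np.random.default_rng(4)
        f = np.linspace(0.5, 70, 418)
        power = 10.0 / f + 5.0 * np.exp(-(f - 10.5) ** 2 / (2 * 0.8**2))
        power *= 1 + 0.01 * rng.standard_normal(f.size)
        assert estimate_iaf(f, power) == pytest.approx(10.5, abs=f[1] - f[0])

    def test_pure_tone_on_flat_noise(self):
        t = np.arange(int(40 * FS)) / FS
        rng = np.random.default_rng(5)
        sig = 5 * np.cos(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(
            t.size)
        f, p = multitaper_psd(sig, FS)
        assert estimate_iaf(f, p) == pytest.approx(10.0, abs=0.1)

    def test_no_alpha_peak_raises(self):
        f = np.linspace(0.5, 70, 418)
        with pytest.raises(NoAlphaPeakError):
            estimate_iaf(f, 10.0 / f)

    def test_detrend_rejects_negative_power(self):
        with pytest.raises(ValueError):
            detrend_psd(np.linspace(1, 40, 50), -np.ones(50))


class TestMorlet:
    def test_cycle_grid_defaults(self):
        freqs, cycles = default_grid()
        assert freqs.size == 140 and cycles.size == 140
        assert freqs[0] == 1.0 and freqs[-1] == 70.0
        assert cycles[0] == 5.0 and cycles[-1] == 12.0

    def test_sigma_formula_at_ten_hz_six_cycles(self):
        # sigma = c / (2 pi f); reflected in the kernel's Gaussian width
        from alphalock.spectral import _morlet_kernel
        k = _morlet_kernel(10.0, 6.0, FS)
        sigma = 6.0 / (2 * np.pi * 10.0)
        assert sigma == pytest.approx(0.0955, abs=1e-4)
        # half-width at 1/sqrt(e) of the envelope equals sigma
        env = np.abs(k) / np.abs(k).max()
        t = (np.arange(k.size) - k.size // 2) / FS
        assert np.interp(sigma, t[t >= 0], env[t >= 0]) == pytest.approx(
            np.exp(-0.5), abs=0.01)

    def test_unit_cosine_flat_unit_envelope_mid_epoch(self):
        t = np.arange(int(3 * FS)) / FS
        freqs, cycles = default_grid()
        i = np.argmin(np.abs(freqs - 10.0))
        tensor = morlet_transform(np.cos(2 * np.pi * freqs[i] * t), FS,
                                  [freqs[i]], [cycles[i]])
        mid = tensor.envelope[0, 0, 400:-400]
        assert np.all(np.abs(mid - 1.0) < 0.01)

    def test_phase_zero_at_cosine_peak(self):
        t = np.arange(int(3 * FS)) / FS
        tensor = morlet_transform(np.cos(2 * np.pi * 10.02 * t), FS,
                                  [10.02], [6.0])
        peak = 400 + np.argmax(np.cos(2 * np.pi * 10.02 * t[400:460]))
        ph = tensor.phase_deg[0, 0, peak]
        assert min(ph, 360 - ph) < 5.0

    def test_nyquist_frequency_rejected(self):
        with pytest.raises(ValueError):
            morlet_transform(np.zeros(1000), FS, [300.0], [6.0])

    def test_matches_mne_reference_transform(self):
        """Cross-check against an independent Morlet implementation."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(6)
        epochs = rng.standard_normal((3, int(2 * FS)))
        f = np.array([10.0])
        ours = morlet_transform(epochs, FS, f, [7.0])
        theirs = mne.time_frequency.tfr_array_morlet(
            epochs[:, None, :], FS, f, n_cycles=7.0, output="complex",
            zero_mean=False)[:, 0, 0, :]
        # compare away from edges (different padding strategies)
        sl = slice(300, -300)
        ratio = np.abs(ours.coeffs[:, 0, sl]) / np.abs(theirs[:, sl])
        assert np.std(ratio) / np.mean(ratio) < 0.02  # same shape up to gain
        dphi = np.angle(ours.coeffs[:, 0, sl] * np.conj(theirs[:, sl]))
        assert np.max(np.abs(dphi)) < 0.05


class TestInstantaneousFrequency:
    def test_constant_frequency_recovered(self, clean_alpha, spec10):
        freq, valid = instantaneous_frequency(clean_alpha.signal[0], spec10,
                                              "sht")
        assert np.nanmean(np.abs(freq[valid] - 10.0)) < 0.05

    def test_chirp_tracked_mid_signal(self, spec10):
        t = np.arange(int(2 * FS)) / FS
        chirp = scipy.signal.chirp(t, f0=8.0, f1=12.0, t1=2.0,
                                   method="linear")
        inst_true = 8.0 + (12.0 - 8.0) / 2.0 * t
        # mid-signal: instantaneous frequency within ~0.5 Hz of the filter
        # center, where the causal filter's group delay is flat
        mid = slice(int(0.75 * FS), int(1.25 * FS))
        # standard-Hilbert estimate, unsmoothed
        freq, valid = instantaneous_frequency(chirp, spec10, "sht")
        err = np.abs(freq[mid] - inst_true[mid])[valid[mid]]
        assert np.nanmax(err) < 0.3
        # per-sample ecHT endpoint estimate with the optional median filter
        # at half an alpha cycle (the endpoint readout ripples on a chirp)
        freq, valid = instantaneous_frequency(chirp, spec10, "echt",
                                              median_ms=51.0)
        err = np.abs(freq[mid] - inst_true[mid])[valid[mid]]
        assert np.nanmax(err) < 0.3

    def test_noise_only_has_undefined_samples_or_wild_variance(self):
        rng = np.random.default_rng(7)
        spec = FilterSpec(10.0, FS)
        freq, valid = instantaneous_frequency(
            1e-3 * rng.standard_normal(int(4 * FS)), spec, "sht",
            envelope_floor=1e-3)
        assert (~valid).sum() > 0

    def test_prestim_mean_matches_iaf_on_stationary_alpha(self, noisy_alpha,
                                                          spec10):
        freq, valid = instantaneous_frequency(noisy_alpha.signal[0], spec10,
                                              "sht")
        assert np.nanmean(freq[valid]) == pytest.approx(10.0, abs=0.1)


class TestPrestimSpectra:
    def _epochs(self, amp, n=40, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(-int(0.75 * FS), int(0.1 * FS) + 1) / FS
        phases = rng.uniform(0, 2 * np.pi, n)
        data = amp * np.cos(2 * np.pi * 10.0 * times[None, :]
                            + phases[:, None])
        data += rng.standard_normal((n, times.size))
        return data, times

    def test_alpha_power_scales_with_amplitude_squared(self):
        hi, times = self._epochs(8.0, seed=1)
        lo, _ = self._epochs(2.0, seed=2)
        c_hi = prestim_psd(hi, times, FS, detrend=None)
        c_lo = prestim_psd(lo, times, FS, detrend=None)
        band = (c_hi.freqs >= 8) & (c_hi.freqs <= 12)
        ratio = c_hi.power[band].sum() / c_lo.power[band].sum()
        assert ratio == pytest.approx(16.0, rel=0.2)

    def test_zero_signal_zero_power(self):
        times = np.arange(-int(0.75 * FS), 1) / FS
        curve = prestim_psd(np.zeros((5, times.size)), times, FS)
        assert np.all(curve.power == 0.0)

    def test_window_beyond_epoch_rejected(self):
        times = np.arange(-int(0.25 * FS), int(0.5 * FS)) / FS
        with pytest.raises(ValueError):
            prestim_psd(np.zeros((3, times.size)), times, FS,
                        window=(-0.5, 0.0))

    def test_evoked_spectrum_attenuates_random_phase_alpha(self):
        locked, times = self._epochs(5.0, n=100, seed=3)
        locked[:] = 5.0 * np.cos(2 * np.pi * 10.0 * times[None, :])  # locked
        random, _ = self._epochs(5.0, n=100, seed=4)
        e_locked = evoked_spectrum(locked, times, FS)
        e_random = evoked_spectrum(random, times, FS)
        band = (e_locked.freqs >= 8) & (e_locked.freqs <= 12)
        assert e_locked.power[band].max() > 20 * e_random.power[band].max()

    def test_identical_trials_evoked_equals_single_trial(self):
        times = np.arange(-int(0.7 * FS), 1) / FS
        trial = np.cos(2 * np.pi * 10 * times)
        e = evoked_spectrum(np.tile(trial, (5, 1)), times, FS,
                            window=(times[0], 0.0))
        f1, p1 = scipy.signal.periodogram(trial, fs=FS)
        np.testing.assert_allclose(e.power, p1, atol=1e-12)

    def test_single_trial_flagged(self):
        times = np.arange(-int(0.75 * FS), 1) / FS
        with pytest.warns(UserWarning):
            evoked_spectrum(np.zeros((1, times.size)), times, FS)
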