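"""Generator tests: oscillator ground truth, event scheduling, ERP embedding."""

import numpy as np
import pytest
import scipy.signal
import scipy.stats

from alphalock.synthgen import (COMPONENT_WINDOWS, ISI_GRIDS, ErpTemplate,
                                EventTable, default_template,
                                embed_responses, generate_dataset,
                                make_background, schedule_events)

FS = 501.0


class TestMakeBackground:
    def test_zero_amplitudes_give_zero_signal_with_defined_phase(self):
        rec = make_background(2.0, FS, iaf=10.0, alpha_amp=0.0, noise_amp=0.0,
                              seed=0)
        assert np.all(rec.signal == 0.0)
        assert np.all((rec.truth_phase >= 0) & (rec.truth_phase < 360))

    def test_periodogram_peak_at_oscillator_frequency(self):
        rec = make_background(20.0, FS, iaf=10.0, alpha_amp=10.0,
                              noise_amp=0.0, seed=1)
        f, p = scipy.signal.periodogram(rec.signal[0], fs=FS)
        assert abs(f[np.argmax(p)] - 10.0) <= f[1] - f[0]

    def test_same_seed_bit_identical(self):
        a = make_background(3.0, FS, iaf=9.0, alpha_amp=4.0, noise_amp=2.0,
                            seed=7)
        b = make_background(3.0, FS, iaf=9.0, alpha_amp=4.0, noise_amp=2.0,
                            seed=7)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_phase_advances_at_alpha_rate(self):
        rec = make_background(5.0, FS, iaf=11.0, alpha_amp=1.0, noise_amp=0.0,
                              seed=2)
        step = np.diff(np.unwrap(np.radians(rec.truth_phase[0])))
        np.testing.assert_allclose(np.degrees(step), 360.0 * 11.0 / FS,
                                   atol=1e-8)

    def test_fz_channel_is_scaled_lagged_copy(self):
        rec = make_background(4.0, FS, iaf=10.0, alpha_amp=5.0, noise_amp=1.0,
                              seed=3, fz_scale=0.8, fz_lag_deg=10.0)
        assert rec.channels == ("Fpz", "Fz")
        lag = int(round(10.0 / (360.0 * 10.0) * FS))
        np.testing.assert_allclose(rec.signal[1],
                                   0.8 * np.roll(rec.signal[0], lag))

    @pytest.mark.parametrize("kwargs", [
        dict(iaf=np.nan), dict(alpha_amp=-1.0), dict(iaf=20.0),
        dict(noise_amp=np.inf)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_background(1.0, FS, **kwargs)


class TestScheduleEvents:
    def test_trough_peak_isis_on_the_10ms_grid(self):
        onsets = schedule_events("trough_peak", 300.0, seed=5)
        isis = np.round(np.diff(onsets), 3)
        assert set(isis) <= {1.628, 1.638, 1.648}

    def test_random_isis_within_stated_range(self):
        onsets = schedule_events("random", 300.0, seed=6)
        isis = np.diff(onsets)
        assert isis.min() >= 0.878 - 1e-9 and isis.max() <= 1.634 + 1e-9

    def test_first_onset_after_baseline_and_all_before_end(self):
        onsets = schedule_events("random", 60.0, seed=7)
        assert onsets[0] > 30.0
        assert onsets[-1] < 60.0

    def test_degenerate_duration_yields_no_events(self):
        with pytest.warns(UserWarning):
            onsets = schedule_events("trough_peak", 30.0, seed=0)
        assert onsets.size == 0

    def test_isi_distribution_uniform_by_chi_square(self):
        rng = np.random.default_rng(0)
        grid = ISI_GRIDS["trough_peak"]
        draws = []
        t = 30.0
        onsets = schedule_events("trough_peak", 30.0 + 10_000 * 1.66, seed=42)
        isis = np.round(np.diff(onsets), 3)
        counts = [np.sum(isis == v) for v in grid]
        _, p = scipy.stats.chisquare(counts)
        assert p > 0.01


class TestErpTemplate:
    def test_default_template_valid_and_windows_respected(self):
        t = default_template()
        for c, (lo, hi) in COMPONENT_WINDOWS.items():
            assert lo <= t.latency[c] <= hi

    def test_disordered_latencies_rejected(self):
        t = default_template()
        lat = dict(t.latency)
        lat["P1"], lat["N1"] = 0.079, 0.081  # still inside windows
        lat["Pa"] = 0.080  # out of order
        with pytest.raises(ValueError):
            ErpTemplate(latency={**lat}, amplitude=dict(t.amplitude),
                        width=dict(t.width))

    def test_sign_constraints_enforced(self):
        t = default_template()
        amp = dict(t.amplitude)
        amp["N1"] = 1.0
        with pytest.raises(ValueError):
            ErpTemplate(latency=dict(t.latency), amplitude=amp,
                        width=dict(t.width))


class TestEmbedResponses:
    def _flat_rec(self, duration=10.0):
        return make_background(duration, FS, iaf=10.0, alpha_amp=0.0,
                               noise_amp=0.0, seed=0)

    def test_zero_gain_is_identity(self):
        rec = self._flat_rec()
        tpl = default_template()
        zero = ErpTemplate(latency=dict(tpl.latency),
                           amplitude=dict(tpl.amplitude),
                           width=dict(tpl.width),
                           phase_gain={"trough": {c: 0.0 for c in tpl.latency}})
        ev = EventTable(onset_sample=np.array([1000]),
                        condition=np.array(["trough"], dtype=object))
        out = embed_responses(rec, ev, zero)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_single_trial_p1_peak_value(self):
        """P1 amplitude 3 µV at 60 ms appears at 60 ms (± neighbour overlap)."""
        rec = self._flat_rec()
        tpl = default_template()
        t3 = ErpTemplate(latency=dict(tpl.latency),
                         amplitude={**tpl.amplitude, "P1": 3.0},
                         width=dict(tpl.width))
        ev = EventTable(onset_sample=np.array([2000]),
                        condition=np.array(["random"], dtype=object))
        out = embed_responses(rec, ev, t3)
        idx = 2000 + int(round(0.060 * FS))
        # neighbours (Pa at 25 ms, N1 at 102 ms) have no support at 60 ms;
        # tolerance covers the sub-sample offset of the 60 ms latency
        assert abs(out.signal[0][idx] - 3.0) < 0.01

    def test_trough_vs_peak_gain_ratio_in_averaged_epochs(self):
        rec = self._flat_rec(40.0)
        tpl = default_template()
        mod = ErpTemplate(latency=dict(tpl.latency),
                          amplitude=dict(tpl.amplitude),
                          width=dict(tpl.width),
                          phase_gain={"trough": {"P1": 1.5},
                                      "peak": {"P1": 0.5}})
        onsets = np.arange(1000, 19000, 600)
        conds = np.array(["trough", "peak"] * (onsets.size // 2),
                         dtype=object)[:onsets.size]
        ev = EventTable(onset_sample=onsets, condition=conds)
        out = embed_responses(rec, ev, mod)
        p1 = int(round(0.060 * FS))
        amp_t = np.mean([out.signal[0][o + p1]
                         for o, c in zip(onsets, conds) if c == "trough"])
        amp_p = np.mean([out.signal[0][o + p1]
                         for o, c in zip(onsets, conds) if c == "peak"])
        assert amp_t / amp_p == pytest.approx(3.0, rel=1e-6)

    def test_event_past_end_dropped_with_warning(self):
        rec = self._flat_rec(2.0)
        ev = EventTable(onset_sample=np.array([100, rec.n_samples - 10]),
                        condition=np.array(["random", "random"], dtype=object))
        with pytest.warns(UserWarning):
            embed_responses(rec, ev)
        assert ev.flagged[1] and not ev.flagged[0]

    def test_noiseless_trial_average_reproduces_template(self):
        """Averaging embedded noiseless epochs recovers the template exactly."""
        rec = self._flat_rec(60.0)
        tpl = default_template()
        onsets = np.arange(1000, 28000, 500)
        ev = EventTable(onset_sample=onsets,
                        condition=np.full(onsets.size, "random", dtype=object))
        out = embed_responses(rec, ev, tpl)
        w = tpl.waveform(FS, "random")
        epochs = np.stack([out.signal[0][o:o + w.size] for o in onsets])
        assert np.max(np.abs(epochs.mean(axis=0) - w)) < 1e-9


class TestGenerateDataset:
    def test_trough_peak_event_count_near_expectation(self, profile10):
        rec, ev = generate_dataset(profile10, "trough_peak", 900.0, seed=3,
                                   fz_scale=None, embed=False)
        assert abs(len(ev) - 531) <= 10

    def test_high_vs_low_alpha_prestim_power(self, profile10):
        _, _ = generate_dataset(profile10, "random", 60.0, seed=4,
                                fz_scale=None, embed=False)
        hi, _ = generate_dataset(profile10, "trough_peak", 60.0, seed=4,
                                 fz_scale=None, embed=False)
        lo, _ = generate_dataset(profile10, "random", 60.0, seed=4,
                                 fz_scale=None, embed=False)
        band = lambda r: np.var(
            scipy.signal.sosfiltfilt(scipy.signal.butter(
                2, [8, 12], "bandpass", fs=FS, output="sos"), r.signal[0]))
        assert band(hi) / band(lo) > 1.0

    def test_different_seeds_different_timings(self, profile10):
        _, ev1 = generate_dataset(profile10, "trough_peak", 70.0, seed=1,
                                  fz_scale=None, embed=False)
        _, ev2 = generate_dataset(profile10, "trough_peak", 70.0, seed=2,
                                  fz_scale=None, embed=False)
        assert not np.array_equal(ev1.onset_sample, ev2.onset_sample)

    def test_ideal_delivery_hits_target_phase(self, profile10):
        rec, ev = generate_dataset(profile10, "trough_peak", 80.0, seed=5,
                                   fz_scale=None, embed=False)
        err = np.abs((ev.true_phase - ev.target_phase + 180) % 360 - 180)
        assert np.nanmax(err) <= 360.0 * 10.0 / FS  # one-sample quantization


class TestEventTable:
    def test_onsets_must_increase(self):
        with pytest.raises(ValueError):
            EventTable(onset_sample=np.array([5, 5]),
                       condition=np.array(["a", "b"], dtype=object))

    def test_phases_wrapped_into_range(self):
        ev = EventTable(onset_sample=np.array([1]),
                        condition=np.array(["trough"], dtype=object),
                        target_phase=np.array([370.0]))
        assert ev.target_phase[0] == pytest.approx(10.0)
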