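"""Stimulation waveforms and evoked-potential processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protustim import (
    EvokedModel,
    EvokedPotential,
    TrialSet,
    amplitude_series,
    bandpass_and_average,
    build_stim_waveform,
    evoked_template,
    load_trialset_csv,
    load_trialset_h5,
    measure_response,
    save_trialset_csv,
    save_trialset_h5,
    simulate_amplitude_sweep,
    simulate_trials,
)


class TestStimWaveform:
    def test_protocol_waveform_structure(self):
        """The stimulation unit: 1 ms phases, 1 ms gap, three repeats,
        exactly zero net charge."""
        w = build_stim_waveform(256.0, 1.0, 1.0, 3)
        assert w.total_charge == 0.0
        assert w.duration_ms == pytest.approx(9.0)
        # six nonzero phases (two per repeat)
        signs = np.sign(w.samples)
        changes = np.count_nonzero(np.diff(signs))
        assert np.count_nonzero(signs != 0) == 6 * 25  # 25 samples/ms at 25 kHz
        # 2 transitions inside each repeat (phase->gap, gap->phase) plus a
        # direct polarity flip between consecutive repeats
        assert changes == 3 * 2 + 2

    def test_polarity_symmetry(self):
        c = build_stim_waveform(64.0, polarity_first="cathodic")
        a = build_stim_waveform(64.0, polarity_first="anodic")
        assert np.array_equal(c.samples, -a.samples)
        assert c.samples[0] < 0 < a.samples[0]

    def test_nonzero_duration_sums_segments(self):
        w = build_stim_waveform(128.0, phase_ms=2.0, interpulse_ms=0.5,
                                n_repeats=2)
        nonzero_ms = np.count_nonzero(w.samples) / w.sampling_rate * 1e3
        assert nonzero_ms == pytest.approx(2 * 2 * 2.0)

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError):
            build_stim_waveform(64.0, phase_ms=1.0, sampling_rate=5000.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1.0, 500.0), st.integers(1, 5),
           st.sampled_from(["cathodic", "anodic"]))
    def test_charge_balance_exact(self, amp, repeats, pol):
        w = build_stim_waveform(amp, 1.0, 1.0, repeats, pol)
        assert w.total_charge == 0.0


class TestBandpassAndAverage:
    def test_out_of_band_tone_rejected(self):
        """A 500 Hz tone must be attenuated > 20 dB by the 1–100 Hz band."""
        rate = 25_000.0
        t = np.arange(int(rate)) / rate
        tone = 50.0 * np.sin(2 * np.pi * 500.0 * t)
        ts = TrialSet(np.stack([tone, tone]), rate, trigger_index=1000)
        ev = bandpass_and_average(ts)
        mid = slice(len(ev.trace) // 4, 3 * len(ev.trace) // 4)
        out_amp = np.max(np.abs(ev.trace[mid]))
        assert 20 * np.log10(50.0 / out_amp) > 20.0

    def test_identical_trials_average_to_single(self):
        model = EvokedModel(noise_sd_uV=0.0, n_trials=1)
        single = simulate_trials(model, 256.0).sweeps[0]
        ts = TrialSet(np.tile(single, (100, 1)), model.sampling_rate,
                      trigger_index=2500)
        ev = bandpass_and_average(ts)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [1.0, 100.0], btype="bandpass",
                     fs=model.sampling_rate, output="sos")
        expect = sosfiltfilt(sos, single)
        assert np.allclose(ev.trace, expect)

    def test_zero_phase_no_latency_bias(self):
        """A symmetric pulse stays symmetric about its center after filtering."""
        rate = 25_000.0
        n = 25_000
        x = np.zeros(n)
        c = n // 2
        width = 500
        x[c - width: c + width + 1] = np.hanning(2 * width + 1)
        ts = TrialSet(np.stack([x, x]), rate, trigger_index=100)
        ev = bandpass_and_average(ts)
        peak = np.argmax(ev.trace)
        assert abs(peak - c) <= 1  # zero-phase: the peak does not move

    def test_noise_reduction_follows_sqrt_n(self):
        """Averaging n=100 independent-noise trials shrinks residual noise
        ≈ 10-fold (Monte-Carlo vs the 1/√n law)."""
        model = EvokedModel(noise_sd_uV=20.0, n_trials=100, seed=11)
        ts = simulate_trials(model, 256.0)
        ev = bandpass_and_average(ts)
        template = evoked_template(model)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [1.0, 100.0], btype="bandpass",
                     fs=model.sampling_rate, output="sos")
        ftemp = sosfiltfilt(sos, template)
        trig = 2500
        resid_mean = np.std(ev.trace - ftemp[trig - 2500:])
        single = sosfiltfilt(sos, ts.sweeps[0])
        resid_single = np.std(single - ftemp)
        ratio = resid_single / resid_mean
        assert 7.0 < ratio < 14.0

    def test_mismatched_band_rejected(self):
        ts = TrialSet(np.zeros((3, 1000)), 25_000.0, 10)
        with pytest.raises(ValueError):
            bandpass_and_average(ts, 100.0, 1.0)

    def test_single_trial_rejected(self):
        ts = TrialSet(np.zeros((1, 1000)), 25_000.0, 10)
        with pytest.raises(ValueError):
            bandpass_and_average(ts)


class TestMeasureResponse:
    def _evoked_from(self, trace, rate=25_000.0, trig=2500):
        times = (np.arange(len(trace)) - trig) / rate * 1e3
        return EvokedPotential(trace, times, rate, 100)

    def test_noise_free_exact_recovery(self):
        """A noise-free evoked trace with an 80 µV peak at 45 ms is recovered
        exactly."""
        model = EvokedModel(peak_amplitude_uV=80.0, latency_ms=45.0,
                            noise_sd_uV=0.0)
        trace = evoked_template(model)
        ev = self._evoked_from(trace)
        amp, lat = measure_response(ev)
        # baseline window catches the far gaussian tail (~1e-6 µV): exact to
        # the template's own support, not to float epsilon
        assert amp == pytest.approx(80.0, abs=1e-4)
        assert lat == pytest.approx(45.0, abs=1e3 / 25_000.0)

    def test_flat_trace_undefined_latency(self):
        ev = self._evoked_from(np.zeros(10_000))
        amp, lat = measure_response(ev, window_ms=(0.0, 200.0))
        assert amp == 0.0 and lat is None

    def test_window_before_trigger_rejected(self):
        ev = self._evoked_from(np.zeros(10_000))
        with pytest.raises(ValueError):
            measure_response(ev, window_ms=(-10.0, 100.0))

    def test_latency_recovery_under_noise(self):
        """Median recovered latency over noisy syntheses stays within one
        filter settling time (~1/high-edge) of the truth."""
        model = EvokedModel(seed=21)
        rng = np.random.default_rng(21)
        lats = []
        for _ in range(50):
            ts = simulate_trials(model, 256.0, rng=rng)
            ev = bandpass_and_average(ts)
            _, lat = measure_response(ev)
            lats.append(lat)
        settle_ms = 1e3 / 100.0  # 10 ms at the 100 Hz edge
        assert abs(np.median(lats) - model.latency_ms) < settle_ms


class TestAmplitudeSeries:
    def test_threshold_behaviour(self):
        """With the generator's sigmoid threshold between 64 and 128 µA, only
        the 64 µA entry stays below the single-trial-noise detection rule."""
        model = EvokedModel(seed=7)
        series = amplitude_series(simulate_amplitude_sweep(model))
        df = series.table.set_index("stim_amplitude_uA")
        assert not df.loc[64.0, "detected"]
        assert df.loc[[128.0, 192.0, 256.0], "detected"].all()
        assert series.kendall_tau > 0.0

    def test_all_zero_input_flat_curve(self):
        ts = {a: TrialSet(np.zeros((4, 20_000)), 25_000.0, 5000)
              for a in (64.0, 128.0)}
        series = amplitude_series(ts)
        assert (series.table["response_uV"] == 0.0).all()
        assert series.kendall_tau == 0.0

    def test_pipeline_linearity(self):
        """Doubling every sweep doubles the evoked amplitudes."""
        model = EvokedModel(seed=3, n_trials=20)
        sets = simulate_amplitude_sweep(model, amplitudes_uA=(128.0, 256.0))
        doubled = {a: TrialSet(2 * t.sweeps, t.sampling_rate, t.trigger_index)
                   for a, t in sets.items()}
        s1 = amplitude_series(sets)
        s2 = amplitude_series(doubled)
        assert np.allclose(s2.table["response_uV"], 2 * s1.table["response_uV"])


class TestTrialSetIO:
    def test_h5_round_trip(self, tmp_path):
        ts = TrialSet(np.random.default_rng(0).normal(size=(5, 200)),
                      25_000.0, 50)
        path = tmp_path / "trials.h5"
        save_trialset_h5(path, ts)
        back = load_trialset_h5(path)
        assert np.array_equal(back.sweeps, ts.sweeps)
        assert np.array_equal(back.trigger_index, ts.trigger_index)
        assert back.sampling_rate == ts.sampling_rate

    def test_csv_round_trip(self, tmp_path):
        ts = TrialSet(np.random.default_rng(1).normal(size=(3, 100)),
                      12_500.0, 10)
        path = tmp_path / "trials.csv"
        save_trialset_csv(path, ts)
        back = load_trialset_csv(path)
        assert np.allclose(back.sweeps, ts.sweeps)
        assert back.sampling_rate == 12_500.0
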