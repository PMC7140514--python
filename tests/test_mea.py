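"""Unit and property tests for the MEA analysis chain."""

import math

import numpy as np
import pytest
from scipy import signal

from neurophenolab.errors import InvalidParameterError
from neurophenolab.mea import (VoltageRecording, SpikeTrainSet,
                               bandpass_filter, filter_magnitude_response,
                               estimate_noise_sd, detect_spikes,
                               classify_active_electrodes, mean_firing_rate,
                               detect_bursts, detect_network_bursts,
                               participation_threshold, compute_well_metrics,
                               export_raster)
from conftest import make_trains

FS = 12_500.0


def sine_recording(freq_hz, duration_s=2.0, amplitude=1.0):
    t = np.arange(int(duration_s * FS)) / FS
    return VoltageRecording(amplitude * np.sin(2 * np.pi * freq_hz * t)[None, :], FS)


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = bandpass_filter(sine_recording(1000.0))
        mid = rec.voltage[0, 2000:-2000]
        assert mid.max() == pytest.approx(1.0, rel=0.01)

    def test_out_of_band_tone_suppressed(self):
        # design response at 10 Hz predicts essentially total rejection
        mag10 = filter_magnitude_response(FS, np.array([10.0]))[0]
        assert mag10 < 0.1
        rec = bandpass_filter(sine_recording(10.0, duration_s=4.0))
        assert np.abs(rec.voltage[0, 5000:-5000]).max() < 0.1

    def test_design_cutoffs_at_3db(self):
        freqs = np.linspace(150, 3500, 20000)
        mag = filter_magnitude_response(FS, freqs)
        half = 1 / math.sqrt(2)
        band = freqs[mag >= half]
        assert band.min() == pytest.approx(200.0, rel=0.01)
        assert band.max() == pytest.approx(3000.0, rel=0.01)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(sine_recording(100.0), low_hz=200, high_hz=7000)


class TestNoiseSd:
    def test_consistency_on_gaussian_noise(self, rng):
        v = rng.normal(0, 1.0, size=(2, int(60 * FS)))
        sd = estimate_noise_sd(VoltageRecording(v, FS))
        assert sd == pytest.approx([1.0, 1.0], abs=0.02)

    def test_homogeneous_in_scale(self, rng):
        v = rng.normal(0, 1.0, size=(1, 50_000))
        rec = VoltageRecording(v, FS)
        rec5 = VoltageRecording(5 * v, FS)
        assert estimate_noise_sd(rec5)[0] == pytest.approx(
            5 * estimate_noise_sd(rec)[0])

    def test_robust_to_spike_contamination(self, rng):
        v = rng.normal(0, 1.0, size=int(60 * FS))
        clean = estimate_noise_sd(VoltageRecording(v[None], FS))[0]
        spiky = v.copy()
        idx = rng.choice(v.size, size=v.size // 100, replace=False)
        spiky[idx] += 20.0                      # 1% of samples carry spikes
        robust = estimate_noise_sd(VoltageRecording(spiky[None], FS))[0]
        plain = estimate_noise_sd(VoltageRecording(spiky[None], FS),
                                  method="sd")[0]
        assert abs(robust - clean) / clean < 0.05
        assert plain > robust                   # plain SD is inflated

    def test_constant_trace_warns_zero(self):
        with pytest.warns(UserWarning):
            sd = estimate_noise_sd(VoltageRecording(np.ones((1, 20_000)), FS))
        assert sd[0] == 0.0


def pulse_trace(amplitudes, spacing_s=0.05):
    """Isolated single-sample-peak deflections at known amplitudes."""
    n = int((len(amplitudes) + 1) * spacing_s * FS)
    v = np.zeros(n)
    for i, a in enumerate(amplitudes):
        c = int((i + 1) * spacing_s * FS)
        v[c - 1:c + 2] = [0.4 * a, a, 0.4 * a]
    return VoltageRecording(v[None], FS)


class TestDetectSpikes:
    def test_six_sd_boundary_strict(self):
        rec = pulse_trace([5.9, 6.1])
        spikes = detect_spikes(rec, noise_sd=1.0)
        assert spikes.trains[0].size == 1
        assert spikes.trains[0][0] == pytest.approx(2 * 0.05, abs=1e-3)

    def test_zero_trace_no_spikes(self):
        spikes = detect_spikes(VoltageRecording(np.zeros((3, 10_000)), FS), 1.0)
        assert all(t.size == 0 for t in spikes.trains)

    def test_dead_time_suppresses_double_counting(self):
        v = np.zeros(10_000)
        v[5000] = 10.0
        v[5005] = 10.0                           # 0.4 ms later: inside dead time
        v[5030] = 10.0                           # 2.4 ms later: separate spike
        spikes = detect_spikes(VoltageRecording(v[None], FS), 1.0)
        assert spikes.trains[0].size == 2

    def test_lower_threshold_never_loses_spikes(self, rng):
        v = rng.normal(0, 1, size=(2, 100_000))
        rec = VoltageRecording(v, FS)
        n_prev = None
        for thr in (6.0, 5.0, 4.0, 3.0):
            n = sum(t.size for t in detect_spikes(rec, 1.0, thr).trains)
            if n_prev is not None:
                assert n >= n_prev
            n_prev = n

    def test_both_polarity_detects_negative(self):
        v = np.zeros(10_000)
        v[4000] = -8.0
        rec = VoltageRecording(v[None], FS)
        assert detect_spikes(rec, 1.0).trains[0].size == 0
        assert detect_spikes(rec, 1.0, polarity="both").trains[0].size == 1


class TestActiveElectrodes:
    def test_strict_five_per_minute_boundary(self):
        trains = [np.linspace(0.1, 299.9, 25), np.linspace(0.1, 299.9, 26)]
        spikes = SpikeTrainSet(trains, 300.0)
        assert classify_active_electrodes(spikes) == {1}

    def test_silent_well_empty(self):
        assert classify_active_electrodes(SpikeTrainSet([np.array([])] * 4,
                                                        300.0)) == set()

    def test_all_fast_electrodes_active(self):
        trains = [np.linspace(0.01, 299.9, 500) for _ in range(16)]
        spikes = SpikeTrainSet(trains, 300.0)
        assert classify_active_electrodes(spikes) == set(range(16))


class TestMeanFiringRate:
    def test_arithmetic_mean_over_active(self):
        spikes = SpikeTrainSet([np.linspace(0.1, 99.9, 100),
                                np.linspace(0.1, 99.9, 300)], 100.0)
        assert mean_firing_rate(spikes, {0, 1}) == pytest.approx(2.0)

    def test_single_electrode(self):
        spikes = SpikeTrainSet([np.linspace(0.01, 299.9, 300)], 300.0)
        assert mean_firing_rate(spikes, {0}) == pytest.approx(1.0)

    def test_empty_active_set_is_nan_not_zero(self):
        spikes = SpikeTrainSet([np.array([])], 60.0)
        assert math.isnan(mean_firing_rate(spikes, set()))


def burst_oracle(spikes, window_s=0.1, min_spikes=5):
    """Brute-force: histogram each train, count bins strictly above."""
    n_bins = int(np.floor(spikes.duration_s / window_s + 1e-9))
    edges = np.arange(n_bins + 1) * window_s
    return [int((np.histogram(t, bins=edges)[0] > min_spikes).sum())
            for t in spikes.trains]


def network_oracle(spikes, window_s=0.1, min_spikes=50, fraction=0.35):
    n_bins = int(np.floor(spikes.duration_s / window_s + 1e-9))
    edges = np.arange(n_bins + 1) * window_s
    counts = np.array([np.histogram(t, bins=edges)[0] for t in spikes.trains])
    need = participation_threshold(spikes.n_electrodes, fraction)
    return int(((counts > min_spikes).sum(axis=0) >= need).sum())


class TestBursts:
    def test_strict_five_spike_boundary(self):
        t = np.concatenate([0.82 + np.linspace(0, 0.05, 6),     # 6 in one bin
                            2.31 + np.linspace(0, 0.05, 5)])    # 5 in another
        calls = detect_bursts(SpikeTrainSet([np.sort(t)], 10.0))
        assert calls.total_bursts == 1

    def test_background_rate_produces_no_bursts(self, rng):
        # Poisson 5 Hz: expected 0.5 spikes per 100 ms bin; Pr(>5) ~ 2e-5
        spikes = make_trains(rng, 4, 60.0, 5.0)
        assert detect_bursts(spikes).total_bursts <= 1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            spikes = make_trains(rng, 3, rng.uniform(1, 10),
                                 rng.uniform(10, 120))
            calls = detect_bursts(spikes)
            assert [len(calls.bursts[e]) for e in range(3)] == \
                burst_oracle(spikes)

    def test_lower_min_spikes_never_loses_bursts(self, rng):
        spikes = make_trains(rng, 4, 10.0, 80.0)
        counts = [detect_bursts(spikes, min_spikes=m).total_bursts
                  for m in (8, 6, 4, 2)]
        assert counts == sorted(counts)


def shared_bin_trains(n_electrodes, hot, k_hot, duration_s=10.0, bin_start=1.0):
    """`hot` electrodes with `k_hot` spikes inside one shared 100 ms bin."""
    trains = []
    for e in range(n_electrodes):
        k = k_hot[e] if hasattr(k_hot, "__len__") else (k_hot if e in hot else 0)
        trains.append(bin_start + np.linspace(0.001, 0.098, k) if k else
                      np.array([]))
    return SpikeTrainSet(trains, duration_s)


class TestNetworkBursts:
    def test_participation_fraction_of_sixteen(self):
        # ceil(0.35 x 16) = 6 electrodes needed
        six = shared_bin_trains(16, set(range(6)), 51)
        five = shared_bin_trains(16, set(range(5)), 51)
        assert detect_network_bursts(six).count == 1
        assert detect_network_bursts(five).count == 0

    def test_fifty_spikes_is_not_participation(self):
        at_50 = shared_bin_trains(16, set(range(8)), 50)
        assert detect_network_bursts(at_50).count == 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            spikes = make_trains(rng, 8, rng.uniform(1, 5),
                                 rng.uniform(100, 400))
            assert detect_network_bursts(spikes).count == network_oracle(spikes)

    def test_lower_participation_never_loses_bursts(self, rng):
        spikes = make_trains(rng, 8, 5.0, 300.0)
        counts = [detect_network_bursts(spikes, participation_fraction=f).count
                  for f in (0.8, 0.5, 0.35, 0.1)]
        assert counts == sorted(counts)

    def test_frequency_per_minute(self):
        spikes = shared_bin_trains(16, set(range(16)), 60, duration_s=180.0)
        assert detect_network_bursts(spikes).frequency_per_min == \
            pytest.approx(1 / 3)


class TestWellMetrics:
    def test_silent_well_sentinels(self):
        spikes = SpikeTrainSet([np.array([])] * 16, 300.0)
        wm = compute_well_metrics(spikes, detect_bursts(spikes),
                                  detect_network_bursts(spikes))
        assert (wm.active_electrodes, wm.burst_count,
                wm.bursting_electrodes, wm.network_burst_freq_per_min) == \
            (0, 0, 0, 0.0)
        assert math.isnan(wm.mean_firing_rate_hz)

    def test_duration_mismatch_rejected(self):
        a = SpikeTrainSet([np.array([])], 60.0)
        b = SpikeTrainSet([np.array([])], 120.0)
        with pytest.raises(InvalidParameterError):
            compute_well_metrics(a, detect_bursts(a), detect_network_bursts(b))

    def test_rate_invariance_under_resampling(self, rng):
        # same noise-free spikes rendered at 12.5 and 25 kHz detect alike
        from neurophenolab.config import MeaSimConfig
        from neurophenolab.simulate.mea import (simulate_spike_trains,
                                                synthesize_voltage)
        base = dict(n_electrodes=4, duration_s=10.0, background_rate_hz=5.0,
                    burst_rate_hz=0.0, network_event_rate_per_min=0.0,
                    noise_sd_uv=0.0, spike_amplitude_uv=40.0)
        ss = np.random.SeedSequence(7)
        truth = simulate_spike_trains(MeaSimConfig(**base), ss)
        counts = []
        for rate in (12_500.0, 25_000.0):
            cfg = MeaSimConfig(sampling_rate_hz=rate, **base)
            rec = synthesize_voltage(truth, cfg, np.random.SeedSequence(8))
            spikes = detect_spikes(bandpass_filter(rec), noise_sd=1.0)
            counts.append([t.size for t in spikes.trains])
        assert np.all(np.abs(np.array(counts[0]) - np.array(counts[1])) <= 1)


class TestExportRaster:
    def test_csv_rows_equal_spike_count(self, tmp_path, rng):
        spikes = make_trains(rng, 4, 10.0, 20.0)
        table = export_raster(spikes, detect_bursts(spikes),
                              detect_network_bursts(spikes),
                              str(tmp_path / "raster.png"))
        assert len(table) == sum(t.size for t in spikes.trains)
        assert (tmp_path / "raster.png").exists()
        assert (tmp_path / "raster.csv").exists()

    def test_silent_well_header_only(self, tmp_path):
        spikes = SpikeTrainSet([np.array([])] * 4, 10.0)
        table = export_raster(spikes, None, None, str(tmp_path / "r.png"))
        assert table.empty
        header = (tmp_path / "r.csv").read_text().splitlines()
        assert header[0].startswith("electrode")
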