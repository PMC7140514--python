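"""Synthetic multi-electrode array recordings.

Spike trains are superpositions of three processes per electrode:

* a homogeneous Poisson background;
* burst epochs (a two-state process: epoch onsets arrive as a Poisson
  process, each opening a short high-rate window);
* well-wide network events: one extra high-rate 100 ms epoch implanted
  simultaneously on a configured fraction of the electrodes.

Voltage is Gaussian noise plus a biphasic ~1 ms waveform template placed at
each spike time. The template is scaled so that its peak height *after* the
default spike-band filter equals ``spike_amplitude_uv``, which makes the
detector-domain SNR directly controllable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ..config import MeaSimConfig, SimConfig
from ..errors import InvalidConfigError
from ..mea import VoltageRecording, SpikeTrainSet, design_bandpass

TEMPLATE_WIDTH_S = 1e-3


@dataclass
class MeaGroundTruth:
    """Everything needed to predict the analysis output at zero noise."""

    spike_times: list[np.ndarray]                 # per electrode, s
    burst_intervals: list[list[tuple[float, float]]]
    network_event_times: np.ndarray               # onsets, s
    network_electrodes: np.ndarray                # indices sharing the events
    duration_s: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "spike_times": [t.tolist() for t in self.spike_times],
            "burst_intervals": self.burst_intervals,
            "network_event_times": self.network_event_times.tolist(),
            "network_electrodes": self.network_electrodes.tolist(),
            "duration_s": self.duration_s,
        }


def spike_template(rate_hz: float) -> np.ndarray:
    """Biphasic ~1 ms waveform with its (positive) maximum at the centre.

    A dominant positive lobe followed by a shallower negative lobe; unit
    peak height before any scaling.
    """
    n = max(9, int(round(TEMPLATE_WIDTH_S * rate_hz)) | 1)  # odd length
    i = np.arange(n)
    centre = n // 2
    pos = np.exp(-0.5 * ((i - centre) / (n / 10.0)) ** 2)
    neg = -0.55 * np.exp(-0.5 * ((i - centre - n / 5.0) / (n / 6.0)) ** 2)
    w = pos + neg
    return w / w.max()


def filtered_template_peak(rate_hz: float) -> float:
    """Peak height of the unit template after the default zero-phase filter."""
    w = spike_template(rate_hz)
    padded = np.zeros(int(round(rate_hz * 0.05)))
    c = padded.size // 2
    padded[c - w.size // 2: c + w.size // 2 + 1] = w
    sos = design_bandpass(rate_hz)
    return float(signal.sosfiltfilt(sos, padded).max())


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float,
                   t1: float) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_spike_trains(config: MeaSimConfig, seed_seq: np.random.SeedSequence,
                          duration_s: float | None = None) -> MeaGroundTruth:
    """Draw ground-truth spike trains for one well (no voltage synthesis)."""
    config.validate()
    rng = np.random.default_rng(seed_seq)
    dur = config.duration_s if duration_s is None else duration_s
    n = config.n_electrodes

    n_net = int(math.ceil(config.network_participation * n - 1e-9))
    network_electrodes = rng.permutation(n)[:n_net]
    # event onsets snap to the analysis grid: an epoch straddling two fixed
    # 100 ms bins splits its spikes and would evade the per-bin count rule
    win = config.network_event_duration_s
    n_slots = max(int(dur / win), 1) if win > 0 else 1
    n_events = min(rng.poisson(config.network_event_rate_per_min / 60.0 * dur),
                   n_slots)
    slots = rng.choice(n_slots, size=n_events, replace=False)
    network_times = np.sort(slots * win)

    trains: list[np.ndarray] = []
    burst_intervals: list[list[tuple[float, float]]] = []
    for e in range(n):
        t = _poisson_times(rng, config.background_rate_hz, 0.0, dur)
        onsets = _poisson_times(rng, config.burst_rate_hz, 0.0,
                                max(dur - config.burst_duration_s, 0.0))
        intervals = [(o, o + config.burst_duration_s) for o in onsets]
        for o, c in intervals:
            t = np.concatenate([t, _poisson_times(rng, config.intra_burst_rate_hz, o, c)])
        if e in network_electrodes:
            for o in network_times:
                t = np.concatenate([
                    t, _poisson_times(rng, config.network_intra_rate_hz, o,
                                      o + config.network_event_duration_s)])
        trains.append(np.unique(t))
        burst_intervals.append(intervals)
    return MeaGroundTruth(trains, burst_intervals, network_times,
                          np.sort(network_electrodes), dur)


def synthesize_voltage(truth: MeaGroundTruth, config: MeaSimConfig,
                       seed_seq: np.random.SeedSequence) -> VoltageRecording:
    """Render ground-truth spike trains into a noisy voltage matrix."""
    rng = np.random.default_rng(seed_seq)
    fs = config.sampling_rate_hz
    n_samples = int(round(truth.duration_s * fs))
    w = spike_template(fs) * (config.spike_amplitude_uv / filtered_template_peak(fs))
    half = w.size // 2
    if config.noise_sd_uv > 0:
        voltage = rng.normal(0.0, config.noise_sd_uv,
                             size=(config.n_electrodes, n_samples))
    else:
        voltage = np.zeros((config.n_electrodes, n_samples))
    for e, train in enumerate(truth.spike_times):
        for t in train:
            c = int(round(t * fs))
            lo, hi = c - half, c + half + 1
            wlo, whi = max(0, -lo), w.size - max(0, hi - n_samples)
            lo, hi = max(lo, 0), min(hi, n_samples)
            if lo < hi:
                voltage[e, lo:hi] += w[wlo:whi]
    return VoltageRecording(voltage, fs, electrode_map=np.zeros(config.n_electrodes,
                                                                dtype=int))


def simulate_mea_recording(config: SimConfig | MeaSimConfig,
                           ) -> tuple[VoltageRecording, MeaGroundTruth]:
    """Simulate one well's voltage recording with recorded ground truth."""
    if isinstance(config, SimConfig):
        seed, mea = config.seed, config.mea
    else:
        seed, mea = 0, config
    mea.validate()
    if mea.duration_s <= 0:
        raise InvalidConfigError("duration must be positive")
    spikes_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    truth = simulate_spike_trains(mea, spikes_ss)
    rec = synthesize_voltage(truth, mea, noise_ss)
    return rec, truth


def truth_to_spike_train_set(truth: MeaGroundTruth) -> SpikeTrainSet:
    """View the ground-truth spike times as a SpikeTrainSet for direct analysis."""
    return SpikeTrainSet([t.copy() for t in truth.spike_times], truth.duration_s)
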