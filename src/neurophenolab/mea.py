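"""Multi-electrode array analysis: voltage -> spikes -> bursts -> well metrics.

The chain mirrors the standard extracellular workflow for neuronal cultures
on 16-electrode wells:

1. zero-phase Butterworth band-pass (default 200-3000 Hz) per electrode;
2. robust per-electrode baseline noise SD;
3. spike detection at a strict ``+6.0 x SD`` positive threshold;
4. active electrodes: average of more than 5 spikes per minute;
5. single-electrode bursts: more than 5 spikes inside a fixed 100 ms bin;
6. network bursts: more than 50 spikes per 100 ms bin simultaneously on at
   least 35% of the well's electrodes (``ceil(0.35 * n)``);
7. well metrics as reported per well: active electrode count, mean firing
   rate per active electrode, burst count, bursting electrode count and
   network burst frequency per minute.

All threshold comparisons are strict (``>``), so an electrode averaging
exactly 5 spikes/min is *not* active and a bin holding exactly 50 spikes
does *not* participate in a network burst.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidParameterError

DEFAULT_LOW_HZ = 200.0
DEFAULT_HIGH_HZ = 3000.0
DEFAULT_FILTER_ORDER = 3
DEFAULT_THRESHOLD_SD = 6.0
DEFAULT_DEAD_TIME_MS = 1.0
DEFAULT_MIN_RATE_PER_MIN = 5.0
DEFAULT_BURST_WINDOW_MS = 100.0
DEFAULT_BURST_MIN_SPIKES = 5
DEFAULT_NET_MIN_SPIKES = 50
DEFAULT_PARTICIPATION = 0.35


# ---------------------------------------------------------------------------
# containers

@dataclass
class VoltageRecording:
    """Raw or filtered extracellular voltage, electrodes x samples, in uV."""

    voltage: np.ndarray
    rate_hz: float
    electrode_map: np.ndarray | None = None  # well id per electrode

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 2:
            raise InvalidParameterError("voltage must be 2-D (electrodes x samples)")
        if self.rate_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.voltage.shape[0]

    @property
    def duration_s(self) -> float:
        return self.voltage.shape[1] / self.rate_hz


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times in seconds over a common duration."""

    trains: list[np.ndarray]
    duration_s: float
    noise_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for t in self.trains:
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or
                           t[-1] > self.duration_s + 1e-9):
                raise InvalidParameterError(
                    "spike times must be strictly increasing within [0, duration]")

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def to_frame(self) -> pd.DataFrame:
        rows = [(e, t) for e, train in enumerate(self.trains) for t in train]
        return pd.DataFrame(rows, columns=["electrode", "time_s"])


@dataclass
class BurstCallSet:
    """Single-electrode burst calls: fixed-bin windows with their counts."""

    bursts: dict[int, list[tuple[float, float, int]]]  # electrode -> (start, end, count)
    window_s: float
    duration_s: float

    @property
    def bursting_electrodes(self) -> set[int]:
        return {e for e, b in self.bursts.items() if b}

    @property
    def total_bursts(self) -> int:
        return sum(len(b) for b in self.bursts.values())


@dataclass
class NetworkBurstSet:
    """Well-level network bursts: bin windows with participating electrodes."""

    windows: list[tuple[float, float, frozenset[int]]]
    duration_s: float

    @property
    def count(self) -> int:
        return len(self.windows)

    @property
    def frequency_per_min(self) -> float:
        return self.count / (self.duration_s / 60.0)


@dataclass
class WellMetrics:
    """The five per-well summary metrics reported for culture activity."""

    active_electrodes: int
    mean_firing_rate_hz: float  # NaN when no electrode is active
    burst_count: int
    bursting_electrodes: int
    network_burst_freq_per_min: float
    duration_s: float = field(default=math.nan)

    def to_series(self) -> pd.Series:
        return pd.Series({
            "active_electrodes": self.active_electrodes,
            "mean_firing_rate_hz": self.mean_firing_rate_hz,
            "burst_count": self.burst_count,
            "bursting_electrodes": self.bursting_electrodes,
            "network_burst_freq_per_min": self.network_burst_freq_per_min,
        })


# ---------------------------------------------------------------------------
# filtering and noise estimation

def design_bandpass(rate_hz: float, low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Design the spike-band Butterworth filter (SOS form).

    The design magnitude response is -3 dB at both cutoffs.
    """
    nyq = rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidParameterError(
            f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=rate_hz, output="sos")


def bandpass_filter(rec: VoltageRecording, low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    order: int = DEFAULT_FILTER_ORDER) -> VoltageRecording:
    """Zero-phase band-pass each electrode (forward-backward application)."""
    sos = design_bandpass(rec.rate_hz, low_hz, high_hz, order)
    filtered = signal.sosfiltfilt(sos, rec.voltage, axis=1)
    return VoltageRecording(filtered, rec.rate_hz, rec.electrode_map)


def filter_magnitude_response(rate_hz: float, freqs_hz: np.ndarray,
                              low_hz: float = DEFAULT_LOW_HZ,
                              high_hz: float = DEFAULT_HIGH_HZ,
                              order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Single-pass magnitude response of the designed filter at ``freqs_hz``."""
    sos = design_bandpass(rate_hz, low_hz, high_hz, order)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=rate_hz)
    return np.abs(h)


def band_noise_factor(rate_hz: float, low_hz: float = DEFAULT_LOW_HZ,
                      high_hz: float = DEFAULT_HIGH_HZ,
                      order: int = DEFAULT_FILTER_ORDER, n: int = 8192) -> float:
    """SD ratio of white noise after the zero-phase band-pass.

    The forward-backward pass has magnitude ``|H|^2``, so the output variance
    of unit white noise is the mean of ``|H|^4`` over frequency.
    """
    freqs = np.linspace(0, rate_hz / 2, n)
    mag = filter_magnitude_response(rate_hz, freqs, low_hz, high_hz, order)
    return float(np.sqrt(np.trapezoid(mag ** 4, freqs) / (rate_hz / 2)))


def estimate_noise_sd(filtered: VoltageRecording, method: str = "mad",
                      baseline: tuple[float, float] | None = None) -> np.ndarray:
    """Per-electrode baseline noise SD of a filtered recording.

    ``mad`` (default): ``median(|v|) / 0.6745``, robust to spikes.
    ``sd``: plain SD, optionally over a caller-designated spike-free
    ``baseline`` interval in seconds.
    """
    v = filtered.voltage
    if method == "mad":
        centre = np.median(v, axis=1, keepdims=True)
        sd = np.median(np.abs(v - centre), axis=1) / 0.6745
    elif method == "sd":
        if baseline is not None:
            i0 = int(round(baseline[0] * filtered.rate_hz))
            i1 = int(round(baseline[1] * filtered.rate_hz))
            v = v[:, i0:i1]
        sd = np.std(v, axis=1)
    else:
        raise InvalidParameterError(f"unknown noise method: {method!r}")
    if np.any(sd == 0):
        warnings.warn("constant trace: noise SD estimated as 0", stacklevel=2)
    return sd


# ---------------------------------------------------------------------------
# spike detection

def detect_spikes(filtered: VoltageRecording, noise_sd: np.ndarray | float,
                  threshold_sd: float = DEFAULT_THRESHOLD_SD,
                  dead_time_ms: float = DEFAULT_DEAD_TIME_MS,
                  polarity: str = "positive") -> SpikeTrainSet:
    """Threshold-crossing spike detection on the filtered voltage.

    A spike is recorded at every local maximum whose peak strictly exceeds
    ``threshold_sd * noise_sd`` (default +6.0 x SD, positive deflections
    only); after each detection further crossings are suppressed for
    ``dead_time_ms``. Spike time = peak sample / sampling rate.
    ``polarity='both'`` additionally detects negative deflections below
    ``-threshold_sd * noise_sd``.
    """
    sd = np.broadcast_to(np.atleast_1d(np.asarray(noise_sd, dtype=float)),
                         (filtered.n_electrodes,))
    dead = max(1, int(round(dead_time_ms * 1e-3 * filtered.rate_hz)))
    trains: list[np.ndarray] = []
    for e in range(filtered.n_electrodes):
        v = filtered.voltage[e]
        thr = threshold_sd * sd[e]
        peaks = _strict_peaks(v, thr)
        if polarity == "both":
            peaks = np.union1d(peaks, _strict_peaks(-v, thr))
        elif polarity != "positive":
            raise InvalidParameterError("polarity must be 'positive' or 'both'")
        kept: list[int] = []
        last = -dead - 1
        for p in peaks:                      # greedy in time order
            if p - last >= dead:
                kept.append(p)
                last = p
        trains.append(np.asarray(kept, dtype=float) / filtered.rate_hz)
    return SpikeTrainSet(trains, filtered.duration_s, noise_sd=np.asarray(sd))


def _strict_peaks(v: np.ndarray, thr: float) -> np.ndarray:
    """Indices of local maxima with value strictly above ``thr``."""
    peaks, _ = signal.find_peaks(v, height=np.nextafter(thr, np.inf))
    return peaks


# ---------------------------------------------------------------------------
# activity, bursts, network bursts

def classify_active_electrodes(spikes: SpikeTrainSet,
                               min_rate_per_min: float = DEFAULT_MIN_RATE_PER_MIN,
                               ) -> set[int]:
    """Electrodes averaging strictly more than ``min_rate_per_min`` spikes/min."""
    if spikes.duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    minutes = spikes.duration_s / 60.0
    return {e for e, t in enumerate(spikes.trains)
            if t.size / minutes > min_rate_per_min}


def mean_firing_rate(spikes: SpikeTrainSet, active_set: set[int] | None = None,
                     ) -> float:
    """Mean firing rate per active electrode, spikes/s (NaN if none active)."""
    if active_set is None:
        active_set = classify_active_electrodes(spikes)
    if not active_set:
        return math.nan
    rates = [spikes.trains[e].size / spikes.duration_s for e in sorted(active_set)]
    return float(np.mean(rates))


def _bin_counts(spikes: SpikeTrainSet, window_s: float) -> np.ndarray:
    """Spike counts per electrode in fixed non-overlapping windows.

    The recording is tiled from t=0; a trailing partial window is dropped.
    """
    n_bins = int(np.floor(spikes.duration_s / window_s + 1e-9))
    edges = np.arange(n_bins + 1) * window_s
    counts = np.zeros((spikes.n_electrodes, n_bins), dtype=int)
    for e, t in enumerate(spikes.trains):
        if t.size:
            counts[e], _ = np.histogram(t, bins=edges)
    return counts


def detect_bursts(spikes: SpikeTrainSet, window_ms: float = DEFAULT_BURST_WINDOW_MS,
                  min_spikes: int = DEFAULT_BURST_MIN_SPIKES) -> BurstCallSet:
    """Single-electrode bursts: fixed 100 ms bins holding more than
    ``min_spikes`` spikes; each qualifying bin is one burst (count
    semantics — adjacent qualifying bins are separate bursts)."""
    window_s = window_ms * 1e-3
    counts = _bin_counts(spikes, window_s)
    bursts: dict[int, list[tuple[float, float, int]]] = {}
    for e in range(spikes.n_electrodes):
        idx = np.nonzero(counts[e] > min_spikes)[0]
        bursts[e] = [(i * window_s, (i + 1) * window_s, int(counts[e, i]))
                     for i in idx]
    return BurstCallSet(bursts, window_s, spikes.duration_s)


def participation_threshold(n_electrodes: int,
                            fraction: float = DEFAULT_PARTICIPATION) -> int:
    """Minimum participating electrodes: ``ceil(fraction * n)``, guarded
    against floating-point excess (0.35 * 100 must give 35, not 36)."""
    return int(math.ceil(fraction * n_electrodes - 1e-9))


def detect_network_bursts(spikes: SpikeTrainSet,
                          window_ms: float = DEFAULT_BURST_WINDOW_MS,
                          min_spikes_net: int = DEFAULT_NET_MIN_SPIKES,
                          participation_fraction: float = DEFAULT_PARTICIPATION,
                          ) -> NetworkBurstSet:
    """Network bursts: 100 ms bins where at least ``ceil(fraction * n)``
    electrodes each hold strictly more than ``min_spikes_net`` spikes."""
    window_s = window_ms * 1e-3
    counts = _bin_counts(spikes, window_s)
    participating = counts > min_spikes_net
    need = participation_threshold(spikes.n_electrodes, participation_fraction)
    windows: list[tuple[float, float, frozenset[int]]] = []
    for i in np.nonzero(participating.sum(axis=0) >= need)[0]:
        members = frozenset(int(e) for e in np.nonzero(participating[:, i])[0])
        windows.append((i * window_s, (i + 1) * window_s, members))
    return NetworkBurstSet(windows, spikes.duration_s)


def compute_well_metrics(spikes: SpikeTrainSet, bursts: BurstCallSet,
                         net_bursts: NetworkBurstSet,
                         min_rate_per_min: float = DEFAULT_MIN_RATE_PER_MIN,
                         ) -> WellMetrics:
    """Assemble the five per-well activity metrics from one well's calls."""
    for d in (bursts.duration_s, net_bursts.duration_s):
        if abs(d - spikes.duration_s) > 1e-6:
            raise InvalidParameterError("inputs span different durations")
    active = classify_active_electrodes(spikes, min_rate_per_min)
    return WellMetrics(
        active_electrodes=len(active),
        mean_firing_rate_hz=mean_firing_rate(spikes, active),
        burst_count=bursts.total_bursts,
        bursting_electrodes=len(bursts.bursting_electrodes),
        network_burst_freq_per_min=net_bursts.frequency_per_min,
        duration_s=spikes.duration_s,
    )


# ---------------------------------------------------------------------------
# export

def export_raster(spikes: SpikeTrainSet, bursts: BurstCallSet | None,
                  net_bursts: NetworkBurstSet | None, path: str,
                  csv_path: str | None = None) -> pd.DataFrame:
    """Write a raster figure (PNG/SVG by extension) and a tidy spike CSV.

    The CSV holds one row per spike: electrode, time and whether the spike
    falls inside a single-electrode burst or a network-burst window.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = []
    for e, train in enumerate(spikes.trains):
        bwins = bursts.bursts.get(e, []) if bursts else []
        nwins = net_bursts.windows if net_bursts else []
        for t in train:
            in_b = any(s <= t < x for s, x, _ in bwins)
            in_n = any(s <= t < x for s, x, _ in nwins)
            rows.append((e, t, in_b, in_n))
    table = pd.DataFrame(rows, columns=["electrode", "time_s", "in_burst",
                                        "in_network_burst"])
    fig, ax = plt.subplots(figsize=(10, 4))
    for e, train in enumerate(spikes.trains):
        ax.vlines(train, e + 0.6, e + 1.4, color="black", lw=0.5)
    if bursts:
        for e, wins in bursts.bursts.items():
            for s, x, _ in wins:
                ax.hlines(e + 0.5, s, x, color="tab:blue", lw=2)
    if net_bursts:
        for s, x, _ in net_bursts.windows:
            ax.axvspan(s, x, color="magenta", alpha=0.2)
    ax.set_xlim(0, spikes.duration_s)
    ax.set_ylim(0.5, spikes.n_electrodes + 0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    table.to_csv(csv_path or str(path).rsplit(".", 1)[0] + ".csv", index=False)
    return table
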