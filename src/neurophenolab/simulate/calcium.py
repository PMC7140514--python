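"""Synthetic fluorescence ROI traces for calcium-transient analysis.

Each ROI trace is ``F0 + amplitude * (events (x) kernel) - bleach + noise``
sampled on the frame grid. The kernel is a double exponential (rise and
decay time constants) normalised to unit peak, so ``event_amplitude`` is the
raw-intensity peak an isolated event adds. Photobleaching is linear by
default (matching a first-minus-last-frame correction); an exponential mode
exists for robustness tests. A configurable subset of the active ROIs shares
one common event train, which gives the synchrony analysis a positive
control with known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import CalciumSimConfig, SimConfig
from ..calcium import RoiTraceSet


@dataclass
class CalciumGroundTruth:
    event_times: list[np.ndarray]      # per ROI, s
    active: np.ndarray                 # bool per ROI (has events)
    shared: np.ndarray                 # bool per ROI (uses the common train)
    bleach_slope: np.ndarray           # per ROI, a.u./frame
    mcherry_positive: np.ndarray       # bool per ROI
    kernel_peak: float                 # raw-intensity peak of one event
    f0: float
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "event_times": [t.tolist() for t in self.event_times],
            "active": self.active.tolist(),
            "shared": self.shared.tolist(),
            "bleach_slope": self.bleach_slope.tolist(),
            "mcherry_positive": self.mcherry_positive.tolist(),
            "kernel_peak": self.kernel_peak,
            "f0": self.f0,
        }


def transient_kernel(frame_interval_s: float, n_frames: int, rise_s: float,
                     decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential transient sampled on the frame grid."""
    t = np.arange(n_frames) * frame_interval_s
    if rise_s <= 0:
        k = np.exp(-t / decay_s)
    else:
        k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_calcium_traces(config: SimConfig | CalciumSimConfig,
                            ) -> tuple[RoiTraceSet, CalciumGroundTruth]:
    """Simulate a plate-field's ROI traces with recorded ground truth."""
    if isinstance(config, SimConfig):
        seed, cfg = config.seed, config.calcium
    else:
        seed, cfg = 0, config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    n, nf = cfg.n_rois, cfg.n_frames
    dt = cfg.frame_interval_s
    duration = nf * dt
    kernel = transient_kernel(dt, nf, cfg.kernel_rise_s, cfg.kernel_decay_s)

    n_active = int(round(cfg.active_fraction * n))
    active = np.zeros(n, dtype=bool)
    active[rng.permutation(n)[:n_active]] = True
    shared = np.zeros(n, dtype=bool)
    active_idx = np.nonzero(active)[0]
    n_shared = int(round(cfg.shared_fraction * active_idx.size))
    shared[active_idx[:n_shared]] = True

    shared_n = rng.poisson(cfg.event_rate_hz * duration)
    shared_train = np.sort(rng.uniform(0, duration, size=shared_n))

    mcherry = np.zeros(n, dtype=bool)
    n_mch = int(round(cfg.mcherry_positive_fraction * n))
    mcherry[rng.permutation(n)[:n_mch]] = True

    traces = np.zeros((n, nf))
    event_times: list[np.ndarray] = []
    frames = np.arange(nf, dtype=float)
    for r in range(n):
        if not active[r]:
            ev = np.array([])
        elif shared[r]:
            ev = shared_train
        else:
            k = rng.poisson(cfg.event_rate_hz * duration)
            ev = np.sort(rng.uniform(0, duration, size=k))
        event_times.append(ev)
        f = np.full(nf, float(cfg.f0))
        for t0 in ev:
            i0 = int(np.ceil(t0 / dt))
            if i0 < nf:
                # kernel evaluated from the event onset on the frame grid
                tail = transient_kernel(dt, nf - i0, cfg.kernel_rise_s,
                                        cfg.kernel_decay_s)
                f[i0:] += cfg.event_amplitude * tail
        if cfg.bleach_mode == "linear":
            f -= cfg.bleach_slope_per_frame * frames
        else:
            f *= np.exp(-cfg.bleach_slope_per_frame / max(cfg.f0, 1.0) * frames)
        if cfg.noise_sd > 0:
            f += rng.normal(0.0, cfg.noise_sd, size=nf)
        traces[r] = f

    truth = CalciumGroundTruth(
        event_times=event_times, active=active, shared=shared,
        bleach_slope=np.full(n, cfg.bleach_slope_per_frame),
        mcherry_positive=mcherry, kernel_peak=cfg.event_amplitude, f0=cfg.f0)
    data = RoiTraceSet(traces=traces, frame_interval_s=dt,
                       roi_ids=[f"roi{r:03d}" for r in range(n)],
                       mcherry_positive=mcherry.copy())
    return data, truth
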