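"""Calcium-transient analysis on ROI fluorescence traces.

Pipeline: photobleach correction -> dF/F normalisation -> per-ROI dFmax ->
calcium-spike-positive classification (dFmax strictly above 0.01 by
default), plus the mCherry-positive fraction over Hoechst-traced nuclei and
a pairwise-correlation synchrony index.

Two readings are implemented where the processing recipe is ambiguous:

* bleach correction: ``ramp`` (default) removes the straight line through
  the first and last frames, anchored so frame 0 is unchanged; ``constant``
  literally subtracts the constant (first - last) from every frame;
* dFmax: ``range`` (default) is ``max(dF/F) - min(dF/F)``; ``max`` is the
  maximum alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

DEFAULT_SPIKE_THRESHOLD = 0.01


@dataclass
class RoiTraceSet:
    """Per-ROI raw fluorescence series F(t) on a common frame grid."""

    traces: np.ndarray                     # (n_rois, n_frames), a.u.
    frame_interval_s: float
    roi_ids: list[str] | None = None
    mcherry_positive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] < 2:
            raise InvalidParameterError("at least 2 frames required")
        if self.frame_interval_s <= 0:
            raise InvalidParameterError("frame interval must be positive")
        if self.roi_ids is None:
            self.roi_ids = [f"roi{r:03d}" for r in range(self.traces.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n_r, n_f = self.traces.shape
        return pd.DataFrame({
            "roi": np.repeat(self.roi_ids, n_f),
            "frame": np.tile(np.arange(n_f), n_r),
            "F": self.traces.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_interval_s: float) -> "RoiTraceSet":
        wide = df.pivot(index="roi", columns="frame", values="F").sort_index()
        return cls(wide.to_numpy(), frame_interval_s, roi_ids=list(wide.index))


@dataclass
class DffTraceSet:
    """Normalised dF/F traces with per-ROI F0, dFmax and activity flags."""

    dff: np.ndarray
    f0: np.ndarray
    frame_interval_s: float
    roi_ids: list[str]
    valid: np.ndarray                      # False where F0 <= 0
    dfmax: np.ndarray | None = None
    spike_positive: np.ndarray | None = None
    mcherry_positive: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": self.roi_ids, "F0": self.f0, "valid": self.valid,
            "dfmax": self.dfmax if self.dfmax is not None else np.nan,
            "spike_positive": (self.spike_positive
                               if self.spike_positive is not None else pd.NA),
        })


def bleach_correct(traces: RoiTraceSet, mode: str = "ramp") -> RoiTraceSet:
    """Correct photobleaching from the first-to-last frame intensity drop.

    ``ramp``: the line through (0, F(0)) and (N, F(N)) is subtracted and
    F(0) re-added, so a pure linear decay becomes constant at F(0).
    ``constant``: the scalar F(0) - F(N) is subtracted from every frame.
    """
    f = traces.traces
    n = f.shape[1] - 1
    drop = f[:, 0] - f[:, -1]              # positive when bleaching
    if mode == "ramp":
        t = np.arange(n + 1) / n
        corrected = f + drop[:, None] * t[None, :]
    elif mode == "constant":
        corrected = f - drop[:, None]
    else:
        raise InvalidParameterError("mode must be 'ramp' or 'constant'")
    return RoiTraceSet(corrected, traces.frame_interval_s,
                       roi_ids=list(traces.roi_ids),
                       mcherry_positive=traces.mcherry_positive)


def compute_dff(traces: RoiTraceSet) -> DffTraceSet:
    """dF/F = (F - F0)/F0 with F0 the frame-0 fluorescence of each ROI.

    ROIs with F0 <= 0 are flagged invalid and excluded from summaries.
    """
    f0 = traces.traces[:, 0].copy()
    valid = f0 > 0
    safe = np.where(valid, f0, 1.0)
    dff = (traces.traces - f0[:, None]) / safe[:, None]
    dff[~valid] = np.nan
    return DffTraceSet(dff=dff, f0=f0, frame_interval_s=traces.frame_interval_s,
                       roi_ids=list(traces.roi_ids), valid=valid,
                       mcherry_positive=traces.mcherry_positive)


def compute_dfmax(dff: DffTraceSet, mode: str = "range") -> np.ndarray:
    """Per-ROI dFmax: the largest excursion of the dF/F series.

    ``range`` (default): max - min over the recording; ``max``: max only.
    Stores the result on the input set and returns it.
    """
    vals = np.full(dff.dff.shape[0], np.nan)
    if mode == "range":
        if dff.valid.any():
            vals[dff.valid] = (dff.dff[dff.valid].max(axis=1) -
                               dff.dff[dff.valid].min(axis=1))
    elif mode == "max":
        if dff.valid.any():
            vals[dff.valid] = dff.dff[dff.valid].max(axis=1)
    else:
        raise InvalidParameterError("mode must be 'range' or 'max'")
    dff.dfmax = vals
    return vals


def classify_spike_positive(dff: DffTraceSet,
                            threshold: float = DEFAULT_SPIKE_THRESHOLD,
                            dfmax_mode: str = "range",
                            ) -> tuple[np.ndarray, float]:
    """Flag ROIs with dFmax strictly above ``threshold`` (default 0.01).

    Returns (per-ROI flags, fraction of positives among valid ROIs);
    the fraction is NaN when no ROI is valid.
    """
    dfmax = dff.dfmax if dff.dfmax is not None else compute_dfmax(dff, dfmax_mode)
    flags = (dfmax > threshold) & dff.valid
    dff.spike_positive = flags
    n_valid = int(dff.valid.sum())
    fraction = flags.sum() / n_valid if n_valid else math.nan
    return flags, float(fraction)


def mcherry_positive_fraction(stack, nuclei, sd_factor: float = 3.0) -> float:
    """Fraction of Hoechst-traced nuclei that are mCherry-positive.

    A nucleus is positive when its mean mCherry intensity exceeds
    background mean + ``sd_factor`` x background SD (background = pixels
    outside all nuclei). NaN when the nucleus set is empty.
    """
    from .imaging import channel_lookup  # local import to avoid a cycle

    mch = channel_lookup(stack, "mcherry")
    labels = nuclei.labels
    if nuclei.table.empty:
        return math.nan
    bg = mch[labels == 0]
    thr = bg.mean() + sd_factor * bg.std()
    pos = 0
    for lab in nuclei.table["label"]:
        if mch[labels == lab].mean() > thr:
            pos += 1
    return pos / len(nuclei.table)


def synchrony_index(dff: DffTraceSet,
                    threshold: float = DEFAULT_SPIKE_THRESHOLD) -> float:
    """Mean pairwise Pearson correlation of dF/F among spike-positive ROIs,
    clipped to [0, 1]; NaN with fewer than 2 active ROIs."""
    if dff.spike_positive is None:
        classify_spike_positive(dff, threshold)
    idx = np.nonzero(dff.spike_positive)[0]
    if idx.size < 2:
        return math.nan
    x = dff.dff[idx]
    sd = x.std(axis=1)
    keep = sd > 0
    if keep.sum() < 2:
        return math.nan
    c = np.corrcoef(x[keep])
    upper = c[np.triu_indices_from(c, k=1)]
    return float(np.clip(np.mean(upper), 0.0, 1.0))


@dataclass
class CalciumSummary:
    """Field-level summary of the calcium analysis."""

    spike_positive_fraction: float
    mcherry_positive_fraction: float = math.nan
    mean_dfmax: float = math.nan
    synchrony: float = math.nan
    n_valid_rois: int = 0
    extras: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series({
            "spike_positive_fraction": self.spike_positive_fraction,
            "mcherry_positive_fraction": self.mcherry_positive_fraction,
            "mean_dfmax": self.mean_dfmax,
            "synchrony": self.synchrony,
            "n_valid_rois": self.n_valid_rois,
        })


def analyze_traces(traces: RoiTraceSet, bleach_mode: str = "ramp",
                   dfmax_mode: str = "range",
                   threshold: float = DEFAULT_SPIKE_THRESHOLD,
                   ) -> tuple[DffTraceSet, CalciumSummary]:
    """Full trace pipeline: bleach-correct, dF/F, dFmax, classification."""
    corrected = bleach_correct(traces, mode=bleach_mode)
    dff = compute_dff(corrected)
    compute_dfmax(dff, mode=dfmax_mode)
    _, fraction = classify_spike_positive(dff, threshold, dfmax_mode)
    valid_dfmax = dff.dfmax[dff.valid]
    summary = CalciumSummary(
        spike_positive_fraction=fraction,
        mean_dfmax=float(np.mean(valid_dfmax)) if valid_dfmax.size else math.nan,
        synchrony=synchrony_index(dff, threshold),
        n_valid_rois=int(dff.valid.sum()),
    )
    return dff, summary
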