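"""File-format adapters: HDF5 voltage, CSV tables, TIFF stacks, JSON truth.

Layouts
-------
HDF5 voltage: datasets ``/voltage`` (electrodes x samples, uV), ``/rate_hz``
(scalar) and ``/electrode_map`` (well id per electrode).
Spike CSV: columns electrode, time_s (long format).
Trace CSV: columns roi, frame, F (long format).
OCR CSV: columns well, time_min, ocr, phase and optionally cells.
TIFF: one page per channel; pixel size carried in the ImageDescription JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .calcium import RoiTraceSet
from .flux import OcrProfile
from .imaging import ChannelStack
from .mea import SpikeTrainSet, VoltageRecording


def write_voltage_h5(rec: VoltageRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("voltage", data=rec.voltage, compression="gzip")
        fh.create_dataset("rate_hz", data=float(rec.rate_hz))
        emap = (rec.electrode_map if rec.electrode_map is not None
                else np.zeros(rec.n_electrodes, dtype=int))
        fh.create_dataset("electrode_map", data=emap)


def read_voltage_h5(path: str | Path) -> VoltageRecording:
    with h5py.File(path, "r") as fh:
        return VoltageRecording(fh["voltage"][()], float(fh["rate_hz"][()]),
                                electrode_map=fh["electrode_map"][()])


def write_spikes_csv(spikes: SpikeTrainSet, path: str | Path) -> None:
    spikes.to_frame().to_csv(path, index=False)


def read_spikes_csv(path: str | Path, duration_s: float,
                    n_electrodes: int | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path)
    n = n_electrodes or (int(df["electrode"].max()) + 1 if len(df) else 0)
    trains = [np.sort(df.loc[df["electrode"] == e, "time_s"].to_numpy())
              for e in range(n)]
    return SpikeTrainSet(trains, duration_s)


def write_traces_csv(traces: RoiTraceSet, path: str | Path) -> None:
    traces.to_frame().to_csv(path, index=False)


def read_traces_csv(path: str | Path, frame_interval_s: float) -> RoiTraceSet:
    return RoiTraceSet.from_frame(pd.read_csv(path), frame_interval_s)


def write_stack_tiff(stack: ChannelStack, path: str | Path) -> None:
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    desc = json.dumps({"channels": names, "pixel_size_um": stack.pixel_size_um})
    tifffile.imwrite(path, data, description=desc)


def read_stack_tiff(path: str | Path, channels: list[str] | None = None,
                    pixel_size_um: float | None = None) -> ChannelStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    try:
        meta = json.loads(desc)
    except (TypeError, ValueError):
        pass
    names = channels or meta.get("channels")
    px = pixel_size_um or meta.get("pixel_size_um")
    if names is None or px is None:
        raise ValueError("TIFF lacks channel/pixel-size metadata; pass "
                         "channels= and pixel_size_um=")
    data = np.atleast_3d(data)
    if data.shape[0] != len(names):
        raise ValueError(f"TIFF has {data.shape[0]} pages for {len(names)} "
                         "channel names")
    return ChannelStack(dict(zip(names, data)), float(px))


def write_ocr_csv(profiles: list[OcrProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        df = p.table.copy()
        df.insert(0, "well", p.well)
        if p.hoechst_cells is not None:
            df["cells"] = p.hoechst_cells
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ocr_csv(path: str | Path) -> list[OcrProfile]:
    df = pd.read_csv(path)
    if "well" not in df.columns:
        df["well"] = "well"
    out = []
    for well, sub in df.groupby("well", sort=False):
        cells = int(sub["cells"].iloc[0]) if "cells" in sub.columns else None
        out.append(OcrProfile(sub[["time_min", "ocr", "phase"]]
                              .reset_index(drop=True),
                              hoechst_cells=cells, well=str(well)))
    return out


def validate_formats(paths: list[str | Path]) -> list[str]:
    """Schema diagnostics for input files; empty list means all valid."""
    diags: list[str] = []
    for p in map(Path, paths):
        if not p.exists():
            diags.append(f"{p}: file not found")
            continue
        suffix = p.suffix.lower()
        if suffix == ".csv":
            try:
                df = pd.read_csv(p, nrows=50)
            except Exception as exc:  # malformed file
                diags.append(f"{p}: unreadable CSV ({exc})")
                continue
            cols = set(df.columns)
            known = [{"electrode", "time_s"}, {"roi", "frame", "F"},
                     {"time_min", "ocr", "phase"},
                     {"gene", "condition", "ct"},
                     {"ab40_pg_ml", "ab42_pg_ml", "protein_ug"},
                     {"group", "value"}]
            if not any(k <= cols for k in known):
                expected = " | ".join(",".join(sorted(k)) for k in known)
                diags.append(f"{p}: columns {sorted(cols)} match no known "
                             f"schema (expected one of: {expected})")
            elif {"time_min", "ocr"} <= cols and "phase" not in cols:
                diags.append(f"{p}: OCR table missing 'phase' column")
        elif suffix in (".tif", ".tiff"):
            try:
                with tifffile.TiffFile(p) as tf:
                    desc = tf.pages[0].description
                meta = json.loads(desc) if desc else {}
            except Exception as exc:
                diags.append(f"{p}: unreadable TIFF ({exc})")
                continue
            if "pixel_size_um" not in meta:
                diags.append(f"{p}: TIFF lacks pixel-size metadata; "
                             "--pixel-size will be required")
        elif suffix in (".h5", ".hdf5"):
            try:
                with h5py.File(p, "r") as fh:
                    missing = {"voltage", "rate_hz", "electrode_map"} - set(fh)
            except Exception as exc:
                diags.append(f"{p}: unreadable HDF5 ({exc})")
                continue
            if missing:
                diags.append(f"{p}: HDF5 missing datasets {sorted(missing)}")
    return diags
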