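"""Synthetic microscopy fields with per-cell ground truth.

Renders a Hoechst channel of elliptical nuclei (healthy nuclei above the
tracing cutoff; pyknotic nuclei smaller *and* brighter by a configured
factor), marker channels (Tubb3/MAP2/NeuN/CellROX/mCherry soma discs only in
cells labelled positive), Tubb3-positive neurite polylines of known total
length, and synaptic punctum discs placed on or off the neurites. The ground
truth carries the per-cell label table, the exact polyline length and the
drawn punctum areas, so every downstream image metric has a known target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse, disk as draw_disk, line as draw_line
from skimage.morphology import dilation, disk as disk_se

from ..config import ImagingSimConfig, SimConfig
from ..imaging import ChannelStack


@dataclass
class ImagingGroundTruth:
    cells: pd.DataFrame              # centroid, area_um2, pyknotic + marker labels
    neurite_length_um: float
    puncta: dict                     # channel -> {drawn_area_um2, on_tubb3_area_um2}
    pixel_size_um: float
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "cells": self.cells.to_dict(orient="list"),
            "neurite_length_um": self.neurite_length_um,
            "puncta": self.puncta,
            "pixel_size_um": self.pixel_size_um,
        }


def _place_cells(rng: np.random.Generator, cfg: ImagingSimConfig,
                 radii: np.ndarray) -> np.ndarray:
    """Rejection-sample non-overlapping centres; warn, then fail loudly."""
    n = len(radii)
    centres = np.zeros((n, 2))
    margin = radii * cfg.soma_radius_factor + 2
    warned = False
    for i in range(n):
        placed = False
        for attempt in range(cfg.max_placement_attempts):
            c = rng.uniform(margin[i], cfg.field_px - margin[i], size=2)
            d = np.hypot(*(centres[:i] - c).T) if i else np.array([])
            min_d = (radii[:i] * cfg.soma_radius_factor +
                     radii[i] * cfg.soma_radius_factor + cfg.min_separation_px)
            if i == 0 or np.all(d > min_d):
                centres[i] = c
                placed = True
                break
            if attempt == cfg.max_placement_attempts // 2 and not warned:
                warnings.warn("cell placement is crowded; retrying",
                              stacklevel=2)
                warned = True
        if not placed:
            raise RuntimeError(
                f"could not place cell {i} without overlap after "
                f"{cfg.max_placement_attempts} attempts; lower n_cells or "
                f"enlarge the field")
    return centres


def _draw_polyline(rng: np.random.Generator, cfg: ImagingSimConfig,
                   mask: np.ndarray, occupied: np.ndarray,
                   ) -> tuple[float, list[tuple[int, int]]]:
    """Draw one neurite polyline avoiding occupied (soma) territory.

    Returns (length in um, centreline pixels). Avoidance keeps the drawn
    skeleton length equal to the recorded polyline length: a process
    crossing a soma would be absorbed into the cell-body mask downstream.
    """
    size = cfg.field_px
    margin = int(cfg.neurite_length_um / cfg.pixel_size_um / 6) + 10
    length_px = cfg.neurite_length_um / cfg.pixel_size_um
    n_seg = 4
    seg = length_px / n_seg
    pad = cfg.neurite_width_px // 2 + 1
    for _ in range(200):   # restart until every segment finds clear ground
        start = rng.uniform(margin, size - margin, size=2)
        if occupied[int(start[0]), int(start[1])]:
            continue
        heading = rng.uniform(0, 2 * math.pi)
        pos = start.copy()
        total_px = 0.0
        pixels: list[tuple[int, int]] = []
        own = np.zeros_like(occupied)   # this polyline's dilated band
        ok = True
        for _ in range(n_seg):
            placed = False
            for _ in range(40):  # re-aim to stay in bounds and off somas
                end = pos + seg * np.array([math.sin(heading), math.cos(heading)])
                if np.all(end > pad + 1) and np.all(end < size - pad - 2):
                    rr, cc = draw_line(int(round(pos[0])), int(round(pos[1])),
                                       int(round(end[0])), int(round(end[1])))
                    # the joint itself sits inside the previous segment's
                    # band; only the rest must keep clear (no doubling back)
                    skip = 3 * pad
                    if (not occupied[rr, cc].any()
                            and not own[rr[skip:], cc[skip:]].any()):
                        placed = True
                        break
                heading = rng.uniform(0, 2 * math.pi)
            if not placed:
                ok = False
                break
            pixels.extend(zip(rr.tolist(), cc.tolist()))
            total_px += math.hypot(round(end[0]) - round(pos[0]),
                                   round(end[1]) - round(pos[1]))
            r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad + 1, size)
            c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad + 1, size)
            patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            patch[rr - r0, cc - c0] = True
            own[r0:r1, c0:c1] |= dilation(patch, disk_se(pad + 1))
            pos = end
            heading += rng.uniform(-0.4, 0.4)
        if ok:
            for r, c in pixels:
                mask[r, c] = True
            return total_px * cfg.pixel_size_um, pixels
    raise RuntimeError("could not route a neurite clear of somata; "
                       "lower n_cells or n_neurites")


def render_synthetic_field(config: SimConfig | ImagingSimConfig,
                           ) -> tuple[ChannelStack, ImagingGroundTruth]:
    """Render one multichannel field with recorded per-cell ground truth."""
    if isinstance(config, SimConfig):
        seed, cfg = config.seed, config.imaging
    else:
        seed, cfg = 0, config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    size = cfg.field_px
    px = cfg.pixel_size_um

    n = cfg.n_cells
    pyknotic = rng.random(n) < cfg.pyknotic_fraction
    areas_um2 = np.where(
        pyknotic,
        np.maximum(rng.normal(cfg.pyknotic_area_um2, cfg.pyknotic_area_um2 * 0.15, n), 5.0),
        np.maximum(rng.normal(cfg.nucleus_area_um2_mean, cfg.nucleus_area_um2_sd, n), 55.0),
    )
    radii_px = np.sqrt(areas_um2 / math.pi) / px
    centres = _place_cells(rng, cfg, radii_px)

    healthy = ~pyknotic
    tubb3 = healthy & (rng.random(n) < cfg.tubb3_fraction)
    map2 = tubb3 & (rng.random(n) < cfg.map2_fraction)
    neun = tubb3 & (rng.random(n) < cfg.neun_fraction)
    cellrox = (tubb3 & (rng.random(n) < cfg.cellrox_fraction)) | \
              (healthy & ~tubb3 & (rng.random(n) < cfg.cellrox_tubb3_negative_fraction))
    mcherry = healthy & (rng.random(n) < cfg.mcherry_fraction)

    channels = {name: np.zeros((size, size))
                for name in ("hoechst", "tubb3", "map2", "neun", "cellrox",
                             "mcherry", "syni", "psd95")}

    # nuclei
    for i in range(n):
        ratio = rng.uniform(0.7, 1.0)
        b = math.sqrt(areas_um2[i] / px / px / (math.pi * ratio))
        a = ratio * b
        rr, cc = draw_ellipse(centres[i, 0], centres[i, 1], a, b,
                              shape=(size, size),
                              rotation=rng.uniform(0, math.pi))
        level = cfg.nucleus_intensity * rng.uniform(0.95, 1.05)
        if pyknotic[i]:
            level *= cfg.pyknotic_brightness_factor
        channels["hoechst"][rr, cc] = level

    # soma discs per marker
    marker_flags = {"tubb3": tubb3, "map2": map2, "neun": neun,
                    "cellrox": cellrox, "mcherry": mcherry}
    for name, flags in marker_flags.items():
        for i in np.nonzero(flags)[0]:
            rr, cc = draw_disk(tuple(centres[i]),
                               radii_px[i] * cfg.soma_radius_factor,
                               shape=(size, size))
            channels[name][rr, cc] = cfg.marker_intensity * rng.uniform(0.95, 1.05)

    # neurites (Tubb3-positive processes), routed clear of every soma disc
    occupied = np.zeros((size, size), dtype=bool)
    halo = cfg.neurite_width_px // 2 + 2
    for i in range(n):
        rr, cc = draw_disk(tuple(centres[i]),
                           radii_px[i] * cfg.soma_radius_factor + halo,
                           shape=(size, size))
        occupied[rr, cc] = True
    neurite_line = np.zeros((size, size), dtype=bool)
    total_len = 0.0
    centreline: list[tuple[int, int]] = []
    for _ in range(cfg.n_neurites):
        length_um, pix = _draw_polyline(rng, cfg, neurite_line, occupied)
        total_len += length_um
        centreline.extend(pix)
        # processes also avoid each other: a crossing widens the band and
        # would be misread as a cell body downstream
        rows = np.array([p[0] for p in pix]); cols = np.array([p[1] for p in pix])
        r0, r1 = max(rows.min() - halo - 1, 0), min(rows.max() + halo + 2, size)
        c0, c1 = max(cols.min() - halo - 1, 0), min(cols.max() + halo + 2, size)
        patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        patch[rows - r0, cols - c0] = True
        occupied[r0:r1, c0:c1] |= dilation(patch, disk_se(halo))
    neurite_band = dilation(neurite_line, disk_se(cfg.neurite_width_px // 2))
    channels["tubb3"][neurite_band] = np.maximum(
        channels["tubb3"][neurite_band], cfg.neurite_intensity)

    # synaptic puncta
    tubb3_mask = channels["tubb3"] > 0
    puncta_truth: dict[str, dict[str, float]] = {}
    for name in ("syni", "psd95"):
        drawn = np.zeros((size, size), dtype=bool)
        n_on = int(round(cfg.puncta_per_channel * cfg.puncta_on_neurite_fraction))
        if centreline and n_on:
            idx = rng.integers(0, len(centreline), size=n_on)
            for j in idx:
                rr, cc = draw_disk(centreline[j], cfg.punctum_radius_px,
                                   shape=(size, size))
                drawn[rr, cc] = True
        n_off = cfg.puncta_per_channel - n_on
        if n_off:
            # the whole punctum disc must stay clear of the Tubb3 area
            clear = ~dilation(tubb3_mask, disk_se(cfg.punctum_radius_px + 1))
            for _ in range(n_off):
                for _ in range(100):
                    c = rng.integers(5, size - 5, size=2)
                    if clear[c[0], c[1]]:
                        break
                rr, cc = draw_disk(tuple(c), cfg.punctum_radius_px,
                                   shape=(size, size))
                drawn[rr, cc] = True
        channels[name][drawn] = cfg.marker_intensity
        puncta_truth[name] = {
            "drawn_area_um2": float(np.count_nonzero(drawn) * px * px),
            "on_tubb3_area_um2": float(np.count_nonzero(drawn & tubb3_mask) * px * px),
        }

    # background noise on every channel
    for name, img in channels.items():
        img += rng.normal(cfg.background_mean, cfg.background_sd, size=img.shape)
        np.clip(img, 0, None, out=img)

    cells = pd.DataFrame({
        "centroid_row": centres[:, 0], "centroid_col": centres[:, 1],
        "area_um2": areas_um2, "pyknotic": pyknotic, "tubb3": tubb3,
        "map2": map2, "neun": neun, "cellrox": cellrox, "mcherry": mcherry,
    })
    truth = ImagingGroundTruth(cells=cells, neurite_length_um=total_len,
                               puncta=puncta_truth, pixel_size_um=px)
    return ChannelStack(channels, px), truth
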