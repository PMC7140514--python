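"""Synthetic OCR step profiles across the mito-stress injection sequence."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import FluxSimConfig, SimConfig
from ..flux import OcrProfile, PHASES


@dataclass
class FluxGroundTruth:
    plateaus: dict                      # phase -> true plateau, pmol/min
    basal: float
    maximal: float
    spare: float
    hoechst_cells: int
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"plateaus": self.plateaus, "basal": self.basal,
                "maximal": self.maximal, "spare": self.spare,
                "hoechst_cells": self.hoechst_cells}


def simulate_ocr_profile(config: SimConfig | FluxSimConfig,
                         ) -> tuple[OcrProfile, FluxGroundTruth]:
    """Three noisy measurements per phase at each configured plateau."""
    if isinstance(config, SimConfig):
        seed, cfg = config.seed, config.flux
    else:
        seed, cfg = 0, config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    t = 0.0
    for phase, plateau in zip(PHASES, cfg.plateaus):
        for _ in range(cfg.n_per_phase):
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            rows.append((t, plateau + noise, phase))
            t += cfg.cycle_minutes
    table = pd.DataFrame(rows, columns=["time_min", "ocr", "phase"])
    base, _oligo, fccp, rot = cfg.plateaus
    basal = base - rot
    maximal = fccp - rot
    truth = FluxGroundTruth(
        plateaus=dict(zip(PHASES, cfg.plateaus)), basal=basal, maximal=maximal,
        spare=maximal / basal if basal > 0 else float("nan"),
        hoechst_cells=cfg.hoechst_cells)
    return OcrProfile(table, hoechst_cells=cfg.hoechst_cells), truth
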