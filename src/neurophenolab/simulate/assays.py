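"""Synthetic Ct and ELISA tables built from configured fold changes.

Ct values are constructed so the comparative-Ct identity
``fold = 2**(-ddCt)`` holds exactly before noise: the reference gene sits at
a fixed Ct in every sample and each target gene's Ct in a condition is the
reference-condition Ct minus log2(fold)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import AssaySimConfig, SimConfig
from ..assays import CtTable, ElisaTable


@dataclass
class AssayGroundTruth:
    fold_changes: dict                   # gene -> condition -> fold
    ab40_pg_ml: float
    ab42_pg_ml: float
    protein_ug: float
    ab42_40_ratio: float
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"fold_changes": self.fold_changes, "ab40_pg_ml": self.ab40_pg_ml,
                "ab42_pg_ml": self.ab42_pg_ml, "protein_ug": self.protein_ug,
                "ab42_40_ratio": self.ab42_40_ratio}


def simulate_assay_tables(config: SimConfig | AssaySimConfig,
                          ) -> tuple[CtTable, ElisaTable, AssayGroundTruth]:
    """Generate Ct and ELISA tables with exactly-known fold changes."""
    if isinstance(config, SimConfig):
        seed, cfg = config.seed, config.assays
    else:
        seed, cfg = 0, config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    folds = {g: {c: (1.0 if c == cfg.reference_condition else
                     cfg.fold_changes.get(g, {}).get(c, cfg.default_fold))
                 for c in cfg.conditions}
             for g in cfg.genes}

    rows = []
    for cond in cfg.conditions:
        for rep in range(cfg.n_replicates):
            noise = (rng.normal(0, cfg.ct_noise_sd)
                     if cfg.ct_noise_sd > 0 else 0.0)
            rows.append((cfg.reference_gene, cond, rep,
                         cfg.reference_ct + noise))
            for g in cfg.genes:
                ct = cfg.base_ct - math.log2(folds[g][cond])
                noise = (rng.normal(0, cfg.ct_noise_sd)
                         if cfg.ct_noise_sd > 0 else 0.0)
                rows.append((g, cond, rep, ct + noise))
    ct_table = CtTable(
        pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"]),
        reference_gene=cfg.reference_gene,
        reference_condition=cfg.reference_condition)

    erows = []
    for s in range(cfg.n_elisa_samples):
        e = (rng.normal(0, cfg.elisa_noise_sd, size=2)
             if cfg.elisa_noise_sd > 0 else np.zeros(2))
        erows.append((f"s{s:02d}", max(cfg.ab40_pg_ml + e[0], 0.0),
                      max(cfg.ab42_pg_ml + e[1], 0.0), cfg.protein_ug))
    elisa = ElisaTable(pd.DataFrame(
        erows, columns=["sample", "ab40_pg_ml", "ab42_pg_ml", "protein_ug"]))

    truth = AssayGroundTruth(
        fold_changes=folds, ab40_pg_ml=cfg.ab40_pg_ml,
        ab42_pg_ml=cfg.ab42_pg_ml, protein_ug=cfg.protein_ug,
        ab42_40_ratio=(cfg.ab42_pg_ml / cfg.ab40_pg_ml
                       if cfg.ab40_pg_ml > 0 else float("nan")))
    return ct_table, elisa, truth
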