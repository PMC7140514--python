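"""Extracellular-flux (mito stress test) respiration metrics.

An OCR profile holds three measurement cycles per phase through the
injection sequence baseline -> oligomycin -> FCCP -> rotenone/antimycin A.
Metric definitions:

* non-mitochondrial OCR: aggregate of the rot/AA phase (mean by default);
* basal OCR: the *third baseline measurement* minus non-mito;
* maximal OCR: the FCCP-phase aggregate minus non-mito;
* spare respiratory capacity: maximal / basal (dimensionless ratio).

Normalisation divides the rate metrics by the Hoechst-positive cell count
(per 1000 cells); the spare ratio is scale-free and unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingPhaseError

PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")


@dataclass
class OcrProfile:
    """One well's OCR time course with phase labels per measurement."""

    table: pd.DataFrame                # time_min, ocr, phase
    hoechst_cells: int | None = None
    well: str = "well"

    def __post_init__(self) -> None:
        missing = {"time_min", "ocr", "phase"} - set(self.table.columns)
        if missing:
            raise InvalidParameterError(f"OCR table lacks columns: {sorted(missing)}")
        seen = [p for p in self.table["phase"].drop_duplicates()]
        order = [p for p in seen if p in PHASES]
        if order != [p for p in PHASES if p in order]:
            raise InvalidParameterError("phases out of injection order")

    def phase_values(self, phase: str) -> np.ndarray:
        vals = self.table.loc[self.table["phase"] == phase, "ocr"].to_numpy()
        if vals.size == 0:
            raise MissingPhaseError(f"no measurements in phase {phase!r}")
        return vals


@dataclass
class RespirationMetrics:
    """Basal/maximal OCR (pmol/min) and the spare-capacity ratio."""

    basal: float
    maximal: float
    spare: float                        # maximal / basal; NaN if basal <= 0
    non_mito: float
    basal_per_1000: float = math.nan
    maximal_per_1000: float = math.nan
    well: str = "well"

    def to_series(self) -> pd.Series:
        return pd.Series({"basal": self.basal, "maximal": self.maximal,
                          "spare": self.spare, "non_mito": self.non_mito,
                          "basal_per_1000": self.basal_per_1000,
                          "maximal_per_1000": self.maximal_per_1000})


def compute_respiration_metrics(profile: OcrProfile,
                                phase_aggregate: str = "mean",
                                spare_as_percent: bool = False,
                                ) -> RespirationMetrics:
    """Compute basal, maximal and spare respiration from one well's profile.

    ``phase_aggregate`` controls how "values after the addition" of an
    inhibitor are summarised: ``mean`` (default) or ``min`` of the phase's
    measurements. Basal always uses the third baseline measurement.
    """
    baseline = profile.phase_values("baseline")
    if baseline.size < 3:
        raise MissingPhaseError("baseline phase needs 3 measurement cycles")
    agg = {"mean": np.mean, "min": np.min}.get(phase_aggregate)
    if agg is None:
        raise InvalidParameterError("phase_aggregate must be 'mean' or 'min'")
    non_mito = float(agg(profile.phase_values("rot_aa")))
    profile.phase_values("oligomycin")     # required phase, not used directly
    basal = float(baseline[2] - non_mito)
    maximal = float(agg(profile.phase_values("fccp")) - non_mito)
    spare = maximal / basal if basal > 0 else math.nan
    if spare_as_percent and not math.isnan(spare):
        spare *= 100.0
    return RespirationMetrics(basal=basal, maximal=maximal, spare=spare,
                              non_mito=non_mito, well=profile.well)


def normalize_by_cells(metrics: RespirationMetrics,
                       hoechst_count: int) -> RespirationMetrics:
    """Express rate metrics per 1000 Hoechst-positive cells."""
    if hoechst_count <= 0:
        raise InvalidParameterError("cell count must be positive")
    k = hoechst_count / 1000.0
    return replace(metrics, basal_per_1000=metrics.basal / k,
                   maximal_per_1000=metrics.maximal / k)
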