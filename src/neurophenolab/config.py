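"""Simulation and analysis configuration.

Every quantitative rule used by the analysis modules is a named default here,
so a config file can override any of them:

* spike detection threshold 6.0 x baseline noise SD
* spike band 200-3000 Hz Butterworth
* active electrode: average of more than 5 spikes/min
* single-electrode burst: more than 5 spikes per 100 ms window
* network burst: more than 50 spikes per 100 ms on at least 35% of electrodes
* calcium-spike-positive cell: dFmax above 0.01
* traced nucleus: area above 50 um^2, not pyknotic; region expansion +50% area
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

import yaml

from .errors import InvalidConfigError


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidConfigError(msg)


@dataclass
class MeaSimConfig:
    """Multi-electrode array simulation parameters (one well).

    Spike amplitude is defined as the waveform's peak height *after* the
    spike-band filter, so the detector-domain signal-to-noise ratio is
    ``spike_amplitude_uv / (noise_sd_uv * band_noise_factor)``.
    """

    n_electrodes: int = 16
    sampling_rate_hz: float = 12_500.0
    duration_s: float = 60.0
    background_rate_hz: float = 5.0
    burst_rate_hz: float = 0.05            # burst epochs per second per electrode
    intra_burst_rate_hz: float = 100.0
    burst_duration_s: float = 0.1
    network_event_rate_per_min: float = 1.0
    network_event_duration_s: float = 0.1
    # multi-unit aggregate rate during a network event; must stay above the
    # network-participation count even after detector dead-time thinning
    # (2000 Hz -> ~667 Hz detected at a 1 ms dead time, ~66 spikes/100 ms)
    network_intra_rate_hz: float = 2000.0
    network_participation: float = 0.5     # fraction of electrodes sharing events
    spike_amplitude_uv: float = 40.0       # post-filter peak height
    noise_sd_uv: float = 5.0

    def validate(self) -> "MeaSimConfig":
        _require(self.n_electrodes >= 1, "n_electrodes must be >= 1")
        _require(self.duration_s > 0, "duration_s must be positive")
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz must be positive")
        for name in ("background_rate_hz", "burst_rate_hz", "intra_burst_rate_hz",
                     "network_event_rate_per_min", "network_intra_rate_hz",
                     "spike_amplitude_uv", "noise_sd_uv"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0.0 <= self.network_participation <= 1.0,
                 "network_participation must be in [0, 1]")
        return self


@dataclass
class CalciumSimConfig:
    """Calcium-trace simulation: kernel-convolved event trains on a baseline.

    Defaults mirror a 5000-frame stream acquisition at ~31.5 ms/frame with a
    slow sensor (rise ~0.2 s, decay ~1.2 s).
    """

    n_rois: int = 30
    n_frames: int = 5000
    frame_interval_s: float = 0.0315
    event_rate_hz: float = 0.08            # per active ROI
    active_fraction: float = 0.4           # ROIs carrying events at all
    shared_fraction: float = 0.0           # of active ROIs, share one event train
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.2
    event_amplitude: float = 30.0          # a.u., added at kernel peak
    f0: float = 100.0
    bleach_slope_per_frame: float = 0.002  # a.u. lost per frame
    bleach_mode: str = "linear"            # or "exponential"
    noise_sd: float = 0.08                 # a.u.; ROI-averaged traces are quiet
    mcherry_positive_fraction: float = 1.0

    def validate(self) -> "CalciumSimConfig":
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(self.n_rois >= 1, "n_rois must be >= 1")
        _require(self.frame_interval_s > 0, "frame_interval_s must be positive")
        _require(self.f0 >= 0, "f0 must be non-negative")
        for name in ("event_rate_hz", "kernel_rise_s", "kernel_decay_s",
                     "event_amplitude", "noise_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("active_fraction", "shared_fraction", "mcherry_positive_fraction"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"{name} must be in [0, 1]")
        _require(self.bleach_mode in ("linear", "exponential"),
                 "bleach_mode must be 'linear' or 'exponential'")
        return self


@dataclass
class ImagingSimConfig:
    """Synthetic microscopy field: elliptical nuclei, marker channels,
    neurite polylines and synaptic puncta.

    Marker fractions follow the reporting conventions of the analysis:
    ``tubb3_fraction`` and ``mcherry_fraction`` are fractions of all healthy
    cells; ``map2_fraction``, ``neun_fraction`` and ``cellrox_fraction`` are
    fractions *of the Tubb3-positive cells*.
    """

    field_px: int = 1024
    pixel_size_um: float = 0.5
    n_cells: int = 120
    nucleus_area_um2_mean: float = 90.0
    nucleus_area_um2_sd: float = 15.0
    nucleus_intensity: float = 100.0
    pyknotic_fraction: float = 0.1
    pyknotic_area_um2: float = 30.0        # mean area of pyknotic nuclei (< 50)
    pyknotic_brightness_factor: float = 3.0
    background_mean: float = 10.0
    background_sd: float = 2.0
    marker_intensity: float = 120.0
    soma_radius_factor: float = 1.4        # soma disc radius / nucleus radius
    tubb3_fraction: float = 0.8
    map2_fraction: float = 0.6
    neun_fraction: float = 0.5
    cellrox_fraction: float = 0.25
    cellrox_tubb3_negative_fraction: float = 0.0
    mcherry_fraction: float = 0.3
    n_neurites: int = 12
    neurite_length_um: float = 200.0
    neurite_width_px: int = 5
    neurite_intensity: float = 80.0
    puncta_per_channel: int = 150
    punctum_radius_px: int = 2
    puncta_on_neurite_fraction: float = 1.0
    min_separation_px: int = 4
    max_placement_attempts: int = 200

    def validate(self) -> "ImagingSimConfig":
        _require(self.field_px > 0, "field_px must be positive")
        _require(self.pixel_size_um > 0, "pixel_size_um must be positive")
        _require(self.n_cells >= 0, "n_cells must be >= 0")
        for name in ("nucleus_area_um2_mean", "pyknotic_area_um2",
                     "neurite_length_um"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("pyknotic_fraction", "tubb3_fraction", "map2_fraction",
                     "neun_fraction", "cellrox_fraction", "mcherry_fraction",
                     "puncta_on_neurite_fraction",
                     "cellrox_tubb3_negative_fraction"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"{name} must be in [0, 1]")
        return self


@dataclass
class FluxSimConfig:
    """Extracellular-flux (OCR) profile: plateau per injection phase.

    Phase order is fixed by the assay: baseline, oligomycin, FCCP,
    rotenone + antimycin A; three measurement cycles per phase.
    """

    plateaus: tuple[float, float, float, float] = (100.0, 40.0, 150.0, 20.0)
    n_per_phase: int = 3
    cycle_minutes: float = 6.5
    noise_sd: float = 2.0
    hoechst_cells: int = 4000

    def validate(self) -> "FluxSimConfig":
        _require(len(self.plateaus) == 4, "exactly 4 phase plateaus required "
                 "(baseline, oligomycin, FCCP, rot_aa)")
        _require(self.n_per_phase >= 1, "n_per_phase must be >= 1")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.hoechst_cells > 0, "hoechst_cells must be positive")
        return self


@dataclass
class AssaySimConfig:
    """qPCR Ct tables and amyloid-beta ELISA tables with known ground truth.

    ``fold_changes`` maps gene -> {condition -> fold change relative to the
    reference condition}; Ct values are built so that fold = 2**(-ddCt)
    holds exactly before noise. ELISA concentrations are pg/ml, protein ug.
    """

    genes: tuple[str, ...] = ("MAP2", "SYN1", "DLG4")
    conditions: tuple[str, ...] = ("ngn2_d20", "ngn2_bmirs_d20")
    reference_condition: str = "ngn2_d20"
    reference_gene: str = "ActB"
    reference_ct: float = 18.0             # ActB Ct, all samples
    base_ct: float = 26.0                  # target-gene Ct in reference condition
    fold_changes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    default_fold: float = 4.0              # fold for genes absent from the map
    n_replicates: int = 3
    ct_noise_sd: float = 0.15              # cycles; typical technical replicate
    ab40_pg_ml: float = 100.0
    ab42_pg_ml: float = 10.0
    protein_ug: float = 2.0
    elisa_noise_sd: float = 3.0            # pg/ml
    n_elisa_samples: int = 4

    def validate(self) -> "AssaySimConfig":
        _require(len(self.genes) >= 1, "at least one target gene required")
        _require(self.reference_condition in self.conditions,
                 "reference_condition must be one of conditions")
        _require(self.reference_gene not in self.genes,
                 "reference_gene must not also be a target gene")
        for name in ("ab40_pg_ml", "ab42_pg_ml", "protein_ug"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for g, m in self.fold_changes.items():
            for c, f in m.items():
                _require(f > 0, f"fold change for {g}/{c} must be positive")
        return self


@dataclass
class SimConfig:
    """Top-level simulation configuration: one seed, one block per modality."""

    seed: int = 0
    mea: MeaSimConfig = field(default_factory=MeaSimConfig)
    calcium: CalciumSimConfig = field(default_factory=CalciumSimConfig)
    imaging: ImagingSimConfig = field(default_factory=ImagingSimConfig)
    flux: FluxSimConfig = field(default_factory=FluxSimConfig)
    assays: AssaySimConfig = field(default_factory=AssaySimConfig)

    def validate(self) -> "SimConfig":
        for block in (self.mea, self.calcium, self.imaging, self.flux, self.assays):
            block.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimConfig":
        blocks = {"mea": MeaSimConfig, "calcium": CalciumSimConfig,
                  "imaging": ImagingSimConfig, "flux": FluxSimConfig,
                  "assays": AssaySimConfig}
        kwargs: dict[str, Any] = {}
        known = {f.name for f in fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise InvalidConfigError(f"unknown config section: {key!r}")
            if key in blocks:
                block_cls = blocks[key]
                block_known = {f.name for f in fields(block_cls)}
                bad = set(value) - block_known
                if bad:
                    raise InvalidConfigError(
                        f"unknown key(s) in section {key!r}: {sorted(bad)}")
                if key == "flux" and "plateaus" in value:
                    value = {**value, "plateaus": tuple(value["plateaus"])}
                kwargs[key] = block_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
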