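"""Virtual-experiment orchestration: simulate -> analyze -> stats -> bundle.

A virtual experiment mirrors the shape of a culture-comparison study: two or
more named conditions (parameter overrides on the simulation defaults), a
number of independent replicates each, every analysis module applied to its
modality, and group statistics on each resulting metric. The bundle is a set
of CSV tables plus a JSON manifest (config hash, seed, package version and
output file hashes); identical config and seed reproduce the bundle
byte-for-byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimConfig
from .errors import InvalidConfigError
from . import calcium as ca
from . import flux as fx
from . import mea as mea_mod
from . import stats as st
from .assays import compute_ddct, normalize_elisa
from .simulate import (simulate_calcium_traces, simulate_mea_recording,
                       simulate_ocr_profile, simulate_assay_tables)
from .simulate.mea import simulate_spike_trains, truth_to_spike_train_set

DEFAULT_MODALITIES = ("mea", "calcium", "flux", "assays")


@dataclass
class ExperimentBundle:
    """In-memory result of one virtual experiment."""

    metrics: pd.DataFrame          # condition, replicate, metric, value
    summary: pd.DataFrame          # per-(metric, group) mean/dispersion/n
    comparisons: pd.DataFrame      # per-metric contrasts with adjusted p
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("metrics", self.metrics), ("summary", self.summary),
                         ("comparisons", self.comparisons)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = str(p)
        self.manifest["file_sha256"] = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in paths.items()}
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        paths["manifest"] = str(mpath)
        return paths


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _replicate_seed(master: int, cond_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([master, cond_idx, rep])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _mea_metrics(cfg: SimConfig, level: str) -> dict[str, float]:
    if level == "voltage":
        rec, _ = simulate_mea_recording(cfg)
        filtered = mea_mod.bandpass_filter(rec)
        sd = mea_mod.estimate_noise_sd(filtered)
        spikes = mea_mod.detect_spikes(filtered, sd)
    elif level == "spikes":
        ss = np.random.SeedSequence(cfg.seed).spawn(2)[0]
        spikes = truth_to_spike_train_set(simulate_spike_trains(cfg.mea, ss))
    else:
        raise InvalidConfigError("mea_level must be 'voltage' or 'spikes'")
    bursts = mea_mod.detect_bursts(spikes)
    nets = mea_mod.detect_network_bursts(spikes)
    wm = mea_mod.compute_well_metrics(spikes, bursts, nets)
    return wm.to_series().to_dict()


def _calcium_metrics(cfg: SimConfig) -> dict[str, float]:
    traces, _ = simulate_calcium_traces(cfg)
    _, summary = ca.analyze_traces(traces)
    s = summary.to_series().to_dict()
    s.pop("n_valid_rois", None)
    s.pop("mcherry_positive_fraction", None)
    return s


def _flux_metrics(cfg: SimConfig) -> dict[str, float]:
    profile, _ = simulate_ocr_profile(cfg)
    m = fx.compute_respiration_metrics(profile)
    m = fx.normalize_by_cells(m, profile.hoechst_cells)
    return {"ocr_basal": m.basal, "ocr_maximal": m.maximal,
            "ocr_spare": m.spare, "ocr_basal_per_1000": m.basal_per_1000}


def _assay_metrics(cfg: SimConfig) -> dict[str, float]:
    ct, elisa, _ = simulate_assay_tables(cfg)
    out: dict[str, float] = {}
    conds = [c for c in cfg.assays.conditions
             if c != cfg.assays.reference_condition]
    if conds:
        mat = compute_ddct(ct)
        for g in mat.neg_ddct.index:
            out[f"neg_ddct_{g}"] = float(mat.neg_ddct.loc[g, conds[0]])
    norm = normalize_elisa(elisa).normalized
    out["ab42_40_ratio"] = float(norm["ab42_40_ratio"].mean())
    out["ab42_pg_per_ug"] = float(norm["ab42_pg_per_ug"].mean())
    return out


_RUNNERS = {"mea": None, "calcium": _calcium_metrics, "flux": _flux_metrics,
            "assays": _assay_metrics}


def run_virtual_experiment(config: Mapping[str, Any] | str | Path,
                           out_dir: str | Path | None = None,
                           ) -> ExperimentBundle:
    """Run a seeded multi-condition virtual experiment end to end.

    ``config`` is a mapping (or YAML path) with keys: ``seed``,
    ``n_replicates``, ``modalities``, ``mea_level`` ('spikes' or 'voltage'),
    ``conditions`` (name -> per-modality overrides) and optionally
    ``control`` (condition name for many-to-one comparisons).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise InvalidConfigError("config must be a mapping or a YAML path")
    seed = int(config.get("seed", 0))
    n_rep = int(config.get("n_replicates", 4))
    if n_rep < 2:
        raise InvalidConfigError("n_replicates: need >= 2 for statistics")
    modalities = tuple(config.get("modalities", DEFAULT_MODALITIES))
    level = config.get("mea_level", "spikes")
    conditions = config.get("conditions")
    if not isinstance(conditions, Mapping) or len(conditions) < 2:
        raise InvalidConfigError("conditions: need a mapping of >= 2 named "
                                 "conditions")
    control = config.get("control")
    if control is not None and control not in conditions:
        raise InvalidConfigError(f"control: {control!r} is not a condition")
    base = config.get("base", {})

    rows = []
    for ci, (cond, override) in enumerate(conditions.items()):
        merged = _merge(dict(base), override or {})
        for rep in range(n_rep):
            merged_seeded = dict(merged)
            merged_seeded["seed"] = _replicate_seed(seed, ci, rep)
            try:
                sim_cfg = SimConfig.from_dict(merged_seeded)
            except InvalidConfigError as exc:
                raise InvalidConfigError(
                    f"condition {cond!r}: {exc}") from exc
            for mod in modalities:
                if mod == "mea":
                    vals = _mea_metrics(sim_cfg, level)
                elif mod in _RUNNERS and _RUNNERS[mod]:
                    vals = _RUNNERS[mod](sim_cfg)
                else:
                    raise InvalidConfigError(f"modalities: unknown {mod!r}")
                rows.extend((cond, rep, k, v) for k, v in vals.items())
    metrics = pd.DataFrame(rows, columns=["condition", "replicate", "metric",
                                          "value"])

    summaries, contrasts = [], []
    for metric, sub in metrics.groupby("metric", sort=True):
        data = sub.rename(columns={"condition": "group"})[["group", "value"]]
        data = data[np.isfinite(data["value"])]
        if (data["group"].nunique() < 2 or len(data) < 4
                or data["value"].std() == 0):   # no variation, nothing to test
            continue
        summ = st.summarize_groups(data, dispersion="SEM")
        summ.insert(0, "metric", metric)
        summaries.append(summ)
        try:
            results = st.compare_groups(data, control=control, seed=seed)
        except Exception:
            continue
        for r in results:
            contrasts.append({"metric": metric, **r.to_dict()})
    summary = (pd.concat(summaries, ignore_index=True) if summaries
               else pd.DataFrame())
    comparisons = pd.DataFrame(contrasts)

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "neurophenolab",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
    }
    bundle = ExperimentBundle(metrics, summary, comparisons, manifest)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
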