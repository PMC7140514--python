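# neurophenolab

Quantitative phenotyping of cultured neurons — the measurement side of a
stem-cell-derived neuron study, reimplemented as an open, tested pipeline.
It covers five acquisition modalities end to end, each driven by a seeded
synthetic-data generator with recorded ground truth, so every stage has
recovery tests without any external data:

| Modality | What is computed |
| --- | --- |
| Multi-electrode array (MEA) | band-pass filtering (200–3000 Hz Butterworth), spike detection at +6.0 × baseline noise SD, active electrodes (>5 spikes/min), single-electrode bursts (>5 spikes/100 ms), network bursts (>50 spikes/100 ms on ≥35% of electrodes), per-well metrics and raster export |
| Calcium imaging | photobleach correction (first-minus-last-frame line removal), ΔF/F = (F − F0)/F0, ΔFmax, calcium-spike-positive cells (ΔFmax > 0.01), mCherry⁺ fractions, synchrony index |
| High-content imaging | traced nuclei (>50 µm², pyknotic excluded), 50% nuclear-region expansion, marker fractions (Tubb3⁺/Ho, MAP2⁺/Tubb3⁺, NeuN⁺/Tubb3⁺, CellROX⁺/Tubb3⁺), neurite length, synaptic area per µm neurite |
| Extracellular flux | basal OCR (third baseline cycle − rot/AA), maximal OCR (FCCP − rot/AA), spare respiratory capacity (maximal/basal), per-1000-cell normalisation |
| Molecular assays | comparative-Ct relative expression (−ΔΔCt and fold 2^(−ΔΔCt) vs ActB and a reference condition), protein-normalised Aβ40/Aβ42 with the Aβ42/40 ratio |
| Statistics | Student's t, Dunnett many-to-one, Tukey all-pairs; mean ± SD/SEM summaries with reference normalisation and significance stars |

The threshold values above are the pipeline defaults; every one of them is
a named, overridable parameter. All rule comparisons are strict
inequalities — an electrode averaging exactly 5 spikes/min is not active,
a bin holding exactly 50 spikes does not join a network burst.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

Simulate one 16-electrode MEA well for 60 s (background 5 Hz, network
events at 3/min) and run the full analysis chain:

```python
from neurophenolab import (SimConfig, bandpass_filter, estimate_noise_sd,
                           detect_spikes, detect_bursts,
                           detect_network_bursts, compute_well_metrics)
from neurophenolab.simulate import simulate_mea_recording

cfg = SimConfig(seed=3)
cfg.mea.duration_s = 60.0
cfg.mea.network_event_rate_per_min = 3.0
rec, truth = simulate_mea_recording(cfg)

filtered = bandpass_filter(rec)              # 200-3000 Hz, zero phase
sigma = estimate_noise_sd(filtered)          # robust baseline SD / electrode
spikes = detect_spikes(filtered, sigma)      # threshold 6.0 x SD, 1 ms dead time
bursts = detect_bursts(spikes)               # >5 spikes per 100 ms bin
nets = detect_network_bursts(spikes)         # >50 spikes on >=35% of electrodes
print(compute_well_metrics(spikes, bursts, nets).to_series().to_string())
print("implanted:", truth.network_event_times.size, "| detected:", nets.count)
```

Output:

```
active_electrodes             16.0000
mean_firing_rate_hz            7.0625
burst_count                   65.0000
bursting_electrodes           15.0000
network_burst_freq_per_min     3.0000
implanted: 3 | detected: 3
```

All 16 electrodes exceed 5 spikes/min, the mean rate per active electrode
is ~7 spikes/s (5 Hz background plus burst and network-event spikes), and
the three implanted network events are all recovered from the raw voltage —
3 events in 1 minute is a frequency of 3.0/min.

## Command line

```sh
neurophenolab simulate mea  --seed 1 --out sim/        # synthetic data + truth
neurophenolab mea     --in sim/recording.h5 --out out/ # spikes, bursts, raster
neurophenolab calcium --traces t.csv --frame-interval 0.0315 --out out/
neurophenolab hcs     --image field.tif --out out/
neurophenolab flux    --in ocr.csv --out out/
neurophenolab assays  ddct --in ct.csv --ref-cond ngn2_d20 --out out/
neurophenolab stats   --in data.csv --method dunnett --control CT --out out/
neurophenolab run     --config experiment.yaml --out bundle/
```

`run` executes a full virtual experiment — two or more simulated
conditions, analysis of every modality, group statistics per metric — and
writes a CSV bundle with a JSON manifest; identical config and seed
reproduce the bundle byte for byte.

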