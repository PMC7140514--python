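# Methods

`neurophenolab` quantifies functional and morphological phenotypes of
cultured (typically stem-cell-derived) neurons across five acquisition
modalities, and ships a seeded synthetic-data generator for each so that
every analysis stage can be validated against known ground truth. This note
records the models, the defaults that matter, the numerical choices, and
what the synthetic data does and does not establish.

## Multi-electrode array analysis

**Model.** Extracellular voltage per electrode is band-limited noise plus
~1 ms multi-unit spike waveforms. The chain is: zero-phase Butterworth
band-pass (200–3000 Hz, order 3, applied forward–backward per electrode);
robust baseline noise SD; positive-threshold peak detection; then binned
burst statistics.

- *Filter.* The designed magnitude response is −3 dB at the 200/3000 Hz
  cutoffs (scipy convention). Because the filter is applied forward and
  backward for zero phase, the applied two-pass response is −6 dB at the
  cutoffs; cutoff measurements in the tests therefore evaluate the designed
  (single-pass) response.
- *Noise SD.* Default estimator is the median absolute deviation about the
  median, scaled by 1/0.6745. It is consistent for Gaussian noise and
  nearly insensitive to a few percent of spike samples, which a plain SD is
  not. A plain-SD-over-designated-baseline alternative exists for
  recordings with annotated quiet intervals.
- *Spike detection.* A spike is a local maximum strictly exceeding
  6.0 × SD (positive polarity only by default — the threshold is defined as
  a positive excursion; a both-polarity option exists). After each
  detection, further peaks are suppressed for a 1 ms dead time so one
  waveform is never counted twice. Spike time is the peak sample divided by
  the sampling rate.
- *Activity and bursts.* All rule comparisons are strict: an electrode is
  **active** iff its average rate exceeds 5 spikes/min; a 100 ms bin is a
  **burst** iff it holds more than 5 spikes; an electrode **participates**
  in a network burst iff its bin holds more than 50 spikes; a bin is a
  **network burst** iff at least ⌈0.35 × N⌉ electrodes participate
  (N = electrodes in the well; the product is guarded against
  floating-point excess so 0.35 × 100 needs 35 electrodes, not 36).
  Bins are fixed and non-overlapping, tiled from t = 0; adjacent qualifying
  bins count as separate bursts (count semantics). A sliding-window variant
  was considered and rejected: the rule wording is a per-window count, and
  fixed bins make the brute-force oracle exact.
- *Well metrics.* Active-electrode count, mean firing rate per active
  electrode (NaN — not zero — when no electrode is active), burst count,
  bursting-electrode count, network-burst frequency per minute.

**Generator.** Spike trains per electrode are the superposition of a
homogeneous Poisson background (default 5 Hz), Poisson-arriving 100 ms
burst epochs with a high intra-burst rate, and well-wide network events:
100 ms epochs implanted simultaneously on a configured electrode fraction
(default 50%). Network-event onsets snap to the 100 ms analysis grid — an
epoch straddling two fixed bins splits its spikes and would evade the
per-bin count rule by construction, which would make implanted-event
recovery depend on phase rather than on the detector. The intra-event
rate defaults to 2000 Hz (a multi-unit aggregate): after dead-time
thinning in the detector (~667 Hz effective at 1 ms) an event still
yields ~66 detected spikes per 100 ms, safely above the 50-spike
participation count, so implanted events survive the full
voltage → detection → binning chain. Voltage is white Gaussian noise plus a biphasic template at
each spike time; the template is rescaled so its **post-filter** peak equals
the configured amplitude, making the detector-domain SNR exactly
amplitude / (noise SD × band factor), where the band factor
(≈0.632 at 12.5 kHz) is the white-noise SD shrinkage of the two-pass filter
computed from the frequency response. Trains carry no refractory period —
an electrode is a multi-unit channel — so at high rates two ground-truth
spikes can fall inside the detector dead time and merge; pipeline-identity
tests therefore condition on draws without sub-dead-time spike pairs,
and detection recovery is scored with ±1 ms matching (F1 ≥ 0.95 at
post-filter SNR 8 with 5 Hz × 16 electrodes × 60 s).

## Calcium-transient analysis

**Model.** Raw ROI fluorescence F(t) is corrected for photobleaching using
the first-minus-last-frame drop: the straight line through (0, F(0)) and
(N, F(N)) is removed and F(0) re-added, so a pure linear decay becomes the
constant F(0). A literal constant subtraction cannot flatten a ramp, which
is why the line-removal reading is the default; the constant mode is kept
as an option. Normalisation is ΔF/F = (F − F0)/F0 with F0 = F(0) (ROIs with
F0 ≤ 0 are flagged invalid and excluded from all summaries). ΔFmax defaults
to max − min of the ΔF/F series (reading "largest change" as the full
excursion); a max-only mode exists, and the spike classifier uses whichever
mode is configured. A cell is calcium-spike-positive iff ΔFmax strictly
exceeds 0.01. The synchrony index is the mean pairwise Pearson correlation
of ΔF/F among spike-positive ROIs, clipped to [0, 1].

The endpoint-based bleach correction is exact only when the last frame is
event-free; an event tail at frame N tilts the fitted line by
(tail amplitude)/N per frame. This is inherent to the endpoint recipe and
is reproduced, not repaired, by the implementation.

**Generator.** Traces are F0 + amplitude × (events ⊛ kernel) − bleach +
noise on a 5000-frame, 31.5 ms grid; the kernel is a unit-peak double
exponential (rise 0.2 s, decay 1.2 s — a slow sensor). Default per-frame
noise SD is 0.08 a.u. on F0 = 100: ROI traces are spatial averages over
many pixels, so their per-frame noise is far below single-pixel camera
noise; at this level the ΔF/F range of a silent 5000-frame trace stays
safely below the 0.01 classification threshold, as it must for the
threshold to mean anything. Bleaching is linear by default (matching the
endpoint correction); an exponential mode exists for robustness tests. A
configured subset of active ROIs shares one event train to give the
synchrony index a positive control.

## High-content imaging

**Model.** Nuclei are segmented from the Hoechst channel by Otsu threshold,
hole filling, and watershed on the distance transform (peak separation set
from the minimum traceable nucleus radius). A candidate is a **traced
nucleus** iff its area strictly exceeds 50 µm² and its mean intensity is
below the pyknotic brightness threshold — the field's median nuclear
intensity × 2 by default (pyknotic nuclei are condensed and over-bright;
no published cutoff exists, so the factor is configurable). Each traced
nucleus is expanded by 50% **in area** into a cytoplasm-proxy region.
Expansion is competitive and exact: every background pixel is assigned to
its nearest nucleus (Euclidean distance transform with index return), and
each label claims its candidate pixels in order of increasing distance
until it reaches ⌈1.5 × nuclear area⌉ pixels. Regions therefore never
overlap or merge, and the area ratio lands within a pixel of 1.5 (a
radius-based mode, √1.5 × equivalent radius, exists as an option).

Marker positivity is region mean intensity strictly above background mean
+ 3 SD (background = pixels outside all cell regions). Reported fractions
follow the figure conventions: Tubb3+/all traced cells; MAP2+ and NeuN+
among Tubb3+ cells; CellROX+ among Tubb3+ cells (CellROX signal in
non-neurons is by definition excluded); mCherry+ among all traced nuclei.

Neurite length: the Tubb3 channel is binarised (Otsu by default — a
mean+3·SD cut leaks Gaussian background noise into the mask), cell bodies
are removed by a disk-opening (radius 4 px) whose surviving blobs are
accepted as somata only above 60 µm² (smaller thick spots are neurite
junctions, not cell bodies), slightly re-dilated and subtracted; the
remainder is skeletonised. Skeleton length uses corrected chain weights
(0.980 per orthogonal step, 1.406 per diagonal, −0.091 per corner), which
bound the straight-line bias below ~3% at every orientation — naive
(1, √2) weights overestimate oblique lines by up to 8%. Synaptic area per
neurite is the binarised punctum channel (SynI or PSD95) intersected with
the binarised Tubb3 area, in µm², divided by the field's neurite length
in µm.

**Generator.** Elliptical nuclei (healthy: ~90 ± 15 µm², pyknotic: smaller
than the 50 µm² cutoff *and* 3× brighter) are placed without overlap by
rejection sampling; marker channels add soma discs only for cells labelled
positive; neurites are polylines of known summed segment length drawn at a
5 px width, routed to avoid soma discs and each other (a process crossing
a soma or another process would be absorbed into, or widen, a mask
downstream, which would silently shift the recorded ground-truth length);
puncta are small discs centred on the neurite centreline (on-neurite) or
placed with their whole disc clear of the Tubb3 area (off-neurite). On
rendered fields of ≥500 cells the pipeline recovers every marker fraction
exactly (well within 3 binomial SE) and neurite length and synaptic area
per neurite within 5%.

What the renderer does *not* emulate: touching or overlapping nuclei,
intensity gradients and vignetting, out-of-focus light, and neurites
emanating from somata. Passing tests therefore establish the correctness of
the measurement definitions and their discretisation behaviour, not
robustness to crowded or degraded real microscopy.

## Extracellular-flux respiration

A profile holds three measurement cycles per phase through
baseline → oligomycin → FCCP → rotenone/antimycin A. Non-mitochondrial OCR
is the rot/AA-phase aggregate (mean of its cycles by default; min as an
option). Basal OCR is specifically the **third baseline cycle** minus
non-mito; maximal OCR is the FCCP-phase aggregate minus non-mito; spare
respiratory capacity is the ratio maximal/basal (dimensionless; NaN when
basal ≤ 0; a ×100 display mode exists). Rates are normalised per 1000
Hoechst-positive cells; the spare ratio is scale-free and unchanged. All
three metrics are invariant to an additive OCR offset by construction. The
generator draws each cycle as plateau + Gaussian noise, so error
propagation is exact: e.g. SD(basal) = σ·√(1 + 1/3).

## Molecular assays

Relative expression uses the comparative-Ct method with efficiency fixed
at 2: ΔCt = Ct(gene) − Ct(ActB) per sample; ΔΔCt = mean ΔCt(condition) −
mean ΔCt(reference condition); reported as −ΔΔCt (higher expression ⇒
larger value) and fold 2^(−ΔΔCt). Replicates are aggregated as mean ΔCt
per condition before differencing. The generator builds Ct values so that
fold = 2^(−ΔΔCt) holds exactly before noise, giving an exact round-trip
test at zero noise and a closed error-propagation bound otherwise. ELISA
amyloid-β concentrations are divided by culture protein; the Aβ42/40 ratio
is computed on raw concentrations and is normalisation-invariant.

## Group statistics

Student's t (equal variance; Welch behind a flag) for two groups; Dunnett
many-to-one and Tukey all-pairs for multiple comparison, delegated to
scipy's multivariate-t and studentized-range implementations behind this
package's tidy contrast interface; stars at 0.05/0.01/0.001. Summary
tables report mean ± SD or SEM with n, optionally normalised to a
reference group's mean. Calibration tests drive the null rejection rate of
all three tests into [0.04, 0.06] at α = 0.05 over ≥2000 simulations; the
Tukey family is calibrated through the exact studentized-range rejection
rule (vectorised for speed) after verifying, case by case, that it agrees
with the `tukey_hsd` implementation's rejections.

## Virtual experiments

`run_virtual_experiment` simulates two or more named conditions (parameter
overrides on the generator defaults) with n replicates each, runs each
modality's analysis, and applies the figure-appropriate statistics per
metric. Replicate seeds are spawned from (master seed, condition index,
replicate index), so the bundle is byte-identical under a fixed seed — the
manifest records config hash, seed, package version and output hashes, and
deliberately no wall-clock timestamp, since a timestamp would break
byte-level reproducibility. MEA simulation defaults to spike-train level
in this context; the voltage path has its own recovery tests, and
statistical calibration needs many runs. Metrics with zero variance across
all replicates (e.g. a saturated active-electrode count) are reported but
not tested. At the defaults used in the tests (5-minute wells, network
events at 3/min), doubling the network-event rate is detected in ≥80% of
seeded runs at n = 5, and with identical conditions the network-burst
contrast stays non-significant in ≥94% of runs.

## Problem sizes used in tests

Spike-recovery runs use one 16-electrode, 60 s well at 12.5 kHz; oracle
equivalence uses 1000 random spike-train sets; image recovery uses one
2048² field with 520 cells; calibrations use 2000–10000 null simulations.
These sizes put every statistical assertion at ≥3σ separation from its
failure boundary while keeping the full suite in a few minutes.

## Known limitations

- No spike sorting; an electrode is treated as one multi-unit signal.
- The endpoint bleach correction inherits the recipe's sensitivity to
  events near the last frame (documented above).
- Nuclear segmentation assumes separable nuclei; heavily confluent fields
  would need a learned or gradient-based splitter.
- ELISA concentrations are taken as kit outputs; no 4PL curve fitting.
- Dunnett/Tukey assume equal variances and approximately normal residuals,
  as their classical forms do.
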