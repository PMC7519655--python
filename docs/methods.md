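# Methods

`dualmea` analyses recordings from a dual-mode high-density microelectrode
array (HD-MEA): a CMOS chip that samples **every** electrode of a hexagonal
lattice in a full-frame stream (APS mode) while simultaneously reading a
small, freely routable subset of electrodes through low-noise channels
(switch-matrix / SM mode). This note documents the models, algorithms,
parameter choices and known limitations of the package, including what the
bundled simulator does and does not emulate.

## Array geometry

The electrode lattice is hexagonal: electrode (r, c) sits at
`x = c·p + (r mod 2)·p/2`, `y = r·p·√3/2` with pitch `p = 18.0 µm`; ids are
0-based row-major. Every interior electrode then has six nearest neighbours
at exactly one pitch. The full device exposes 19,584 electrodes; the vendor
describes the pixel matrix as "108 × 192", which cannot be an unbroken
row-major grid of that size (it would hold 20,736 sites), so the default
lattice here is 102 × 192 = 19,584. Only the electrode count, the pitch and
the hexagonal packing matter to any algorithm in the package; the exact
row/column split does not. Sub-arrays of any size can be built for
desk-scale work.

## Recording model and container

A `DualModeRecording` holds the two streams in microvolts with one shared
clock origin:

| stream | electrodes | rate | noise (AP band) |
|---|---|---|---|
| APS (full frame) | all | 11.6 kHz | 10.4 µV rms |
| SM (high SNR) | ≤ 246 selected | 24.4 kHz | 3.0 µV rms |

The two rates are not integer multiples, so streams are aligned on
timestamps, never on sample counts. On disk, samples are int16 with an
explicit µV-per-LSB scale (default 0.0625 µV/LSB, ±2048 µV full scale);
after one write the container round-trips losslessly. Data are chunked
electrode-major in blocks of ≤1 s so full-array recordings can be streamed.

## Synthetic ground truth

The simulator exists so that every downstream stage can be tested against a
known answer. It generates:

* **Arbors** — branches are polylines starting at the axon initial segment
  (AIS), each with its own conduction velocity. Defaults bracket cortical
  cultures: velocities of a few hundred mm/s, branch lengths of 600–900 µm,
  somatic peak −150 µV, axonal source amplitudes 14 → 9 µV along the branch
  (electrode-level axonal amplitudes then land in the 5–10 µV range typical
  of such recordings).
* **Waveform** — one biphasic template (negative lobe σ = 0.12 ms, then a
  40% positive lobe; 1.4 ms total), negative peak normalised to −1 and
  scaled by the local amplitude. A trough of ~0.3 ms is wide enough that the
  11.6 kHz sampling loses at most ~6% of the peak depending on spike phase;
  sharper templates would make single-frame amplitudes strongly
  phase-dependent.
* **Spatial decay** — an electrode sees the nearest point of each branch
  with amplitude × 1/(1 + d/λ), λ = 10 µm (a line-source stand-in), clipped
  below 1 µV; the soma uses the same law squared, as befits a compact
  source (otherwise a −150 µV soma would remain visible millimetres away),
  normalised so the AIS-nearest electrode records exactly the nominal
  somatic peak regardless of where the soma sits within a lattice cell.
  Real amplitude-vs-distance profiles are not published for this device;
  the law is isolated in `SpatialDecay` and easily replaced.
* **Spiking** — inhomogeneous Poisson trains (baseline mean 2.4 Hz) whose
  rate is multiplied by a gain inside network-burst windows (default 0.8 s
  bursts); monosynaptic couplings add a postsynaptic spike at +latency
  (1–5 ms) with a transmission probability per presynaptic spike.
* **Noise** — white Gaussian per stream, scaled so the rms **inside the AP
  band (0.3–5 kHz)** equals the nominal mode noise, because that is how the
  device's noise figures are quoted. No correlated or common-mode noise is
  modelled.

Rendering is deterministic given the generator: identical seeds produce
bit-identical recordings, and each rendered event is attributable to a
(neuron, spike, branch point) in the returned ground truth.

What the simulator does **not** emulate: biophysical (compartmental)
waveform diversity, electrode–tissue filtering, bursting amplitude
attenuation, drift, overlapping-spike interference between many densely
packed units, or correlated noise. Passing the recovery tests therefore
shows the algorithms are correct and noise-calibrated, not that they are
robust to every pathology of real tissue.

## Detection and spike-triggered averaging

Filtering is a 4th-order Butterworth applied forward–backward (zero phase);
the AP band is 300–3000 Hz for detection, 1–300 Hz is the LFP preset for
slice work. Detection thresholds are 7.5× the noise std of the filtered
trace; the noise std is estimated robustly as `median(|x|)/0.6745`, because
a plain standard deviation is inflated by the spikes themselves. Threshold
crossings within 1.5 ms are merged and refined to the local minimum.
Electrode preselection for sorting keeps electrodes whose filtered APS trace
exceeds 80 µV.

Spike-triggered averaging (STA) cuts windows of 12 ms (configurable; ±2 ms
is a common choice for display) from the APS stream around trigger times and
averages them per electrode, suppressing uncorrelated noise as 1/√N. The
triggers may come from the same stream, from an external sorter, or — the
dual-mode mechanism — from the simultaneously recorded low-noise SM stream,
which is what makes units invisible to direct APS detection recoverable
across the whole array. SM trigger times are mapped to the nearest APS
frame (error ≤ half a frame, 43.1 µs).

A `Footprint` carries, per electrode: the averaged waveform, the |negative
peak| amplitude, the peak latency relative to the initiation site (the
electrode with the largest amplitude; ties broken by lowest id), and a
peak-time jitter. The jitter is computed as a robust std (1.4826 × MAD) of
the negative-peak times over sub-averages of the trigger set (default 8
groups), with the peak search confined to ±2 ms around the footprint peak.
Single-window peak times would be meaningless at axonal signal-to-noise
(5–10 µV signals under 10.4 µV rms noise); sub-averaging restores enough
SNR that electrodes with a stable propagating signal show sub-frame jitter
while noise electrodes scatter uniformly (std ≈ 1.15 ms over a ±2 ms
window, safely above the 0.7 ms cut).

## Footprint cleaning and axonal tracking

Cleaning keeps electrodes with amplitude > 5.5× the per-electrode noise std
of the averaged signal **and** peak-time jitter < 0.7 ms. The noise std
defaults to the same median-based estimate on the footprint waveform (the
brief spike transient occupies too few of the 139 window samples to bias
the median).

The tracker works on the delay map at discrete frame resolution (one APS
frame = 86.2 µs; no sub-sample interpolation):

1. **Terminal selection.** Candidate terminals are unassigned cleaned
   electrodes whose delay is a local maximum within the 80 µm search
   radius. Electrodes of an already-traced wavefront suppress equal-delay
   stragglers (strict comparison against assigned neighbours); without
   this, the second-largest-amplitude electrode of every frame would seed a
   duplicate parallel segment, double-counting arbor extension. Candidates
   are processed in order of decreasing delay, then decreasing amplitude,
   then ascending id.
2. **Backward walk.** From the current electrode peaking in frame N, the
   candidates are cleaned unassigned electrodes peaking in frame N−1 within
   80 µm; the largest amplitude wins (ties to lowest id). If a frame is
   empty — axonal amplitudes of 5–10 µV routinely drop below threshold —
   the search expands to frame N−r and radius r × 80 µm for r up to 5.
3. **Stop rule.** The walk stops five frames before the initiation frame
   (the AIS/somatic signal is large and visible on many electrodes, making
   peak times unreliable there) or when no candidate remains.
4. **Velocity.** The path is reversed into initiation→terminal order;
   consecutive inter-electrode distances are summed and an ordinary
   least-squares fit of cumulative distance (µm) against peak latency (ms)
   gives the conduction velocity in mm/s (µm/ms ≡ mm/s) with its R².
   Fewer than 3 points or zero latency spread ⇒ velocity undefined.

Segments shorter than 5 electrodes are discarded (too short for a
meaningful fit) but still marked processed so extraction terminates.
Electrodes of an accepted segment are excluded from later traces, so a
shared proximal trunk is attributed to the first-traced branch — a known,
deliberate bias that keeps total extension free of double counting.
Distance along the path is summed inter-electrode distance; Euclidean
distance from the initiation site is available by flag for the fit.

Per-neuron morphometrics: segment count, longest segment, total extension
(sum of segment lengths), mean velocity over valid fits, footprint maximum
amplitude, firing rate.

Because the tracker excludes the five-frame initiation region by
construction, recovered total extension is compared (in the validation
experiments) against the suprathreshold ground-truth branch length *beyond*
that region; at 500 mm/s the excluded region is ~215 µm of axon.

## Bursts and connectivity

The population rate is the summed spike count in 0.01 s bins over all
units, divided by the bin and smoothed with a Gaussian kernel of σ = 0.3 s
(normalised: the rate integral equals the spike count up to <0.1% edge
loss). A burst is a contiguous interval where the smoothed rate exceeds
1.35× the baseline; "baseline" is not further specified by convention, so
the median of the smoothed rate is used (robust to the bursts themselves;
the mean is available by flag). Burst duration is crossing-to-crossing
around the single rate peak of the interval; the interburst interval runs
from one burst's offset to the next burst's onset (onset→onset is a flag).
Single-bin excursions carry no crossing pair and are ignored.

Connectivity uses cross-correlograms with 1 ms bins over ±50 ms, the lag-0
bin centred on zero; `counts[l]` is the exact number of spike pairs with
`t_b − t_a` in bin l (verified bin-for-bin against exhaustive pair
enumeration). The slow-comodulation predictor is the CCG convolved with a
**partially hollow Gaussian** (σ = 10 ms, centre-bin weight removed,
renormalised; edge bins normalised by in-range kernel mass), so each bin's
own — possibly monosynaptic — counts do not inflate its own null. The upper
band is the pointwise Poisson (1−α) quantile at the predicted mean,
α = 0.01. A putative excitatory connection is called when a bin within
±5 ms (lag 0 excluded: it cannot be directional and usually indicates
common input) exceeds the band; the sign of the lag gives the direction,
the lag itself the latency, and the maximal-excess lag wins per direction.
Pairs with fewer than 50 spikes in either train are skipped as untested.
Whether the reference convention's bands are pointwise or global, and the
exact kernel width, are configuration (`CCGParams`); the defaults above are
this package's documented choice. Only excitatory (peak-based) connections
are detected; troughs (inhibition) are out of scope.

The network graph is a directed multigraph-free `networkx.DiGraph` over all
tested pairs; node centres are the footprint amplitude-maximum electrodes
(not centroids), edge distance is the Euclidean centre-to-centre distance.

## Pipeline

`run_pipeline` executes simulate → STA → trace → network, persisting every
intermediate (HDF5 recording + ground truth, footprints, per-electrode
segment and per-neuron CSVs, burst/IBI/edge/degree CSVs, GraphML) so every
number in the session report is recomputable from stored artefacts. Runs
are deterministic given config + seed; the report embeds the seed, a config
hash and the package version. `compare_sessions` aligns several session
reports by population statistics (median and quartiles per metric); no
cross-day unit matching is attempted.

## Validation experiment sizes

The experiments in `dualmea.validation` (also run by
`scripts/acceptance.py`) use problem sizes chosen to finish on one CPU in a
few minutes while leaving the statistics meaningful: a noiseless 800 µm /
500 mm/s axon for exact tracker recovery; 50 noisy arbors (velocities
uniform in 300–700 mm/s, 300 averaged spikes each, own 20 × 56 sub-array)
for parameter recovery; a −40 µV unit with 1000 grid-aligned spikes on an
8 × 8 sub-array for STA convergence and the dual-mode mechanism; 40 units /
20 injected synapses / 300 s for connectivity recovery; 1000 independent
Poisson pairs for null calibration against an independently coded oracle;
and a deterministic two-burst raster whose extra in-window rate is chosen
analytically so the smoothed rate crosses threshold exactly at the window
edges, making the expected durations and IBI exact.

## Known limitations

* The tracker assigns one electrode per frame; at 18 µm pitch and
  ~500 mm/s an action potential passes ~2.4 electrodes per frame, so traced
  paths are a per-frame subsequence of the electrodes a branch touches.
* Shared trunks go to the first-traced branch; branch counts near the soma
  are therefore conservative.
* Latencies are frame-quantised (86.2 µs); velocity fits inherit a ~1%
  quantisation floor over 800 µm at 500 mm/s.
* The CCG null is pointwise; with 10 tested bins per pair the per-pair
  false-positive rate is several times α, exactly as for the reference
  convention — calibration is asserted against an oracle of the identical
  test, not against α itself.
* Spike sorting is delegated: the pipeline consumes unit spike trains (from
  the container, ground truth, or single-electrode SM detection); no
  PCA/template-matching sorter, drift correction or overlap resolution is
  included.
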