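# Methods

This note documents the models, conventions, and design choices behind
meakit, in the spirit of the methods documentation of mature scientific
packages: what each stage assumes, which parameters matter, and what the
synthetic validation does and does not show.

## Data model and units

Voltages are microvolts throughout; time is seconds, recording-relative,
with the absolute start kept separately as `t0`. Sample index and time are
interconverted by `round(t · rate)`. The raw-binary dialect is
channel-interleaved little-endian int16 with a JSON sidecar carrying the
sampling rate, channel count, and raw→µV scale — the form most acquisition
boards export — and an HDF5 container with a schema-version attribute is
provided for self-describing storage. Sampling at 30 kHz per electrode is
the assumed acquisition convention; nothing in the code requires it.

## Filtering

The spike band is isolated with a third-order Butterworth band-pass whose
half-power (−3 dB) edges are 200 and 3000 Hz. Digital design via bilinear
transform with pre-warping places the half-power points exactly at the
requested edges; the acceptance script verifies this by bisection on the
magnitude response. Application is forward–backward (zero-phase) by
default: an offline pipeline has no causality constraint, and zero-phase
filtering leaves spike extrema where they occurred, which matters because
timestamps are defined at the extremum. The trade-off is a doubled
effective attenuation (the single-pass band edge is no longer the −3 dB
point of the applied response); the half-power contract is therefore defined
on the single-pass response. A causal single pass is available via
`FilterSpec(zero_phase=False)`. Filters are realized as second-order
sections; a direct transfer-function realization of an order-3 band-pass
with a 200 Hz edge at 30 kHz sampling loses precision. Edge transients are
controlled with odd reflection padding.

## Noise estimation and spike detection

The per-channel noise scale is `σ̂ = median(|x|)/0.6745`. For zero-mean
Gaussian noise the median absolute value is 0.6745σ, so σ̂ is unbiased for
σ and, unlike the sample standard deviation, nearly unaffected by the
spikes themselves. The detection threshold is `5σ̂` (multiplier
configurable). Detection is polarity-aware (default negative, the dominant
polarity of extracellular somatic spikes); each contiguous supra-threshold
excursion contributes one event at its extremum, which gives a stable
alignment point for sorting. A dead time (default 1 ms) suppresses later
events too close to an accepted one — the first extremum wins. Events
without a complete cutout window (default 1 ms pre / 2 ms post) at the
recording boundary are dropped and counted. On pure Gaussian noise at
30 kHz these defaults yield well below 0.2 false events/s/channel.

Degenerate channels (σ̂ = 0, i.e. flat traces) are skipped with a warning
rather than producing division artifacts.

## Spike sorting

Cutouts are clustered in the space of their top principal components
(default 2). The clusterer is k-means with a fixed seed; the cluster count
is selected by the silhouette score over k = 2…5. The silhouette is
undefined at k = 1, so a single unit is returned when the best multi-cluster
silhouette falls below 0.5 — i.e. when no convincing multi-unit structure
exists. Sorting is per-channel in intent (templates are effectively
single-channel under the simulator's spatial attenuation); the function
itself operates on any cutout set. Zero-variance cutout sets return one
unit with a warning.

## Channel and network statistics

* **Firing rate** is count/duration; a channel is *active* when its rate
  strictly exceeds 0.5 Hz.
* **SNR** is the mean absolute spike peak amplitude divided by the standard
  deviation of the channel's entire band-pass-filtered trace. Channels
  without events have undefined SNR, reported as missing — never zero.
* **Correlation** is the product-moment correlation of spike counts in
  10 ms half-open bins `[k·Δ, (k+1)·Δ)`. Zero-variance channels yield
  undefined (NaN) entries, reported rather than imputed.
* **Bursts** are maximal runs of ≥ `min_spikes` (default 3) consecutive
  spikes with every inter-spike interval ≤ `max_isi` (default 100 ms). This
  transparent run-scan rule was chosen over model-based burst detectors
  because it is exactly checkable against an independent oracle.
* **Box summaries** use linear-interpolation quartiles and whiskers at the
  box edge ± 1.5·IQR, clipped to the most extreme observed points inside
  that range; values beyond are outliers. The quartile method is pinned for
  testability.

## Layout geometry

Coordinates are µm, origin at the array centroid, y up, electrode centers.
The 59-site grid is the commercial-compatible footprint: 8×8 minus the four
corners minus one reference site (here the row-3, column-0 site — which
grid position hosts the reference electrode is a convention). The 128-site
grid is 12×11 minus corners; 256 is 16×16; 512 is 23×23 minus the four
corners and the 13 remaining sites farthest from the centroid (ties broken
deterministically), keeping a near-square footprint. Pitch defaults to
200 µm and diameter to 30 µm; both are parameters.

The curved layout bends each electrode row onto a circular arc of radius
1/κ (κ in mm⁻¹, default 0.35), preserving along-arc pitch within the row,
with arc centers stacked vertically so the radial row spacing along the
midline equals the pitch. Equal radii per row — rather than concentric arcs
of varying radius — were chosen so that a circle fit to *any* row recovers
exactly 1/κ, which makes the geometry verifiable row by row; at κ = 0 the
construction degenerates to the rectangular grid. Circle fitting uses the
algebraic (Kåsa) least-squares fit, exact for noiseless arcs.

The perturbed layout displaces every electrode by a vector drawn uniformly
from the disk of radius `max_disp` (default 50 µm); uniform-over-the-disk is
the least-informative reading of "random displacements up to a bound". The
bound must stay below pitch/2 to exclude electrode collisions. Multi-well
layouts tile identical sub-grids on a super-grid of well centers spaced
(by default 3× the well diagonal) so that the minimum inter-well electrode
distance always exceeds the maximum intra-well distance.

## Stimulation protocols

Biphasic electrical pulses are a positive phase immediately followed by a
negative phase of equal duration (default 400 µs each, i.e. approximately
charge-balanced), repeated at the pulse rate within a train; two phases must
fit inside one pulse period. Optical pulses are on-intervals of
`duty_cycle/rate` each. Pulses are anchored at multiples of 1/rate from the
train start and partial trailing pulses are dropped (`floor(rate ·
duration)` pulses per train), since fractional-pulse handling is otherwise
ambiguous. Compiled timelines are explicitly validated (ordering,
non-overlap, bounds) before export. Command amplitudes (e.g. 700 or
1500 mV) are stimulator inputs; their electrode-level effect is
hardware-specific and out of scope.

## Calcium analysis

ΔF/F₀ = (F − F₀)/F₀ with F₀ the *initial* intensity, operationalized as the
mean of the first second of frames (an explicit convention, since "initial"
is otherwise ambiguous); a 10th-percentile baseline is available for
drifting traces. Transient onsets are upward threshold crossings separated
by at least a minimum interval — because transients decay slowly (~3 s), the
series can graze the threshold on the way down, and the separation parameter
(not hysteresis) is the mechanism for suppressing those re-crossings.
LFP extraction is a fourth-order zero-phase low-pass at 100 Hz with optional
decimation to 1 kHz (≥ 2.5× the cutoff); the band is a declared default, not
a measured constant. First-edge alignment reports the time difference of the
first upward crossings of half of each series' own peak (sub-sample via
linear interpolation), making the lag independent of the two modalities'
very different amplitudes and time constants.

## The simulator

The generator is phenomenological, not biophysical. Ground-truth trains are
homogeneous Poisson backgrounds (default 2 Hz/channel) superposed with
population bursts (Poisson burst events at 0.2 Hz; ~10 spikes per channel
per burst at ~10 ms intra-burst intervals with 20% jitter), thinned to a
2 ms refractory interval. With `well_sync`, burst skeletons are drawn
independently per well, producing the block-structured correlation matrix
expected of independent cultures on one chip. Evoked activity is emulated
by inserting bursts at given times; no stimulus-response physiology is
modeled.

The extracellular renderer inserts a difference-of-Gaussians biphasic
template (negative main phase, default 60 µV peak, 0.3 ms width) at each
spike, attenuated on neighboring electrodes by `exp(−d/λ)` with λ = 60 µm —
at 200 µm pitch a neighbor sees < 4% of the amplitude, keeping units
effectively single-channel, consistent with per-channel sorting — plus
i.i.d. Gaussian noise (default 6 µV, so peaks are 10× noise). The
fluorescence renderer convolves the per-frame population rate with a
fast-rise/slow-decay kernel `(1 − e^{−t/τ_r}) e^{−t/τ_d}` (τ_r = 0.1 s
< 150 ms, τ_d = 3 s), scales it (0.05 ΔF/F₀ per spike per channel), offsets
by F₀ and adds noise.

What passing tests on this synthetic data show: the chain's algorithms are
correct and internally consistent (thresholds sit where the formula says,
detection recovers known events, correlation reproduces known community
structure, ΔF/F₀ inverts exactly). What they do not show: performance on
real recordings with correlated noise, electrode drift, overlapping units,
bursting non-stationarity, movement or photobleaching artifacts — none of
which the generator emulates.

## Problem sizes and numerical choices

Validation runs use desk-scale problems: 59–128 channels, 10–60 s of
simulated data, 20 seeds for recovery studies, 1000 seeds for layout bounds
— sizes chosen so the full suite completes in about a minute while keeping
Poisson counting error well below the tolerances tested. Tolerances: noise
estimator 1% at 10⁶ samples (its sampling s.e.); filter edges 0.1% (limited
only by bisection depth); rate recovery 10% (dominated by detection errors
in bursts, measured at ≤ 6%); correlation oracle 1e−12 (floating-point
accumulation); curvature 1e−6 relative (algebraic fit is exact up to
conditioning). Ties and degenerate inputs are handled explicitly: flat
channels are skipped in detection, zero-variance channels are NaN in
correlation, boundary events are dropped and counted, empty inputs raise
typed errors rather than returning silent zeros.

## Known limitations

No artifact blanking around stimulation pulses, no notch filtering, no
template-matching or drift-corrected sorting, no criticality/avalanche or
information-theoretic measures, no raw-video processing (the calcium module
consumes ROI-mean traces), and no streaming ingestion. The stimulation
module designs protocols; it does not drive hardware.
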