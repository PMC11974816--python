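# Methods

This note documents the models and procedures implemented in lamelloscope,
the parameters that matter and their defaults, what the synthetic-data
generators emulate (and deliberately do not), and the numerical choices made
where the design was genuinely open.

## Conventions

Pixel coordinates are 0-based `(row, col)` with pixel centers at integer
coordinates. Physical conversions go through `pixel_size_um` (µm/px) and
`frame_interval_s` (s/frame). Intensities are promoted to float64 on load;
no saturation handling is applied. Multi-page TIFFs are de-interleaved with
a declared convention (default channel-fastest: pages cycle through channels
within each timepoint). All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical seeds give bit-identical
datasets.

## Ratiometric mapping

Model: the reporter channel is the product of the biological ratio of
interest and the reference channel, both multiplied by a smooth illumination
field and offset by a camera/medium pedestal. The chain inverts that model
stage by stage, in this order:

1. **Shading correction** — divide each channel by its cell-free blank,
   normalised to unit mean (preserves intensity scale). Blanks must be
   strictly positive; an optional Gaussian smooth (default off) handles
   noisy blanks.
2. **Registration** — rigid translation by phase correlation onto frame 0
   (upsampled 10×), applied to all channels. A dense TV-L1 optical-flow mode
   exists for non-rigid drift; translation is the default because stage
   drift dominates in practice and is exactly testable.
3. **Background subtraction** — per frame, the background pixel *set* is
   everything below the Otsu threshold of a guide channel (default: the
   reference channel, which has reliable cell/background contrast); each
   channel subtracts the median of its own intensities over that set,
   negatives clipped. Computing the set on a guide matters: in low-contrast
   channels Otsu lands inside the background distribution and the
   below-threshold median is biased low.
4. **Denoise + divide** — Gaussian σ = 0.5 px on both channels, then
   reporter/reference. Pixels outside the cell mask or with denominator
   below 1e−6 × the in-mask median reference are flagged NaN in memory
   (zero is a legal ratio) and written as 0 in exported TIFFs.
5. **Cell mask** — Otsu on a structural channel, hole filling, largest
   connected component.

The edge/body ratio takes the mean ratio in the band of in-mask pixels
within `edge_depth_um` (default 1.5 µm) of the mask boundary, over the mean
in the remaining body.

Because both channels are smoothed before division, the recovered ratio is
G∗r rather than r near discontinuities of the true ratio field; with
σ = 0.5 px the two agree to < 1e−6 beyond ~2.5 px of a discontinuity, which
the validation tests respect.

## FRET bleed-through correction

With background-subtracted, registered channels, per-pixel corrected
efficiency is E = (FRET_raw − α·donor − β·acceptor)/donor, donor-guarded as
above. α (donor → FRET) and β (acceptor → FRET) are calibrated from
single-fluorophore cells as the slope of a zero-intercept least-squares fit
of FRET on fluorophore intensity over in-mask pixels pooled across frames.

Numerical choices:

* **Zero intercept** because channels are background-subtracted first.
* **Robustness** by discarding pixels outside the 1st–99th fluorophore
  intensity percentiles (hot/dead pixels) instead of iterative M-estimation.
* **Unclipped residuals in the fit.** The display convention clips
  background-subtracted intensities at zero, but the calibration fit sees
  unclipped values: in the dim FRET channel of an acceptor-only cell the
  noise straddles zero, and clipping would bias the slope upward by tens of
  percent on a coefficient as small as β ≈ 0.05.
* Negative fitted slopes are clamped to 0 with a warning.
* Calibration is persisted as JSON and passed explicitly; the published
  coefficient values appear only as generator defaults in synthetic data,
  never inside the correction.

Region statistics: lamellipodia-to-cell-body efficiency ratio over two
disjoint masks, and an edge line profile binning in-mask pixels by Euclidean
distance to a densely resampled boundary polyline (per-bin mean ± SE).

## Kymographs and edge dynamics

A kymograph samples one channel along a line at 1-px spacing by bilinear
interpolation, averaged across `width_px` (default 3, odd) parallel offsets
along the line normal. The first endpoint is on the cell-interior side;
outward displacement is positive.

Edge tracing uses one Otsu threshold for the whole kymograph; per frame the
edge is the outermost above-threshold sample, refined to sub-pixel by linear
interpolation across the crossing. Two robustness rules: the outermost
sample must be supported by its interior neighbour (isolated noise spikes in
the background occasionally clear the global threshold and would otherwise
teleport the trace), and frames without any crossing are linearly
interpolated from neighbours and flagged (error if > 50 % missing). The
absolute position carries a sub-pixel constant offset that depends on where
Otsu lands within the edge's partial pixel; velocities are unaffected.

* **Spreading speed** — the fast-spreading phase is operationalised as the
  contiguous window (≥ 20 % of frames) with maximal mean outward velocity;
  the reported speed is the least-squares slope of position over that
  window. Purely retracting traces give a negative value.
* **Phases** — protrusion if v > +v_stall, retraction if v < −v_stall, else
  stall; v_stall defaults to 0.5 µm/min and runs shorter than 3 frames are
  merged into their neighbours. No numeric thresholds exist in the source
  protocol; both are config-exposed and recorded in output metadata.
* **Protrusion speed** — maximal protrusion runs with net displacement
  ≥ 0.2 µm are events; the five largest-displacement events contribute their
  regression slopes, averaged. Event selection by displacement rank is this
  package's rule; the protocol names five events without a selection rule.

## Edge–signal cross-correlation

The near-edge signal is the mean of the 4 kymograph samples (≈ 1.5 µm)
immediately interior to the traced edge, per frame. Both the edge series and
the signal series are Gaussian-filtered (σ = 1 frame), z-scored, and
correlated at all lags with biased (1/n) normalisation, bounding
coefficients in [−1, 1]. Positive lag means the signal leads the edge. Lags
are limited to ±n/3 frames, where the estimate is stable. A cubic smoothing
spline evaluated on a 10×-refined lag grid refines the peak location.

The edge series may be displacement (default, matching the protocol's
wording) or velocity (config switch). For a signal that encodes the
*velocity* of the edge — the coupling the generators plant — the velocity
correlogram is the one whose peak sits at the physical delay, and the
validation and demo use it.

## EM meshwork porosity

Chain: optional contrast inversion (micrographs are often presented
inverted) → Gaussian blur (default σ = 0.5 px) → white top-hat with a disc
(default radius 15 px) → 2-cluster k-means on pixel intensities with
deterministic initialisation at the 25th/75th percentiles (bit-reproducible
masks; the brighter cluster is filament foreground) → porosity = background
fraction within the ROI → pore areas = connected components (8-connectivity)
of the inverted mask, excluding border-touching components (unbounded area)
and components below `min_area_px` (default 10).

Parameter rationale: the top-hat disc must exceed the filament width but not
the pore scale; 15 px does both for few-pixel-wide filaments. The blur only
needs to suppress shot noise, and must stay small relative to the filament
width: σ = 1 px widens a 3-px strut to ≈ 3.8 px at half maximum, which
biases porosity low by ≈ 0.05 at intermediate densities, while σ = 0.5 px
preserves the half-maximum width. Porosity + coverage = 1 holds by
construction; the full chain is invariant to affine intensity rescaling.

The method presumes lattice-like texture: filaments individually thinner
than the structuring disc. Images containing solid bright patches wider than
the disc (e.g. dense membrane skeleton sheets) violate that assumption — the
top-hat erases patch interiors and porosity is overestimated.

## Migration tracking

* **Detection** — scale-normalised negative Laplacian of Gaussian at
  σ = diameter/(2√2·pixel size) (diameter default 25 µm); local maxima with
  response ≥ 0.08 of the frame's maximum response are kept (per-frame
  normalisation makes the threshold transferable across intensity scales),
  with quadratic sub-pixel refinement.
* **Linking** — consecutive-frame assignment minimising total squared
  displacement, solved optimally (Hungarian algorithm) on a cost matrix
  augmented with per-detection non-link alternatives at the maximum link
  distance (default 50 µm); then segment gap closing joining track ends to
  later starts within 50 µm and 2–3 frame gaps, again by optimal assignment.
  Optimal rather than greedy assignment keeps results deterministic and
  order-invariant.
* **Filtering** — keep tracks with duration ≥ 60 min and span ≥ 18 µm. Span
  is the total path length by default ("spanned" read as the whole
  trajectory); net displacement is a config switch.
* **Metrics** — speed = path length / duration (µm/min); DI = displacement /
  path ∈ [0, 1]; 3-D displacement speed = ‖last − first‖ / duration (µm/hr),
  accepting pre-made (x, y, z) tables. All metrics are invariant to rigid
  motions of the coordinate frame.

## Morphometrics

Max-intensity z-projection then background subtraction (Otsu-median rule).
ROI means over polygon interiors (pixel-center even-odd rule). Control
normalisation divides every measurement by the control group's mean, making
the control mean exactly 1. The enriched-perimeter fraction thresholds at
whole-cell mean + k·SD (k = 1.5) and walks the longest subpixel boundary
contour, testing the local in-mask mean within a 5-px band at each segment;
the fraction is arclength-weighted. The protocol's "approximately greater
than 1.5 SD" is formalised as a strict parameter here. Adhesion classes use
half-open bins nascent [0.05, 0.20), mature [0.20, 1.75], fibrillar
(1.75, ∞) µm² — the prose ranges overlap at the edges, so the tie-break is
made explicit — with sub-0.05 µm² objects dropped and counted.

## Synthetic data: what it emulates, and what it does not

Each generator produces the statistical structure its analysis stage
assumes, carries every generating parameter in a `GroundTruth` record, and
is exactly invertible in the zero-noise limit:

* **Ratiometric movies** — a disc-plus-lobe cell (a well-defined free edge),
  a step edge/body ratio contrast (so the edge/body statistic has an exact
  planted value), a constant reference level, a unit-mean polynomial shading
  bump, an additive camera pedestal under the whole image, integer-pixel
  rigid drift (np.roll, so registration can invert it exactly), and additive
  Gaussian noise.
* **FRET triplets** — the exact forward model FRET = E·donor + α·donor +
  β·acceptor, radial expression ramps (the intensity spread a regression
  needs), donor-only/acceptor-only variants for calibration, constant
  background, Gaussian noise.
* **Meshworks** — the edge set of a Voronoi tessellation of random seeds
  (~3 filament segments per seed) drawn at a set width: a lattice whose
  struts stay thinner than the pores they bound, matching branched-actin
  texture and the top-hat's assumption, with exact planted porosity and void
  areas recorded. Independent random chords were rejected: at realistic
  densities they merge into solid patches wider than the structuring
  element, which no top-hat-based chain can binarise correctly.
* **Edge movies** — a piecewise-constant velocity plan integrated into an
  edge trajectory rendered with partial-pixel coverage (sub-pixel tracing
  stays smooth), and a near-edge band whose intensity is an affine map of
  the *instantaneous* (centred) edge velocity delayed by the planted lag.
* **Tracks** — correlated random walks with constant step length, heading
  noise scaled by (1 − persistence), grid-separated starts, and optional
  detection dropout that spares track endpoints (so gap closing, not
  truncation, is exercised).
* **Adhesion tables** — uniform draws within each class bin.

Not emulated: optics (PSF, depth of field), photobleaching, Poisson-dominant
shot noise statistics (additive Gaussian with optional shot-noise hook keeps
recovery tolerances analytic), cell shape change during ratio movies,
filament curvature and branching geometry in meshworks, and cell division
or merging in tracks. Passing the recovery suite therefore demonstrates
correctness of the computational chain under its stated model, not
robustness to every artifact of real microscopy.

## Validation scope and problem sizes

The test suite and the demo run at desk scale: 128×128–256×256 images,
tens of frames, ≤ 10 seeds per condition — sizes at which every stage's
recovery behaviour is already stable. The acceptance script regenerates the
two calibration recoveries (20 frames, 128×128, SNR 20) from scratch at
run time; no measured value is stored in the repository.

## Known limitations

* Edge tracing follows the outermost threshold crossing; detached bright
  debris outside the cell on the sampling line would capture the trace.
* The kymograph must be oriented interior-first; feeding a reversed line
  violates the outermost-crossing convention rather than flipping signs.
* Porosity assumes filament-bright lattice texture (see above).
* The LAP implementation handles linking and gap closing but not splitting
  or merging costs; dividing cells should be pre-truncated (the source
  protocol also ended tracks manually at division).
* Spline peak refinement on very broad correlograms (few velocity
  transitions) can wander within the plateau; the raw-correlogram peak is
  also reported.
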