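# lamelloscope

Quantitative image analysis for lamellipodial signalling and cell motility:
ratiometric Ca²⁺ imaging, FRET biosensor bleed-through correction, kymograph
edge dynamics, edge–signal cross-correlation, electron-microscopy actin
meshwork porosity, and single-cell migration tracking — with a synthetic-data
generator so every stage is validated by parameter recovery, no microscopy
data required.

## Who this is for

Cell biologists and image analysts quantifying leading-edge (lamellipodial)
dynamics in migrating or spreading cells: how a second messenger such as
Ca²⁺ or a GTPase activity reporter such as a RhoA FRET biosensor co-varies
with membrane protrusion, how the branched actin network's density changes,
and how those molecular events translate into whole-cell motility.

## What it computes

**Ratiometric maps.** A reporter channel (e.g. GCaMP6f) divided by a
co-expressed reference (e.g. mCherry) cancels expression and path-length
artifacts. The chain is: flat-field (shading) correction with a cell-free
blank → rigid registration onto the first frame → per-frame background
subtraction (median of the below-Otsu pixels) → Gaussian denoise (σ = 0.5 px)
→ reporter/reference division → logical AND with an Otsu cell mask.
Summary statistic: edge/body ratio, the mean ratio in an edge band over the
mean in the remaining cell body.

**FRET efficiency.** For a donor (mTFP1) / acceptor (mVenus) biosensor the
FRET channel is contaminated by spectral bleed-through. With
background-subtracted channels,

```
E = (FRET_raw − α·mTFP1 − β·mVenus) / mTFP1
```

where α and β are the donor and acceptor bleed-through fractions, calibrated
from cells expressing a single fluorophore as the zero-intercept regression
slope of FRET on fluorophore intensity (published values: α = 0.3072,
β = 0.05228 — always recalibrated, never assumed).

**Edge dynamics.** Kymographs (3-px-wide line normal to the free edge,
bilinear sampling), sub-pixel edge tracing by outermost threshold crossing,
spreading speed (regression slope over the max-mean-velocity window),
protrusion speed (mean slope of the five largest protrusion events), and
protrusion / stall / retraction phase labels.

**Edge–signal coupling.** Near-edge signal (mean of the 4 pixels inside the
traced edge) cross-correlated with edge motion: both series
Gaussian-filtered (σ = 1 frame), z-scored, normalised cross-correlation over
lags with a smoothing-spline-refined peak. Positive lag = signal leads the
edge.

**Meshwork porosity.** Platinum-replica EM images: Gaussian blur → white
top-hat (extracts filaments thinner than the structuring disc) → 2-cluster
k-means binarisation (deterministic percentile initialisation) → porosity =
background fraction, plus pore areas from the inverted mask.

**Migration tracks.** LoG nucleus detection (diameter 25 µm, quality ≥ 0.08),
LAP-style optimal-assignment linking (max 50 µm) with gap closing (50 µm,
≤ 3 frames), filters (≥ 60 min, ≥ 18 µm span), then speed = path/duration
and directionality index DI = displacement/path; 3-D speed =
displacement/duration.

**Morphometrics.** Max-intensity projection + background subtraction, ROI
means normalised to control, marker-enriched perimeter fraction
(mean + 1.5 SD rule), and focal-adhesion classification by area:
nascent [0.05, 0.20) µm², mature [0.20, 1.75] µm², fibrillar (1.75, ∞) µm².

## Worked example

The bundled end-to-end demo generates one synthetic dataset per stage,
analyses it, and writes a manifest with the recovered versus planted values:

```sh
lamelloscope run --outdir demo
cat demo/manifest.json
```

Output (seed 0):

```
"ratio":         { "edge_body_ratio": 1.4822, "true": 1.5 }
"fret":          { "alpha": 0.30720, "beta": 0.05229 }
"edge_coupling": { "peak_lag_s": 27.0, "true_lag_s": 30.0 }
"porosity":      { "porosity": 0.6561, "true": 0.6561 }
"tracks":        { "n_tracks": 10, "mean_di": 0.380 }
"adhesions":     { "fractions": { "nascent": 0.3, "mature": 0.5, "fibrillar": 0.2 } }
```

Reading: the Ca²⁺ edge/body contrast planted at 1.5 is recovered within
1.2 %; the bleed-through coefficients generated at 0.3072/0.05228 are
recovered to four decimals; the 30 s edge–signal delay is localised within a
third of a frame on the spline-refined correlogram; meshwork porosity is
recovered exactly at this noise level; ten migration tracks survive the
duration/span filters with the expected moderate directionality for a
correlated random walk; and the planted 30/50/20 adhesion-class mix is
reproduced.

Each stage is also a subcommand (`synth`, `ratio`, `fret`, `kymo`, `xcorr`,
`porosity`, `measure`, `adhesions`, `track`) and a plain Python API, e.g.:

```python
from lamelloscope.synthetic import simulate_fret_triplet
from lamelloscope.fret import estimate_bleedthrough

stack, truth = simulate_fret_triplet(variant="donor-only", alpha=0.3072,
                                     n_frames=20, noise_sd=50.0, seed=1)
cal = estimate_bleedthrough(stack, "donor")
print(cal.alpha)        # 0.30704 — within 0.1 % of the generating value
```

## Layout

```
src/lamelloscope/
  core_io.py        ChannelStack/BinaryMask, TIFF + CSV I/O, config, logging
  synthetic.py      ground-truth generators for every input class
  ratiometric.py    shading, registration, background, ratio maps
  fret.py           bleed-through calibration + corrected efficiency maps
  edge.py           kymographs, edge traces, speeds, phases
  coupling.py       cross-correlation lag analysis
  porosity.py       EM meshwork porosity and pore sizes
  morphometrics.py  ROI stats, enriched perimeter, adhesion classes
  tracking.py       LoG detection, LAP linking, migration metrics
  cli.py            `lamelloscope` entry point
docs/methods.md     models, parameters, validation scope, limitations
```
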