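# Methods

`uptakequant` quantifies how human B cells take up large antigen-coated
particles (bacteria, micron-scale beads) from two kinds of image data: single
cell event images from an imaging flow cytometer, and time-lapse ratiometric
FRET biosensor movies of RAC1 activation during engulfment. This note
documents the models, the parameters that matter, the synthetic data the
package validates itself against, and the numerical choices made where the
design was open.

## 1. Internalization scoring of event images

### Model

Each event is a four-channel image of one cell (brightfield, nuclear stain,
surface marker, particle fluorescence) with a known pixel size. The analysis:

1. **Cell segmentation** — Otsu threshold on the surface-marker channel
   (the highest-contrast stain covering the whole cell footprint), hole
   filling, largest connected component (8-connectivity). Cell size is
   summarized as the equivalent-circle radius R = √(area/π) in μm.
2. **Particle segmentation** — a particle is *present* when some pixel of the
   particle channel exceeds the channel median by k·σ (k = 5, σ the scaled
   median absolute deviation); its mask is the largest component above
   max(Otsu, median + k·σ). Absence is a value, not an error.
3. **Centroids** — intensity-weighted centroids computed over the mask
   dilated by 3 px. The dilation matters: a hard threshold truncates the
   symmetric blur skirt of a small particle and biases its centroid by
   ~0.2 px, which is visible in the score when the centroid distance is
   small.
4. **Focus gate** — both pipelines only make sense when cell and particle
   are imaged in the same focal plane. Sharpness is measured per channel as
   the gradient RMS over the object mask, normalized by the mean
   background-subtracted in-mask intensity and by the pixel size (units:
   per μm). An event passes when the cell metric ≥ 0.45 and, if a particle
   is present, the particle metric ≥ 1.2. Gated-out events are labelled
   `excluded_unfocused` and removed from every denominator except the total
   event count.
5. **Score** — with d the cell-to-particle centroid distance,

       s = R / max(d, ε),        ε = 0.33 μm (one native pixel)

   Membrane-bound geometry (particle centroid just outside the membrane,
   d = R + D/2) gives s < 1; a particle at half radius gives exactly s = 2;
   deeper particles give larger s. Events with s ≥ τ (default τ = 2) are
   classified `internalized`, others `bound`. The alternative reading of a
   radius-corrected distance as a depth in μm, s = R − d, is available via
   `formula="depth"`; the ratio form is the default because it is
   dimensionless and its natural decision boundary coincides with τ = 2.
   ε is a *fixed physical* floor rather than the current image's pixel size:
   tying it to the pixel would make the score of a nearly-concentric
   particle change under rescaled acquisition of the same scene, breaking
   scale invariance.
6. **Cohort summary** — gating chain
   `n_total ≥ n_focused ≥ n_particle_positive ≥ n_internalized`, with
   % interacting = particle-positive / focused and
   % internalized = internalized / particle-positive (undefined, reported
   as NaN, when no event is particle-positive). Time courses of
   % internalized are reduced to a trapezoidal area under the curve in
   %·min.

### Focus-gate calibration

The sharpness cutoffs were calibrated once against the generator's sharp
(optical blur 0.15 μm) and defocused (particle blur 1.0 μm) populations,
150 events per class at 0 and 50-count noise. The particle metric separates
cleanly (sharp minimum 1.68 vs defocused maximum 0.89 → cutoff 1.2, roughly
the geometric midpoint). The cell metric separates weakly (sharp minimum
0.50 vs defocused-cell maximum 0.49 → cutoff 0.45); in practice the gate's
work is done by the particle channel, and the cell cutoff mainly rejects
grossly defocused cells. The cutoffs are frozen constants in
`uptakequant.events`, not refit at run time.

### Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| τ (`threshold`) | 2.0 | — | internalization decision boundary on s |
| ε (`epsilon`) | 0.33 | μm | centroid-distance floor (one native pixel) |
| k (`detection_k`) | 5 | — | particle-detection noise multiple |
| cell focus cutoff | 0.45 | /μm | minimum cell sharpness |
| particle focus cutoff | 1.2 | /μm | minimum particle sharpness |

## 2. Ratiometric FRET biosensor pipeline

### Model

The single-chain biosensor reports active GTP-bound RAC1 as increased FRET:
activation is read as the acceptor (Venus) over donor (Cerulean3) emission
ratio. With β the fraction of donor emission leaking into the acceptor
channel, the corrected per-pixel ratio is

    F = (V − β·C) / C

computed after (in this order): per-frame background subtraction (median
outside the cell mask, clipped at 0), integer-pixel alignment of every frame
to the first (phase cross-correlation of the donor channel, identical shift
applied to all channels), and 3×3 uniform mean smoothing of both
fluorescence channels. Background correction must precede the β subtraction
because β multiplies the background-free donor signal; on the noiseless
forward model this ordering inverts the generator exactly. A threshold on
the acceptor channel only (default: median + 3 scaled-MAD) sends background
pixels to NaN; above-threshold pixels with zero donor signal are also NaN
(division guard, counted and logged).

β defaults to 0.62 and can be recalibrated with `estimate_bleedthrough`:
pooled in-cell pixels of donor-only cells, least-squares slope of
background-corrected acceptor vs donor. Note a small attenuation bias is
inherent to this regression (the donor regressor carries shot/read noise);
at 2% noise and the synthetic brightness spread it is ≈ 0.008, well inside
the ±2-point calibration tolerance used here.

Localized activation is summarized per frame as the **activation ratio**
A(t) = mean F in a membrane ROI / mean F in a cytosol ROI, both restricted
to the angular sector (half-angle 45°) centered on the cell-centroid →
particle-centroid direction. The membrane ROI is the in-mask band within
1.0 μm of the mask boundary (Euclidean distance transform); the cytosol ROI
is the deeper in-sector remainder. Means are NaN-aware; frames without a
particle, or with an empty ROI, report A as missing rather than 0.

The 1.0 μm membrane width deserves a note. The 3×3 mean filter mixes ratio
values across the band/cytosol interface over roughly one pixel on each
side. At the default 0.065 μm/px a 0.5 μm band is ~8 px wide and the mixed
pixels are a fifth of the ROI, biasing A of a genuinely 2×-activated sector
down to ~1.9; at 1.0 μm the bias is 2–3% (measured A ≈ 1.95). 1.0 μm also
matches the thickness of the actin-rich cup at the contact site, so it is
both the numerically and biologically sensible default. Both the width and
the sector half-angle are configurable.

### Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| β (`beta`) | 0.62 | — | donor→acceptor bleed-through fraction |
| acceptor threshold | median + 3·MAD | counts | NaN gate on the Venus channel |
| smoothing kernel | 3×3 | px | uniform mean filter |
| membrane width | 1.0 | μm | membrane ROI thickness |
| sector half-angle | 45 | ° | contact sector around the particle direction |
| registration | integer px | — | subpixel alignment is out of scope |

Heatmaps render finite ratios through a perceptually ordered blue→red LUT
(`coolwarm` by default) over a configurable range; out-of-range values clip
to the endpoints and NaN renders black.

## 3. Synthetic data generator

The generator is first-class, tested code; it defines the conditions every
validation in this package runs under.

**Event images** (default 64 px at 0.33 μm/px, 16-bit-range counts): the
cell is an anti-aliased disc (radius N(3.5, 0.3²) μm, clipped to
[2.8, 4.2] — a ~7 μm cell), with a darker brightfield disc, a nuclear inner
disc (0.55 R), a uniform surface-marker disc (1000 counts over a
100-count background) and a particle disc (4000 counts; bacterium 1.0 μm or
bead 3.0 μm diameter). All channels get a 0.15 μm Gaussian optical blur;
off-plane events blur the particle channel with σ = 1.0 μm instead. Noise
is additive Gaussian (default 50 counts = 5% of the cell signal), chosen
over Poisson for simplicity since every downstream contract is
tolerance-based. Class geometry: `bound` places the particle centroid
exactly at R + D/2; `internalized` draws the centroid distance uniformly
from the *inner half* of the admissible range [0, (R − D/2)/2], emulating
the perinuclear position of phagosomes after uptake (internalized particles
traffic to antigen-loading compartments deep in the cell); `off_plane`
places it anywhere laterally.

**FRET stacks** (default 208 px at 0.065 μm/px — a 63× objective with 1.6×
optovar on 6.45 μm camera pixels — cell radius 5 μm, 12 frames at 0.5 min):
the donor signal is brightness · (1 − 0.3 (r/R)²) on the cell footprint
(cells are thinner at the rim), the acceptor is (a + β) times the donor
signal plus background, where the true activation map a(x, t) is baseline
1.0 on the footprint and 2.0 inside the membrane-proximal contact band
during the engulfment frames (4–8 of 12 by default). Frames are translated
by integer drifts before noise. Donor-only calibration cells draw radius
U(3.5, 5) μm and brightness U(0.7, 1.3)×nominal so pooled intensities span
a range the regression can use.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: Poisson photon statistics, optical
point-spread functions (discs have linear 1-px edges plus Gaussian blur),
rod-shaped bacteria, multiple particles per cell, photobleaching, spectral
cross-excitation, autofluorescence, cell-shape irregularity and membrane
ruffling. Results on synthetic cohorts validate the *computational*
contracts (geometry → score → label; forward model → ratio → A), not
instrument-specific robustness.

## 4. Validation at a glance

The test suite checks, among others (sizes chosen to keep the default run
fast):

- on a 400-event cohort (equal class mixture, 5% noise) every off-plane
  event is excluded by the focus gate and ≥95% of the remaining events
  receive their true label (measured: 100%);
- the segmented score agrees with the score computed from true geometry
  within 5% on noiseless events (worst observed 3.0% over 160 events);
- the full ratiometric chain inverts the noiseless forward model to
  ≤ 1e-6 and, at 2% noise with ≤5 px drift, recovers the activation map
  with <5% median error and reads A = 2 ± 5% on a 2×-activated sector;
- β̂ from 50 donor-only cells at 2% noise recovers 62% within ±2 points;
- identical config + seed reproduce all output tables bit-identically.

## 5. Known limitations

- Cell defocus separation of the sharpness metric is weak (see calibration
  above); the gate is reliable for particle defocus, which is what the
  shared-focal-plane requirement is about.
- The score's ε floor makes s insensitive to centroid distances below one
  native pixel; ranking among deeply internalized particles is not
  meaningful there.
- Integer-pixel registration leaves sub-pixel jitter uncorrected; at the
  default pixel size this is ≤ 0.03 μm.
- `estimate_bleedthrough` uses ordinary least squares and inherits its small
  attenuation bias under donor noise; a measurement-error model is out of
  scope.
- The membrane/cytosol ROI geometry is a declared convention (band width,
  sector angle), not derived from data; A(t) values are comparable only
  under a fixed convention.
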