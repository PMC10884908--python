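# Methods and design notes

This note documents the models, parameter choices and numerical conventions
behind `sheetscan`, what the synthetic data do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic scene model

Every component is validated against synthetic dishes rendered by
`sheetscan.synthetic`, which is first-class, tested code. A scene is a pure
function of its `SceneParams` (including the seed); identical parameters give
bit-identical arrays.

**Shading.** The pattern sheet (default: 450 µm circular holes on a 900 µm
square lattice) is rasterized at the scene's pixel size (default 10 µm/px,
the scanner camera resolution at 2400 dpi) and mapped to
`white_level = 0.85` / `black_level = 0.15`. A Gaussian low-pass with
σ = 680 / (2·1.2816) ≈ 265.3 µm makes the 10–90 % transition across a
*straight* boundary span ≈ 680 µm, the empirically observed visualization
band. For holes whose radius is comparable to σ (the 450 µm hole's 225 µm
radius is smaller), curvature keeps the profile from reaching the white level
and the apparent band is narrower; the width test therefore measures across a
locally straight boundary (a 6 mm hole). Patterns whose pitch is below twice
the blur are rejected: their bands would merge and no flat zones would
remain. The actual black/white levels and noise statistics of a real scanner
are not published anywhere we know of; the defaults are free parameters, not
calibrated values.

**Cells.** A cell (diameter drawn uniformly from 15–20 µm, the size range of
the cultured cells this method targets) is stamped into the scan as a
zero-mean radial dipole — a bright and a dark crescent, footprint
≈ diameter + 2 px — mimicking how refraction displaces light across a shading
gradient without claiming optical fidelity. Its amplitude is

```
cell_amplitude · (vc · g + (1 − vc)) · illum(shading)
```

with `g` the normalized local shading-gradient magnitude, `vc` the
*visibility coupling* (default 0.8), and `illum` a deep-shadow attenuation
ramping from 0.15 at the black level to 1.0 at 30 % of the black→white span.
With `vc = 1` a cell in a flat shading zone vanishes exactly (a directly
tested property); the `illum` factor is what creates genuine blind spots in
the darkest lattice interstices while leaving cells in moderately dark areas
detectable — matching the observation that blind-spot losses are a
percent-level, not a dominant, error. Defaults (`cell_amplitude = 0.15`,
`noise_sd = 0.001` additive Gaussian, clipped to [0, 1]) were chosen once as
a realistic operating point: cell cores saturate the ×200 display map while
the noise floor (≈ 0.15 on that map) stays below the gray-support threshold.

**Placement.** Uniform rejection sampling with a 100× retry budget; requested
counts that cannot be placed raise an error naming the achievable maximum.
The minimum separation is one mean cell diameter but never below 2.5 px: at
10 µm/px a 15 µm cell is 1.5 px, and two nuclei spots that close cannot be
resolved on the pixel grid at any threshold, which would silently break the
nuclei-count conservation invariant the generator guarantees (the threshold
0.3 used by `count_nuclei_blobs` sits below the worst-case off-grid peak
value e⁻¹ ≈ 0.37 of a σ = 0.5 px unit spot and far above the midpoint value
of two spots at minimum separation).

**Companion channels and debris.** The phase image carries small bright
blobs (σ ≈ 0.9 px) at cell positions over a flat 0.25 background — a
stand-in for phase-contrast halos at scanner-matched resolution — and the
nuclei image carries tight σ = 0.5 px spots. Debris (default 5 per dish,
≈ 2.5 % of the default 200 cells, consistent with percent-level image-origin
error rates in practice) is stamped in scan and phase but never in nuclei,
so it is countable downstream as an image-origin false positive. Debris
amplitude is not gradient-modulated.

**Growth series.** Exponential growth with optional logistic cap; frame *t*
holds `round(curve(t))` cells, and earlier frames' positions are a prefix of
later frames', so fixed fields of view see a coherent history. A single
frame reduces exactly to `render_scene`.

**What the generator does not emulate:** confluent colonies and spheroids,
cell morphology, optical photorealism, scanner vignetting, or focus drift.
Tests passing on these scenes show the *pipeline logic* is correct under the
stated image model; they are not evidence about any particular real scanner.

## 2. Information volume map and metrics

The IVM follows the reference recipe exactly: σ = 1.0 background blur,
positive and negative residuals truncated at zero, each re-blurred with
σ = 1.5 and summed; amplification ×200 for display, ×100 for object
contrast, clipped at 1.0. Gaussian kernels are truncated at 4σ with
replicate borders — the convolution oracle in the tests applies the same
rule, so equivalence is checked to < 1e−10. Residuals below
16·eps·max(1, |img|∞) are zeroed so a constant image maps to an exactly zero
IVM rather than an O(1e−17) field.

Conventions the reference description leaves ambiguous, fixed here and
tested against oracles: brightness *deviation* is the sample SD (N−1);
*object contrast* is the population variance (N) of the ×100 map;
cross-entropy uses the natural logarithm with the prediction clamped to
[1e−7, 1 − 1e−7], and consumes the ×200 display map; the *local brightness
difference* is max − min over a disk of 10 px radius (the operator itself is
not specified in the source, only the radius).

## 3. Phase-contrast segmentation

White top-hat (disk radius 1) → Gaussian blur σ = 0.75 → power enhancement
x^0.15 → Otsu threshold → removal of 8-connected components under 2 px.
Enhancement precedes thresholding because a power law after binarization
would be a no-op; Otsu stands in for the unspecified automatic threshold.
The binarized support is additionally intersected with the strictly positive
top-hat response before the area rule: the blur propagates evidence outward
but should not create support where the top-hat saw nothing. Without this
restriction a 1-px speck blurs into a ~40 px supra-threshold blob that the
area < 2 rule could never remove; with it, the speck is a single-pixel
component and is removed, while real cell blobs (whose top-hat support spans
several pixels) are unaffected. A constant image yields an empty map (the
threshold degenerates); this is documented behaviour, not an error.

## 4. Detection

The production counterpart of this detector is a trained segmentation
network; its published inference contract — clear white areas are cells,
black is background, gray is ambiguous — is implemented here as hysteresis
thresholding: white seeds (≥ 0.5 on the display map) grown into gray support
(≥ 0.2), 8-connected components, area filter (≥ 4 px), and splitting of
merged blobs. Thresholds and size rules were calibrated once on the default
synthetic scene and live in `DetectorConfig`.

Because the display map clips at 1.0, neighbouring cells merge into one
white plateau; `detect_scan` therefore also passes the *unclipped* amplified
IVM, and components containing ≥ 2 intensity peaks at white level separated
by ≥ 3 px are watershed-split at those peaks. Components larger than
`max_single_cell_area_px` with a single peak fall back to
distance-transform-peak splitting. Centroids are intensity-weighted
(weights `(I − gray)²`), which localizes isolated cells to ≈ 0.1 px. Two
cells closer than ≈ 4 px (40 µm) remain one detection — the device's
resolution limit at 10 µm/px, and the origin of lack-of-resolution errors.

The analysis window is a crop of a physically larger scan, so `detect_scan`
pads the window by 16 px of linear edge extrapolation (value and slope taken
from a σ = 2 px smoothed copy so border noise is not amplified) before
computing the IVM; replicate padding instead turns the shading slope at the
crop border into a line of spurious detections.

Whole-vessel counting tiles the scan (512 px tiles, 64 px context overlap)
and assigns each detection to the unique tile whose core rectangle contains
its centroid, so seam cells are counted exactly once without a merge radius.

## 5. Error taxonomy

Matching is greedy one-to-one by ascending distance with ties broken toward
the lower truth index, never beyond `max_dist_px` (default 5 px ≈ 50 µm,
above a cell footprint, below typical nearest-neighbour spacing at the
densities simulated; the evaluation of localization quality uses 2 px).
Greedy matching equals the optimal assignment whenever their total costs
agree, which the tests check against `linear_sum_assignment` on small
configurations.

Unmatched detections: within 5 px of a debris centroid → *image-origin*;
else, nearest truth within the matching radius is a matched cell of diameter
≥ 25 µm (above the 15–20 µm culture range; the source says only "large
cells") → *large-cell*. Unmatched truths: inside the dark-zone mask (shading
below 20 % of the level span) → *blind spot*; else another truth within
2 × median cell diameter → *lack of resolution*. Precedence (image-origin
over large-cell, blind-spot over resolution) is documented and arbitrary.
Remaining items are reported as unclassified; the accounting identities
`matched + overs = n_detected` and `matched + unders = n_truth` are enforced
by construction on every report.

## 6. Pattern geometry

Coverage is the fraction of sheet pixels whose Euclidean distance to the
open/closed interface is ≤ 340 µm (half of the 680 µm band), computed as the
one-sided distance transform on each side minus half a pixel — placing the
interface between the pixel layers to sub-pixel accuracy, which is needed to
match the single-hole annulus closed form π(r+w)² − π(max(r−w,0))² within
1 % at practical raster sizes. The band is applied to the *unblurred*
raster: the 680 µm width is empirical optics, used here as pure geometry.
Hole pitch and lattice are free inputs — the manufactured sheets' layouts are
not published — so the coverage ranking across the four hole sizes is
reported conditionally on a layout, not asserted as a universal optimum.
(With 450 µm holes at 900 µm pitch the default layout measures ≈ 97 %
coverage; `scripts/acceptance.py` recomputes it.)

## 7. Ray-optics demonstration

A deliberately minimal 2-D model (one lateral axis + optical axis): the
diffuse lamp is a 12 mm row of 601 point emitters with uniform emission
within ±30°; the sheet is a perfectly opaque plane with open intervals
(the hole-pattern cross-section) 100 µm above the cell plane; model cells
are circles of 100 µm radius, RI 1.360 in medium 1.335 (a culture-medium
-like default — not a published value, configurable); the sensor is an
ideal binned line 500 µm below (no lens — straight-line propagation).
At each cell-circle intersection a ray scatters into a uniform random
direction with probability `diffusion_ratio = 0.3`, else refracts by
Snell's law (total internal reflection reflects). The "80 % diffuser"
condition replaces the apertures with a plane that re-randomizes ray
direction with probability 0.8.

Geometry rationale: the source is wide enough that the full ±30° cone
arrives at every relevant sensor position, making no-sheet illumination
fully diffuse (so the diffuser condition is statistically equivalent to it),
while the sheet sits close enough to the cells that its shadow penumbra
(≈ source_extent × 100/4900 ≈ 245 µm) stays below the 900 µm pattern pitch.
All per-ray randomness is pre-drawn from the seed, so runs are
deterministic, ray conservation (absorbed + lost + binned = n_rays) is
exact, and two configs differing only in apertures are coupled ray-by-ray —
adding apertures can only add binned light. The model validates the
*qualitative* contrast ordering (sheet ≫ no-sheet ≈ diffuser); it does not
reproduce any quantitative illuminance values, and the with-sheet contrast
metric also picks up the shadow pattern itself, which is why comparisons are
made across conditions at fixed geometry.

## 8. Field-of-view sampling

25 microscope-sized fields (640 × 480 px at 10 µm/px) centered on a regular
5 × 5 grid over the largest centered box inscribed in the vessel mask
(real-world field placements are somewhat irregular; a regular grid is the
reproducible choice). The estimator is the k-field mean count scaled by
vessel/field area; k = 1 reports all 25 singletons, k > 1 draws 5 subsets
without replacement, and time series reuse the same subsets per k so each
line is one fixed set of observation points. The estimator is unbiased by
linearity (verified by full enumeration for k ≤ 3) and its subset variance
follows the finite-population correction (σ²/k)·(25−k)/24 (verified within
20 % by Monte Carlo). The "true" total is the ground-truth count in
synthetic mode or the whole-vessel detection count in pipeline mode.

## 9. Problem sizes and reproducibility

Default dishes are 1024² px (1.05 cm² at 10 µm/px) with 50–500 cells —
densities of ~50–500 cells/cm², the sparse regime where noninvasive counting
matters most; replicate-correlation dishes are 512² px, and the ray tracer
uses 10⁶ rays × 5 seeds per condition. These sizes give stable percent-level
statistics while keeping a full run (test suite or acceptance script) in the
minutes range on one CPU. All randomness flows from explicit seeds
(`numpy.random.default_rng`); pipeline outputs are written without
timestamps so fixed-seed re-runs are byte-identical.

## 10. Known limitations

- The cell appearance model (zero-mean dipole, gradient-coupled amplitude)
  is a phenomenological stand-in; no claim of optical correctness is made.
- The detector's rule set replaces a trained network; real scans with
  condensation, uneven media or unusual morphologies are out of scope.
- Live/dead discrimination is impossible from this modality.
- Real-data error percentages and R² values depend on the cultures,
  manufactured sheets and trained model of the original measurement and are
  not reproduction targets for the synthetic pipeline; what is reproduced is
  the structure of those results (error classes at percent level, high
  density correlation, FOV spread shrinking with k and density).
- The 2-D ray tracer omits the lens, sheet-material refraction, wavelength
  dependence and 3-D geometry.
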