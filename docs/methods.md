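# Methods

## Imaging model of the synthetic generator

The generator (`sparticle.synth`) emulates how mycelial particles appear in
×10 phase-contrast whole-slide images.  A pellet is rendered as a disk of
core radius *R* with three intensity zones: a dark fringe (default grey 40)
between the edge and the bright ring, a bright ring (default 120) of
configurable width (default 12 px) centred a fraction *f* of the radius
inside the edge (default *f* = 0.2), and a darker interior core (default
65, within the background class).  `n_hyphae` jagged filaments (random
walks of 2 px steps with N(0, 0.2 rad) angular jitter, fixed thickness)
protrude radially from the rim at fringe intensity.  This reproduces the
qualitative phase-contrast signature — dark protruding hyphae, a bright
ring where the dense region starts, a darker interior — that the
segmentation (edge threshold + hole fill) and the radial band profiler
rely on.

Contaminants follow the geometry the filters are designed to catch: air
bubbles are dark annuli wider than 900 µm across (their filled area exceeds
the 6×10⁵ µm² cap), debris specks are below 200 px, and fibers are
rectangles at least 10× longer than wide.

Noise is additive Gaussian (default SD 2 grey levels) clipped to the bit
depth.  At the default contrast the noise cannot cross the 50/90 background
bounds (≥ 7.5 SD away), so thresholding is exercised but not randomized.
A single seeded RNG drives hyphal walks and noise; identical specs render
bit-identically.

What the generator does **not** emulate: no point-spread function or true
phase-contrast transfer function, no focus gradients, no illumination
vignetting, no overlapping/occluding particles, no intensity texture inside
the core.  Passing the recovery benchmarks therefore demonstrates the
correctness of the algorithmic chain under the stated geometry and
contrast, not detection performance on real cultures.

The standard study slide (`random_slide`) is 2048² px (≈ 1.6 × 1.6 mm at
0.78 µm/px) with ten particles of core radius 25–115 px (≈ 40–180 µm
diameter, spanning the fragment/pellet split), one centred bubble, one
fiber and three debris specks, placed on a seeded jittered anchor ring so
that a valid non-overlapping layout exists for every seed.  Twenty such
slides (≈ 200 true particles) form the recovery benchmark; the batch runs
in about a minute on one CPU, which is why this size was chosen over a
full 20×20-tile slide per sample.

## Mosaic assembly

Tiles are placed at their nominal stage offsets — step =
round(tile·(1−overlap)) — with no feature registration, trusting the
motorized-stage geometry; the mosaic footprint is the closed form
tile + (n−1)·step.  In overlap zones the later tile in meander order wins:
deterministic, and seams remain visible for debugging, while blending would
add no analytic value.  Brightness normalization is multiplicative
(illumination fluctuation is a gain effect and a gain preserves zero): each
tile is scaled by reference/background, where the background estimate is
the modal grey value (ties to the lowest mode) and the default reference is
the median of the tile backgrounds.

## Segmentation conventions

* Threshold bounds are inclusive in the background class: a pixel is
  foreground iff value < 50 or value > 90.  Users can move both bounds in
  `SegmentationConfig`.
* Hole filling uses 4-connectivity for the background, components use
  8-connectivity — the standard complementary pair that avoids topological
  paradoxes.
* The watershed operates on the inverted Gaussian blur (σ = 5 px ≈ 4 µm at
  default calibration) of the filled mask, restricted to the mask.  Seeds
  are the regional maxima of the blurred field after quantizing it in steps
  of h = 0.05 on its 0–1 scale.  The quantization suppresses maxima of
  prominence < h: without it, float-level ripples along the flat crest of
  an elongated object (a fiber) spawn dozens of seeds and shatter the
  object into sub-200 px chunks before the rule filter can see it, while
  genuinely separate touching particles — whose peaks are divided by a deep
  saddle at the contact neck — keep one seed each.
* The 150 µm interface rule is operationalized as the cut-line length:
  the number of 4-adjacent pixel pairs between two watershed regions times
  the pixel size.  Cuts at or above 150 µm are undone by re-merging the
  two regions (union–find, evaluated independently per region pair).
* Voronoi influence zones assign every pixel to its Euclidean-nearest
  label, equidistant pixels to the lower label.  The exact tie-break is a
  running minimum over per-label distance transforms; since that costs one
  full-image transform per label, images where size × labels exceeds
  3.2×10⁷ use a single nearest-feature transform instead (its rare ties
  follow scan order).  The inter-zone border marks, for every cross-zone
  8-adjacent pixel pair, the pixel that comes first in scan order, which
  guarantees that subtracting the border leaves no 8-connectivity between
  zones.
* Size bounds are strict on both sides ("smaller than 200 pixels",
  "larger than 6×10⁵ µm²"); surviving labels are renumbered by descending
  area (ties by previous label) for stable, human-friendly ordering.
* The area cap is applied after Voronoi splitting; a bubble survives
  watershed as one region (its blurred interior is a single quantized
  plateau) and is removed there.

## Metric conventions

* **Perimeter** is the 4-direction Crofton estimate.  Chain-code tracing
  with √2 diagonal weights overestimates smooth digital boundaries by
  5–6%, which would push a disk's circularity to ≈ 0.89; the Crofton
  estimator is accurate to a few tenths of a percent, so disks score
  circularity and roughness ≈ 1 as intended.  Circularity is capped at 1.
* **Fitted ellipse**: same normalized second central moments as the mask;
  its perimeter uses Ramanujan's second approximation.
* **Feret diameter**: convex-hull pixel coordinates are rotated in 2°
  steps over [0°, 180°); the vertical extent is (max − min) + 1 px so a
  single pixel has extent 1.  The 2° grid underestimates a true diameter
  by at most 1 − cos(1°) ≈ 0.015%.
* **Morphology number** Mn = 2√(A/π)·S/(Feret·E), normalized so a disk
  scores 1; elongated or ragged particles approach 0.
* **Polar circularity** C = min(1, 2√(A/π)/(3 r̄)) with r̄ the mean
  distance of all mask pixels from the unweighted mask centroid (for a
  disk r̄ = 2R/3, hence the normalization).  Because every pixel counts
  rather than only the perimeter, thin protruding hyphae barely move it.
* **Fractal dimensions**: the mask is cropped to its bounding box and
  zero-padded to the next power-of-two square; boxes of size
  s ∈ {2, 4, …, side/4} are counted and the dimension is the least-squares
  slope of log N(s) against log(1/s).  The mass dimension uses the filled
  mask, the surface dimension its one-pixel inner boundary, and the
  quotient is D_BM/D_BS.  Bounding boxes under 16 px give too few box
  sizes for a slope; those particles carry a `fractal_undefined` flag
  instead of failing.
* **Radial bands**: the Euclidean distance-to-edge transform inside the
  mask (image boundary counts as edge), normalized by its maximum; band k
  of 20 collects normalized depths in ((k−1)/20, k/20], band 1 also depth
  0, so the bands partition the mask exactly.  Bands are therefore
  iso-depth "donuts" that follow the ROI's own shape.  An alternative
  construction by geometric shrinking of the outline polygon would behave
  similarly for convex shapes but is ill-defined for the spiky outlines
  hyphae produce, which is why the distance-transform form was chosen.
* **Halo width**: mean depth (µm) of the band with the highest mean
  intensity; ties go to the outermost band, giving a conservative halo.
* **Density ratio**: count-weighted mean intensity of bands 1..peak over
  bands peak+1..20.  If the peak falls in the innermost band the ratio is
  taken against that band alone and flagged degenerate.  Whether a given
  pellet scores above or below 1 depends on its fringe depth: a thin
  fringe with a broad bright ring yields > 1, while a deep dark hyphal
  fringe can pull the outer mean below the core intensity.  The measure
  still separates dense-core from open-centre ("mat") morphologies, which
  is its purpose — given identical outer structure, a brighter (more
  open) core always lowers the ratio.

## Filtering

Rules are inclusive on both bounds (the size filter's strict "smaller
than" convention applies only there); a particle with an undefined (NaN)
metric fails any rule on that metric.  The shipped default set —
elongation ≤ 6, polar circularity ≥ 0.2, intensity SD ≥ 3 grey levels,
density ratio in [0.2, 5] — implements the two canonical exclusions (long
non-circular fibers; objects deviating from normal pellet density) with
values validated on the synthetic fixtures.  They are deliberately broad
and are expected to be tuned per organism via the YAML form.

## Population statistics

The fragment/pellet split uses the maximum Feret diameter as the
operational "length", strict < 150 µm for fragments.  Confidence ellipses
come from the eigen-decomposition of the 2×2 sample covariance with
semi-axes √(q·λᵢ), q the χ² quantile at the chosen level with 2 degrees of
freedom (5.991 at 95%).  Population comparisons use Welch's unequal-
variance t-test (two-sided): with group variances unknown and typically
unequal, Welch is the safer default over Student's pooled test.

## Known limitations

* Nominal-offset stitching cannot correct stage drift or rotation.
* The interface-length rule measures 4-adjacency counts, which
  overestimates the metric length of strongly diagonal cut lines by up to
  √2; the 150 µm cap is generous relative to realistic necks.
* Fractal dimensions from a single decade of box sizes carry ±0.1-class
  uncertainty; they are comparative descriptors, not precision estimates.
* The default filter values are fixture-validated stand-ins, not values
  fitted to any real culture.
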