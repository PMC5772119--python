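# sparticle

Whole-slide image analysis of mycelial particles — pellets and hyphal
fragments of filamentous microorganisms such as *Streptomyces* — in
phase-contrast micrographs.

Filamentous bacteria and fungi grown in shaken liquid culture form a
continuum of morphologies, from dense roughly-spherical **pellets** to open
mats and small **mycelial fragments**, and this morphology co-determines
growth and product yield.  Assessing it quantitatively needs both image
quality (to resolve single hyphae) and throughput (hundreds of particles per
sample).  `sparticle` provides the analysis side of a whole-slide-imaging
workflow: it stitches motorized-stage tile grids into one calibrated mosaic,
detects and separates candidate particles, filters out contaminants, and
computes a rich per-particle shape descriptor vector.  A synthetic-slide
generator with pixel-exact ground truth replaces the microscope, so the
entire pipeline is testable and benchmarkable offline.

## What it computes

Given a grayscale mosaic calibrated in µm/px (default 0.78 µm/px, a ×10
objective):

1. **Segmentation** — pixels with grey values inside [50, 90] are
   background; darker pixels (hyphae) and brighter pixels (phase rings) are
   candidate edges.  Hole filling turns closed edge contours into solid
   objects; a Gaussian-blur + watershed step proposes separations between
   touching particles, applied only where the contact interface is shorter
   than 150 µm; Voronoi borders make touching objects disjoint; objects
   smaller than 200 px (debris) or larger than 6×10⁵ µm² (air bubbles) are
   discarded.
2. **Rule-set filtering** — a storable YAML list of inclusive bounds on any
   metric, ANDed; the shipped default rejects elongated fibers and objects
   deviating from normal pellet density.
3. **Per-particle metrics** — area *A*, intensity mean/SD, perimeter *P*,
   moments-fitted ellipse, circularity 4π*A*/*P*², roundness
   4*A*/(π·major²), maximum Feret diameter by 2° rotation, roughness
   *P*/*P*<sub>ellipse</sub>, morphology number
   *Mn* = 2√(*A*/π)·*S*/(Feret·*E*) (solidity *S*, elongation *E*; 1 for a
   disk), box-counting fractal mass/surface dimensions D<sub>BM</sub>,
   D<sub>BS</sub> and their quotient, a polar (radial-mass) circularity
   *C* = 2√(*A*/π)/(3·r̄) that protruding hyphae cannot dominate, and a
   20-band radial intensity profile yielding the halo width (depth of the
   bright ring below the edge — the size of the low-density hyphal
   exterior) and the outer/inner density ratio (dense-core pellets vs open
   mat formers).
4. **Population reports** — fragment/pellet split at 150 µm maximal length,
   per-group summary statistics, diameter-versus-polar-circularity scatter
   with 95% confidence ellipses (semi-axes √(5.99·λᵢ) from the sample
   covariance), and Welch two-sample *t*-tests.

## Worked example

```python
import sparticle as sp

spec = sp.random_slide(7)                 # 2048² synthetic slide, seed 7
img, truth = sp.generate_image(spec)      # image + pixel-exact ground truth
particles = sp.segment(img)               # candidate ROIs
metrics = sp.measure_all(particles, img)  # full descriptor table
accepted, rejected = sp.apply_filterset(
    metrics, sp.default_streptomyces_filter())
fragments, pellets = sp.split_population(accepted)
print(len(particles), len(accepted), len(fragments), len(pellets))
```

prints `11 10 8 2`: eleven candidates survive the size filters, the rule
set rejects one (the synthetic cotton fiber, failing
`elongation;sd_intensity`), and the ten accepted mycelial particles split
into eight fragments (< 150 µm) and two pellets.  The first metric rows:

```
 label  feret_um  circularity  polar_circularity  roughness  morphology_number  halo_width_um  density_ratio
     1   205.884        0.495              0.999      1.420              0.752         15.479          0.929
     2   196.015        0.471              0.999      1.455              0.714         18.124          0.885
     3   133.971        0.491              0.998      1.424              0.674          9.450          1.003
```

Note the signature of hyphae-fringed pellets: conventional circularity is
dragged to ≈ 0.5 by the protruding filaments while polar circularity stays
≈ 1.0, and the halo width reports the depth of the bright phase ring (the
start of the dense region) below the particle edge in micrometers.

The same workflow is available from the shell:

```sh
sparticle synth  --config slide.yaml --out tiles/ --seed 7 --tiles 20 20
sparticle stitch --tiles tiles/ --rows 20 --cols 20 --overlap 0.10 --out mosaic.tif
sparticle segment mosaic.tif --out-labels labels.tif --out-all all_labels.tif
sparticle measure labels.tif mosaic.tif --out metrics.csv
sparticle filter  metrics.csv --out accepted.csv --rejected rejected.csv
sparticle report  accepted.csv --split-um 150 --out report/
```

## Documentation

`docs/methods.md` describes the imaging model the synthetic generator
emulates, every tunable parameter with its default and units, the numerical
conventions (perimeter estimator, watershed seeding, tie-breaks) and known
limitations.
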