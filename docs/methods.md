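# Methods

This note records the models, estimators, conventions and parameter
choices behind `leafmorph`, and what the synthetic validation does and
does not demonstrate about real micrographs.

## Segmented-image model and outline extraction

Input segmented micrographs are assumed to encode cell outlines in the
green channel over tissue rendered in red (the common convention when
manual segmentation strokes are drawn in green on a red-tinted
projection). The outline mask is `max(green − red, 0) > t`; the
threshold `t` is Otsu's method on the histogram of nonzero differences
by default, or a fixed value. The subtraction makes the mask invariant
to adding a constant to both channels. Non-tissue surroundings are
removed by marking everything outside a tissue polygon (or everything
reachable from background flood-fill seeds) as barrier; cell interiors
are then the 4-connected components of the inverted mask. Outlines act
as 8-connected barriers and interiors are 4-connected, which prevents
diagonal leakage between neighbouring cells. Cell class (pavement vs.
stoma) is assigned from the majority fill color under a palette
(nearest entry within a configurable RGB distance, default 40); there
is no automatic stoma detector — the class information must be present
in the segmentation, as it is in practice when stomata are filled with
a distinct color. Components touching the image border are flagged and
excluded from descriptor statistics by default, since truncated cells
bias every shape measure.

## Shape descriptors

Pixels are unit squares `[x, x+1) × [y, y+1)`; all descriptors are
reported in physical units via the µm/pixel scale.

- **A** — pixel count × scale². Exact for the segmented region.
- **CA, CP** — area (shoelace) and perimeter of the convex hull taken
  over the four corner points of every pixel square. The corner (not
  center) convention guarantees `A ≤ CA`, hence `CC = A/CA ∈ (0, 1]`,
  for every pixel set including 1-px-wide ones. The cost is a ~0.5 px
  margin around the object: for a digitized disk of radius r the hull
  margin caps CC near `(r/(r+0.6))²` (≈ 0.98 at r = 50, → 1 as r
  grows). Waviness comparisons should therefore be made at comparable
  image resolution, which in practice they are.
- **P** — exposed-unit-edge count × scale (the pixel-boundary polygon,
  including interior hole boundaries). Exact for axis-aligned shapes;
  overestimates smooth oblique boundaries by up to 4/π (~27%), e.g. a
  digital disk measures ≈ 8r rather than 2πr, putting its isoperimetric
  circularity near π²/16 ≈ 0.62 instead of 1. The estimator is kept as
  default because it is simple, exactly reproducible and order-exact
  for comparisons at fixed resolution; a 4-direction Crofton estimator
  (`perimeter_method="crofton"`) is available when a low-bias perimeter
  is needed (disk circularity ≈ 0.99).
- **L, W** — sides of the minimum-area enclosing rectangle of the hull,
  found by rotating calipers (the optimum is attained with a rectangle
  side collinear with a hull edge). Symmetric pixel shapes can admit
  several minimum-area rectangles of different aspect; the tie is broken
  deterministically toward the most elongated rectangle, then the
  smallest angle, so that L and W are well-defined quantities.
- **C = 4πA/P²**, **R = A/(L·W)**, **CC = A/CA**, **E = 1 − W/L** —
  standard dimensionless shape indices; C is 1 for a perfect disk under
  an unbiased perimeter estimator, R and CC are 1 for rectangles, E is
  0 for squares/disks and → 1 for needles.

Stomatal density divides the stoma-class object count by the measured
tissue area; when guard cells are annotated individually the count is
divided by a pairing factor of 2 (configurable to 1 for one-object
stomata). No geometric pair-matching is attempted.

## Synthetic epidermis generator

The generator exists to provide exact ground truth for every pipeline
stage; its defaults emulate a potato-leaf epidermis field.

- **Tessellation.** Sites are Poisson-disc sampled (dart throwing with
  minimum spacing `0.7·√(mean cell area)`, deterministically relaxed if
  the target count cannot be placed) and the field is partitioned by
  their Voronoi diagram, clipped exactly to the rectangle by mirroring
  sites across all four edges. Poisson-disc rather than uniform
  sampling avoids degenerate sliver cells and gives a realistic
  cell-size spread. The expected cell count is `field area / mean cell
  area` (default mean 1500 µm²).
- **Wall waviness.** Every interior Voronoi edge is replaced by a
  sinusoidal polyline (amplitude, wavelength and a per-edge random
  phase), pinned at both endpoints by a half-sine envelope and applied
  identically to both adjacent cells, so the tessellation remains an
  exact partition at any amplitude (border edges stay straight, keeping
  Σ areas = field area to float precision). The amplitude is clamped
  per edge at 0.3 × edge length and 0.35 × the edge's clearance (half
  the distance between its two generating sites) so lobes cannot pinch
  a cell shut or invade a neighbour's centre. Defaults: amplitude 2 µm,
  wavelength 30 µm; with the default cell size the clamps stay inactive
  across the 0–6 µm amplitude range, so mean true CC decreases strictly
  with amplitude.
- **Stomata.** `round(density × field area)` host cells receive a
  guard-cell-pair ellipse (default 30 × 22 µm) at the host's pole of
  inaccessibility, preferentially aligned with the host's long axis,
  inside a safety margin (default 5 µm, relaxed once to 3.5 µm) so the
  rendered ring of host cytoplasm cannot be severed by outline strokes.
  The ellipse is split along its major axis into two mirrored guard
  cells (one-object stomata available via a flag); the host keeps its
  outer wall and acquires an interior ring. An error names the
  constraint if the requested stomata cannot be placed.
- **Rendering.** Every pixel centre is assigned to its containing
  polygon; 1-px outline strokes (pure green, (0, 255, 0)) are placed on
  the tissue side of every ownership change, interiors are filled with
  class palette colors (pavement (180, 0, 0), stoma (180, 0, 120)) and
  the surrounding margin is black. This guarantees that the
  green-minus-red mask recovers the stroke set pixel-for-pixel and that
  cell interiors are exactly 4-separated. Isolated interior slivers of
  ≤ 5 px (a lobe tip cut off by a stroke) are absorbed into the stroke
  set; any larger fragmentation raises an error naming the scale as too
  coarse. A JSON sidecar records parameters, palette and seed.

## Synthetic fold-line profiles and trichome measurement

Fold-line micrographs show the leaf edge in profile: a dark tissue band
with trichomes lying flat against the slide. The generator draws a
body band (150 µm) along the bottom edge and trichomes as
constant-curvature arcs of log-normal arc length (default median
300 µm, σ = 0.4 — strictly positive and right-skewed, as hair-length
data are), combed to one common bend side as hairs lie in a fold
preparation. Stalks are drawn at 10 µm width; a glandular fraction
(default 0.3) carries a terminal disc of 35 µm. Trichome count is
deterministic (`round(density × edge length)`); bases keep a minimum
separation and each arc is accepted only if its path keeps at least one
stalk width + head radius of clearance from all previously placed
trichomes, with whole-image retries ending in an all-straight
configuration that always fits. Truth length is measured base-to-apex
(stalk arc plus head radius for glandular trichomes).

Measurement: Otsu thresholding of luminance (dark objects by default,
polarity flag otherwise) keeps the largest connected component; the
leaf body is the morphological opening with a disc whose radius
(default 15 µm) must exceed the widest stalk and stay below the
shortest trichome of interest; protrusions are components of
(mask − body) touching the body. Each protrusion is skeletonized and
its length taken as the longest geodesic path from the body contact to
a skeleton endpoint plus the tip radius from the distance transform
(compensating skeleton retraction at the tip). The geodesic path is
measured as a polyline subsampled every 5 px rather than by summing
1/√2 chamfer steps: the chamfer metric overestimates oblique straight
runs by up to ~8%, while the subsampled polyline keeps straight hairs
within ~1% at any orientation (and < 5% at 0°/30°/60° by test). A
glandular head is declared when a terminal blob survives an opening
that removes the stalk and is wider than 2× the median stalk width
(configurable); its pixel area is reported. Protrusions of < 2 px are
dropped with a warning; merged protrusions are flagged multi-base
rather than silently split.

## Statistics

- **Median profiles.** Medians use the standard convention (middle
  value / mean of the two middle values). Species feature names are
  side- and class-qualified (`CC_ab`, `st_C_ad`, `st_D_ab`, `tr_L`,
  `gtr_D`, ...). Densities of absent structures are imputed as 0 (a
  species with no glandular trichomes has `gtr_D = 0`); lengths and
  shapes of absent structures stay missing and are excluded pairwise.
- **Correlation.** Kendall tau-b (tie-corrected) per feature pair. The
  default unit of observation is the per-image aggregate (median per
  image), which avoids pseudo-replicating thousands of cells while
  keeping more rows than species; per-cell and per-species levels are
  available. A constant column has undefined tau and is reported as
  missing, never as 0. No p-values are computed.
- **PCA.** Eigen-decomposition of the covariance of z-scored medians
  (standardization is the default and practically mandatory, as the
  features mix µm, µm² and dimensionless indices). Sign convention:
  the largest-magnitude loading of each component is positive.
  Variance fractions are λᵢ/Σλ. A zero-variance feature raises an
  error naming it; the pipeline driver instead drops constant features
  with a log message, which is the right behaviour for small pilot
  runs.
- **Clustering.** Average-linkage agglomerative clustering on pairwise
  Euclidean distances between z-scored species medians (metric and
  linkage configurable). Rows are sorted by species name before
  linkage so tie-breaking is deterministic and row-order invariant.
  The dendrogram exports to Newick.

## What the synthetic validation shows — and does not

Passing the synthetic suite demonstrates that the measurement chain is
correct on its own assumptions: exact segmentation (1-px closed
outlines, known palette), exact scale, non-overlapping trichomes, and
noise-free rasters. It does not demonstrate robustness to the failure
modes of real micrographs: broken or double-drawn outlines, uneven
illumination, stain bleed-through, overlapping or out-of-plane
trichomes, and operator variability in manual segmentation. The
descriptor stage consumes any labeled component map, so an external
segmentation QC step can be inserted without touching the rest of the
pipeline.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based (row, col); scale is µm/pixel; areas µm²,
  lengths µm, densities mm⁻² (stomata, pavement cells) and mm⁻¹
  (trichomes).
- Reproducibility: one RNG stream per generated image, seeded from the
  parameter set; identical parameters give bit-identical truth, rasters
  and CSVs.
- A single-pixel component is a unit square (hull area 1, perimeter 4).
- Hull and caliper computations compare at float precision; the test
  suite asserts agreement with brute-force oracles to 1e-9.
- `measure_component` never fails on valid nonempty components; empty
  tables (all cells border-touching) are returned empty with a warning.
- Problem sizes in the validation experiments (fields of 0.09–1 mm²,
  50–700 cells per field, 200-trichome profiles, 8-species regime
  experiment) were chosen as the smallest sizes at which count
  quantization is negligible relative to the 5% recovery tolerances.

## Known limitations

- The exposed-edge perimeter bias (up to 4/π on smooth oblique
  boundaries) propagates into C; cross-study comparisons of C should
  fix the estimator (or use Crofton) and the image resolution.
- CC carries the corner-hull margin bias (≈ −2% at 50 px object
  radius, smaller for larger objects).
- Glandular classification is a width-ratio heuristic on the rendered
  silhouette; it does not model multicellular head anatomy and will
  miss heads narrower than 2× the stalk.
- The generator does not emulate photorealistic texture, staining,
  3-D leaf curvature, or trichome overlap; the stats stage assumes
  each species' cells are exchangeable across its images.
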