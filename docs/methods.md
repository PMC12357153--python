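# Methods

`swathagg` aggregates Level-2 satellite column retrievals (per-pixel
quadrilateral footprints with a column value in 10^15 molecules/cm² and a
QA score in [0, 1]) directly onto GEOID-keyed administrative polygons, and
computes population-weighted exposure-disparity statistics on the result.
This note records the models, the numerical choices, and what the
synthetic test scenes do and do not establish.

## Oversampling model

For a polygon *x* and temporal window *t*, every method reports the
weighted mean

    Ω̄_{x,t} = Σ_t Σ_i w_{i,x} Ω_i / Σ_t Σ_i w_{i,x}

over QA-screened observations *i* (kept iff qa strictly > 0.75). The
methods differ only in the weight:

* **AWO** (area-weighted): w_{i,x} is the area (km²) of the intersection
  between the footprint quadrilateral and the polygon. Zero outside the
  footprint.
* **PGO** (physics-based Gaussian): the instrument's spatial sensitivity
  around the nominal footprint is modelled as a 2-D super-Gaussian in the
  pixel-local along-track (x) / across-track (y) frame,

      S(x, y) = exp(−(|x/w_x|^n + |y/w_y|^m)),
      w_x = FWHM_x / (2 (ln 2)^{1/n}),  w_y = FWHM_y / (2 (ln 2)^{1/m}),

  with n = 2 (along) and m = 4 (across) by default, appropriate for a
  push-broom UV-VIS imager; the natural logarithm is forced by the
  requirement S(±FWHM/2, 0) = ½. FWHMs are the corner-derived footprint
  extents (mid-edge to mid-edge), optionally rescaled by a configurable
  factor for instruments whose calibrated response differs from the
  nominal footprint. w_{i,x} = ∫_x S, evaluated on a raster of the
  polygon (below). Strictly positive at any finite distance, so polygons
  under a cloud-masked pixel can still be estimated from neighbouring
  valid pixels — the method's missing-value advantage.
* **AWO-Grid** (baseline): observations are first averaged area-weighted
  onto a regular 0.01° grid with explicit registration (half-open cells,
  configurable origin — a registration shift changes the pattern, so it is
  always logged); polygons larger than a grid cell take the unweighted
  mean of valid cells whose centres fall inside, smaller polygons take the
  cell nearest their centroid (ties: lowest row, then column).

Accumulation is additive in numerator and denominator, so per-day runs
combine exactly into any longer window (tested to 1e-12 relative).

### Geometry

All coordinates are WGS84 lon/lat. Distances and areas use a local
equirectangular tangent plane per pixel (111.19 km per degree of latitude,
scaled by cos φ in longitude), which is accurate to well under 0.2% at
footprint scale; since weights enter as ratios, most of the residual
cancels. Corners are stored counterclockwise from the (−along, −across)
corner; the along-track unit vector runs from the trailing across-track
edge midpoint to the leading one, and the across-track unit vector is its
+90° CCW rotation (S is even in both axes, so only consistency matters).
Antimeridian-crossing and |lat| ≥ 85° footprints are rejected; the package
targets continental domains.

### Polygon rasterization (PGO)

Each polygon part is overlaid with a 10×10 grid spanning its bounding box.
Every grid cell is clipped against the polygon exactly and contributes
S(piece centroid) × piece area. Two alternatives were measured and
rejected:

* counting whole cells whose *centre* is inside: the half-cell placement
  error of boundary area reaches ~19% of the weight for ~2 km polygons
  lying on the steep m = 4 across-track flank of S (verified against a
  400×400 quadrature oracle);
* the same centre rule with sub-sampled S per cell: no improvement, since
  the error is area misplacement, not S sampling.

With exact clipping the worst-case deviation from the oracle drops to
~1.3%. Multipolygon parts are rasterized separately, so coastal two-part
polygons are not smeared across the gap; degenerate zero-extent polygons
fall back to S(centroid) × polygon area.

### Truncation and missing values

A pixel is a candidate contributor to a polygon iff the pixel's bounding
box dilated by 3 × max(FWHM) intersects the polygon's bounding box; beyond
3 FWHM the response is < 10⁻⁴ of its peak. A polygon is reported missing
when its accumulated weight is below 10⁻⁶ × polygon area (PGO) or
10⁻⁶ km² of intersection (AWO) — the Gaussian tail makes PGO sums never
exactly zero, and the floor prevents tail-only artifacts. No minimum
observation count is imposed; `total_weight` and `n_obs` are reported so
users can filter.

## Disparity layer

Per region (a CBSA-like grouping of polygons), group exposure is the
population-weighted mean Σ pop·Ω̄ / Σ pop over polygons with both a value
and population (missing polygons drop out of numerator and denominator).
The relative disparity is 100 × (comparison − reference)/reference with
white non-Hispanic as the racial/ethnic reference against the pooled
minority population (Hispanic + Black + Asian + Native American, one
comparison population, not a mean of per-group disparities), and the
high-income group (income-to-poverty ratio > 1.5) as the reference against
the low-income group (ratio < 1.24); the middle band belongs to neither
group. Positive values mean the minority or low-income group is more
exposed. Disparities are invariant to rescaling all exposures by a common
factor, so they compare across regions with different absolute levels.

Polluted days are the top 5% (configurable) of days ranked by the
regional daily mean — unweighted over non-missing polygons, with a day
valid only if ≥ 50% of the region's polygons are non-missing (guards
against cloud-biased selection; both knobs are config-exposed, and a
population-weighted regional mean can be substituted). Ties at the
selection boundary go to the earlier date. The polluted-minus-baseline
disparity change is reported in percentage points. The normalized spatial
gradient (polygon value ÷ regional maximum) is provided as a
scale-free map of within-region structure.

## Synthetic scenes

The generator produces the full input stack deterministically from a seed
(independent named random streams per purpose and per day):

* **Field**: uniform background (default 1.0 × 10^15 molecules/cm²) plus
  exponential plumes (defaults: two plumes, amplitudes 6 and 4, decay 10
  and 14 km), multiplied by a median-1 lognormal day factor (σ = 0.3).
  Designated stagnation days (5% of days) model pollution build-up: the
  whole field is multiplied by the sharpening factor (1.8) *and* plumes
  steepen (amplitude × 1.8, decay ÷ 1.8). Sharpening alone would shrink
  the plume's integrated mass (a·L²/f) and stagnation days would rank
  *low* in the regional mean; the accumulation multiplier is what makes
  polluted-day selection recover them, as intended.
* **Swath**: north-running scanlines of 5.5 km (along) × 3.5 km (nadir
  across) quadrilaterals; across-track width grows quadratically to 1.8×
  at the swath edge (halfwidth 150 km); the swath centre longitude and
  scanline phase jitter daily so footprint boundaries move between days —
  the variation oversampling relies on. Pixel values are 5×5 footprint
  means of the field. QA embeds contiguous cloud blobs (radius 15 km)
  sized so ~20% of pixels fall below the 0.75 screen.
* **Polygons**: a centroidal Voronoi tessellation (two Lloyd iterations)
  of ~200 cells on a 1°×1° domain; half the generating points cluster
  within 2 km of plume cores, giving an urban/rural area spectrum from
  ~0.4 to ~250 km². A coarse n×n split of the domain assigns region ids.
* **Demographics**: minority share per polygon interpolates between a
  uniform base share (0.30) and exp(−d_core/8 km) under the segregation
  parameter s ∈ [0, 1]; the low-income share analogously under its own
  parameter. Population totals scale with 1/area (dense urban cores).
  Counts are expected values and deliberately stay fractional — rounding
  would break the exact zero-disparity property of s = 0.

What the scenes do **not** emulate: chemical transport, wind-driven plume
asymmetry, retrieval error correlated with the scene (QA is independent of
the column value given the cloud mask), terrain/parallax, orbit geometry
beyond a jittered north-running track, and real census geography. Passing
tests therefore establish the correctness and internal consistency of the
estimators, not the magnitude of any real-world disparity.

## Problem sizes and determinism

The benchmark scene for the PGO↔AWO comparison uses 300 daily swaths over
~200 polygons (≈1.9 × 10⁵ footprints after screening), chosen as the
smallest ensemble for which the long-window comparison is clearly in its
converged regime; the disparity-recovery scenes use 40 days × 80 polygons
with daily σ = 0.05 so the two designated stagnation days dominate the
polluted-day ranking. All random draws flow from
`numpy.random.default_rng([seed, stream, ...])`; identical seeds give
byte-identical outputs across platforms, and no computation depends on
dict or set iteration order.

## Known limitations

* Equirectangular scaling degrades towards high latitudes; the hard stop
  is |lat| < 85°, but sub-0.2% accuracy claims hold only well below that.
* GeoJSON is the only supported polygon format; Shapefiles must be
  converted first.
* The NetCDF swath dialect covers flat per-observation layouts (one
  observation dimension, a 4-corner bound dimension); scanline×ground-pixel
  2-D layouts must be flattened by the caller or added to the dialect
  table.
* AWO-Grid inherits grid-registration sensitivity by construction; results
  are only comparable across runs with identical registration (recorded in
  the run manifest).
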