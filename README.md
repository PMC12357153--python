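# swathagg

Oversampling of satellite swath columns directly onto administrative
polygons, with a population-weighted exposure-disparity layer.

## The problem

Satellite trace-gas retrievals (e.g. tropospheric NO₂ columns from a
push-broom imager) come as Level-2 swaths: irregular quadrilateral
footprints, a few kilometres across, whose boundaries move from day to
day. Health and socioeconomic data, by contrast, live on administrative
polygons (census block groups keyed by GEOID), whose areas span
~0.001–10,000 km² — often far smaller than any regular Level-3 grid cell.
Snapping a gridded product to polygons mismatches exactly the small urban
units where exposure gradients and populations are largest.

`swathagg` skips the grid: it aggregates screened Level-2 observations
straight onto polygons by spatial oversampling, and is written for
researchers linking column observations to neighbourhood-level demographic
data (exposure assessment, environmental-justice analysis).

## Methods

Every method reports, per polygon *x* and temporal window *t*, the
weighted mean column

    Ω̄_{x,t} = Σ_t Σ_i w_{i,x} Ω_i / Σ_t Σ_i w_{i,x}

over observations with QA > 0.75, and they differ only in the weight
w_{i,x}:

* **PGO** (physics-based Gaussian oversampling) — the instrument's
  spatial response around a footprint is a 2-D super-Gaussian
  S(x,y) = exp(−(|x/w_x|ⁿ + |y/w_y|ᵐ)) in the pixel's along-/across-track
  frame, with w = FWHM/(2(ln 2)^{1/n}) and defaults n = 2, m = 4;
  w_{i,x} = ∫ₓ S. Pixels near a polygon but not overlapping it still
  carry (small) weight, which both smooths short-window maps and fills
  polygons under cloud-masked pixels from neighbouring valid ones.
* **AWO** (area-weighted oversampling) — w_{i,x} is the
  footprint-polygon intersection area; fast, vector-based, and in
  long-window averages nearly identical to PGO.
* **AWO-Grid** (baseline) — area-weighted averaging to a regular 0.01°
  grid first, then grid-to-polygon assignment (mean of interior cells, or
  nearest cell for sub-cell polygons).

The disparity layer computes, per region (CBSA-like grouping),
population-weighted group exposures and relative disparities
100 × (comparison − reference)/reference — white non-Hispanic vs pooled
minority populations, and high- vs low-income (income-to-poverty ratio
> 1.5 vs < 1.24) — for the full record and for the top 5% polluted days
(ranked by regional daily mean). See `docs/methods.md` for the full model
description and numerical choices.

A seeded synthetic scene generator (swaths with across-track pixel
growth and contiguous cloud gaps, a centroidal-Voronoi polygon
tessellation with an urban/rural size spectrum, demographics with a
tunable segregation parameter) makes the whole pipeline testable offline.

## Worked example

```python
import numpy as np
import swathagg as sa

config = sa.SceneConfig(n_days=30, n_polygons=60, seed=7)
scene = sa.generate_scene(config)

observations = []
for day in range(config.n_days):
    observations.extend(sa.screen_qa(sa.generate_swath(config, day)))
print(f"{len(observations)} screened observations over {config.n_days} days")

pgo = sa.aggregate_polygons(observations, scene.polygons, "pgo")
awo = sa.aggregate_polygons(observations, scene.polygons, "awo")
values = {r.geoid: r.mean_column for r in pgo}
cols = np.array([v for v in values.values() if v is not None])
print(f"PGO column range: {cols.min():.2f}-{cols.max():.2f} x 1e15 molec/cm2")

awo_v = {r.geoid: r.mean_column for r in awo}
rel = [abs(values[g] - awo_v[g]) / awo_v[g] * 100
       for g in values if values[g] is not None and awo_v[g] is not None]
print(f"median PGO vs AWO difference: {np.median(rel):.2f}%")

report = sa.disparity_report({"full": values}, scene.demographics, scene.region_map)
for _, row in report.iterrows():
    print(f"region {row.region_id}: mean {row.mean_all:.2f}, "
          f"racial disparity {row.racial_disparity_pct:+.1f}%, "
          f"income disparity {row.income_disparity_pct:+.1f}%")
```

prints

```
26022 screened observations over 30 days
PGO column range: 1.03-5.28 x 1e15 molec/cm2
median PGO vs AWO difference: 0.19%
region R00: mean 4.09, racial disparity +14.5%, income disparity +14.9%
region R01: mean 1.20, racial disparity +0.2%, income disparity +0.2%
region R10: mean 1.37, racial disparity +0.9%, income disparity +1.1%
region R11: mean 3.69, racial disparity +6.3%, income disparity +6.4%
```

The two plume regions (R00, R11) show elevated columns and — because the
scene's minority and low-income populations concentrate towards plume
cores (segregation 0.5) — positive exposure disparities; the background
regions sit near the 1.0 × 10^15 baseline with disparities near zero. The
0.19% PGO-vs-AWO median difference illustrates how closely the two
weighting schemes agree once footprint boundaries have been averaged over
many days.

The same pipeline runs from the shell:

```sh
swathagg simulate --seed 7 --days 30 --out-dir scene/
swathagg oversample --l2 scene/swaths --polygons scene/polygons.geojson \
         --method pgo --daily --out daily.csv
swathagg disparity --exposure daily.csv --demographics scene/demographics.csv \
         --region-map scene/regions.csv --out report.csv
```

Readers accept flat-CSV or NetCDF swaths and GeoJSON polygons; results are
written as CSV or joined back onto polygon GeoJSON. Every run writes a
JSON manifest (config digest, input counts, screening statistics).

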