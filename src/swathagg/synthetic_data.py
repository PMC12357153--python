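"""Seeded synthetic scenes: swaths, tessellations, demographics, truth fields.

The generator emulates the statistical structure the oversampling method
assumes, so every stage of the pipeline can be exercised offline:

* a smooth column field — exponential plumes on a uniform background,
  modulated by a day-to-day lognormal factor, with designated 'stagnation'
  days on which plumes sharpen (larger amplitude, shorter decay length),
  mimicking the steeper gradients of polluted days;
* a push-broom swath — scanlines of quadrilateral footprints whose
  across-track width grows from the swath centre towards the edge, with a
  daily cross-track jitter of the swath centre (so footprint boundaries
  move between days, which is what makes oversampling work), and QA values
  drawn so that contiguous cloud blobs fall below the screening threshold;
* a centroidal Voronoi tessellation of administrative polygons whose cells
  are dense (small) near plume cores and coarse elsewhere, echoing the
  urban/rural size spectrum of census block groups;
* demographics with a tunable segregation parameter s in [0, 1]: at s = 0
  every polygon has identical group shares (all disparities are exactly
  zero downstream); at s = 1 minority and low-income populations are fully
  concentrated towards plume cores.

Everything is deterministic under a fixed seed; independent random streams
are derived per purpose and per day, never shared.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, box

from .disparity import DemographicTable
from .oversampler import AdminPolygon
from .response_kernel import polygon_area_km2
from .swath_geometry import KM_PER_DEG, PixelObservation

# random-stream ids (combined with the scene seed)
_STREAM_POLYGONS = 1
_STREAM_DEMOGRAPHICS = 2
_STREAM_DAILY = 3
_STREAM_STAGNATION = 4
_STREAM_SWATH_BASE = 100


@dataclass(frozen=True)
class Plume:
    """One exponential plume: column = amplitude * exp(-distance/decay)."""

    lon: float
    lat: float
    amplitude: float  # 10^15 molecules/cm^2
    decay_km: float


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene.

    Defaults describe a 1 deg x 1 deg domain with two urban plumes over a
    background of 1.0 x 10^15 molecules/cm^2, 300 daily overpasses, 20%
    cloud cover in contiguous blobs, TROPOMI-like 5.5 x 3.5 km nadir
    pixels growing 1.8x towards the swath edge, ~200 polygons and moderate
    residential segregation.
    """

    lon_min: float = -100.0
    lat_min: float = 34.0
    lon_span: float = 1.0
    lat_span: float = 1.0
    n_days: int = 300
    seed: int = 7
    start_date: _dt.date = _dt.date(2019, 1, 1)
    plumes: tuple[Plume, ...] = (
        Plume(lon=-99.70, lat=34.35, amplitude=6.0, decay_km=10.0),
        Plume(lon=-99.30, lat=34.70, amplitude=4.0, decay_km=14.0),
    )
    background: float = 1.0
    daily_sigma: float = 0.3  # lognormal sigma of the day factor
    stagnation_fraction: float = 0.05
    stagnation_sharpening: float = 1.8
    cloud_fraction: float = 0.2
    cloud_blob_radius_km: float = 15.0
    pixel_along_km: float = 5.5
    pixel_across_km: float = 3.5
    across_growth: float = 1.8  # edge / nadir across-track width
    swath_halfwidth_km: float = 150.0
    n_polygons: int = 200
    core_fraction: float = 0.5  # share of polygon seeds clustered at plume cores
    core_sigma_km: float = 2.0
    lloyd_iterations: int = 2
    n_region_side: int = 2  # regions form an n x n partition of the domain
    segregation: float = 0.5  # racial/ethnic segregation s in [0, 1]
    income_segregation: float = 0.5
    base_minority_share: float = 0.30
    base_low_income_share: float = 0.20
    middle_income_share: float = 0.15
    segregation_length_km: float = 8.0
    population_scale: float = 3000.0  # population = scale / area_km2

    def __post_init__(self) -> None:
        if not (0.0 <= self.segregation <= 1.0 and 0.0 <= self.income_segregation <= 1.0):
            raise ValueError("segregation parameters must be in [0, 1]")
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ValueError("cloud fraction must be in [0, 1)")
        if any(p.amplitude < 0 for p in self.plumes):
            raise ValueError("plume amplitudes must be >= 0")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.lon_span

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.lat_span

    @property
    def center_lat(self) -> float:
        return self.lat_min + 0.5 * self.lat_span

    @property
    def east_scale(self) -> float:
        return KM_PER_DEG * float(np.cos(np.deg2rad(self.center_lat)))

    def date_of(self, day: int) -> _dt.date:
        return self.start_date + _dt.timedelta(days=day)


def _rng(config: SceneConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def stagnation_days(config: SceneConfig) -> np.ndarray:
    """Boolean mask over day indices marking designated stagnation days."""
    rng = _rng(config, _STREAM_STAGNATION)
    return rng.random(config.n_days) < config.stagnation_fraction


def daily_factors(config: SceneConfig) -> np.ndarray:
    """Median-1 lognormal day-to-day factors, one per day."""
    rng = _rng(config, _STREAM_DAILY)
    return np.exp(config.daily_sigma * rng.standard_normal(config.n_days))


@dataclass(frozen=True)
class DailyField:
    """Continuous column field for one day; callable on lon/lat arrays."""

    config: SceneConfig
    day: int
    factor: float
    stagnation: bool

    def __call__(self, lon, lat):
        cfg = self.config
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        total = np.full(np.broadcast(lon, lat).shape, cfg.background, dtype=float)
        # stagnation = accumulation: the whole field is elevated by the
        # sharpening factor AND plumes steepen (higher peak, shorter decay);
        # sharpening alone would shrink the plume's total mass and polluted
        # days would not rank highest in the regional mean
        sharp = cfg.stagnation_sharpening if self.stagnation else 1.0
        for p in cfg.plumes:
            d = np.hypot(
                (lon - p.lon) * cfg.east_scale, (lat - p.lat) * KM_PER_DEG
            )
            total += p.amplitude * sharp * np.exp(-d / (p.decay_km / sharp))
        return total * self.factor * sharp


def generate_field(config: SceneConfig, day: int) -> DailyField:
    """The truth field for day index ``day`` (0-based)."""
    return DailyField(
        config=config,
        day=day,
        factor=float(daily_factors(config)[day]),
        stagnation=bool(stagnation_days(config)[day]),
    )


def _across_track_columns(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Across-track cell edges (km from swath centre), centre outwards.

    Width at offset d is w0 * (1 + (g - 1) * (d/H)^2), so the outermost
    pixel is ``across_growth`` times wider than the nadir pixel.
    """
    w0, g, H = config.pixel_across_km, config.across_growth, config.swath_halfwidth_km

    def march(start: float, direction: float) -> list[tuple[float, float]]:
        cells, e = [], start
        while abs(e) < H:
            w = w0
            for _ in range(3):  # fixed point: width evaluated at the cell centre
                w = w0 * (1.0 + (g - 1.0) * (min(abs(e) + 0.5 * w, H) / H) ** 2)
            cells.append((e, e + direction * w))
            e += direction * w
        return cells

    offset = rng.uniform(-0.5, 0.5) * w0
    cells = march(offset, +1.0) + march(offset, -1.0)
    return np.array(sorted((min(a, b), max(a, b)) for a, b in cells))


def generate_swath(
    config: SceneConfig, day: int, field: Callable | None = None
) -> list[PixelObservation]:
    """Quadrilateral footprints tiling the domain (plus margin) for one day.

    The track runs due north; across-track is east-west.  The swath centre
    longitude jitters daily, as does the along-track scanline phase, so
    footprint boundaries differ between days.  QA values embed contiguous
    cloud blobs: a ``cloud_fraction`` share of pixels (in expectation)
    receives qa < 0.75.
    """
    cfg = config
    field = field or generate_field(cfg, day)
    rng = _rng(cfg, _STREAM_SWATH_BASE, day)

    margin_km = 20.0
    center_lon = cfg.lon_min + 0.5 * cfg.lon_span + rng.uniform(-0.3, 0.3) * cfg.lon_span
    cols = _across_track_columns(cfg, rng)
    # keep only columns overlapping the domain + margin
    dom_lo = (cfg.lon_min - center_lon) * cfg.east_scale - margin_km
    dom_hi = (cfg.lon_max - center_lon) * cfg.east_scale + margin_km
    cols = cols[(cols[:, 1] > dom_lo) & (cols[:, 0] < dom_hi)]

    along_phase = rng.uniform(0.0, cfg.pixel_along_km)
    lat_lo_km = -margin_km - along_phase
    n_rows = int(np.ceil((cfg.lat_span * KM_PER_DEG + 2 * margin_km) / cfg.pixel_along_km)) + 1
    row_edges = cfg.lat_min + (lat_lo_km + cfg.pixel_along_km * np.arange(n_rows + 1)) / KM_PER_DEG

    # cloud blobs over the swath footprint
    cloudy_centers: np.ndarray | None = None
    if cfg.cloud_fraction > 0:
        area = (cfg.lon_span * cfg.east_scale + 2 * margin_km) * (
            cfg.lat_span * KM_PER_DEG + 2 * margin_km
        )
        n_blobs = max(1, round(cfg.cloud_fraction * area / (np.pi * cfg.cloud_blob_radius_km**2)))
        cloudy_centers = np.column_stack(
            [
                rng.uniform(cfg.lon_min - 0.1, cfg.lon_max + 0.1, n_blobs),
                rng.uniform(cfg.lat_min - 0.1, cfg.lat_max + 0.1, n_blobs),
            ]
        )

    u = (np.arange(5) + 0.5) / 5.0  # footprint sampling offsets
    uu, vv = np.meshgrid(u, u)
    observations: list[PixelObservation] = []
    for irow in range(n_rows):
        lat_s, lat_n = row_edges[irow], row_edges[irow + 1]
        lat_c = 0.5 * (lat_s + lat_n)
        east = KM_PER_DEG * np.cos(np.deg2rad(lat_c))
        for icol, (y0, y1) in enumerate(cols):
            lon_e = center_lon + y1 / east  # across-track axis points west
            lon_w = center_lon + y0 / east
            lon_c = 0.5 * (lon_e + lon_w)
            # counterclockwise from the (-along, -across) = SE corner
            corners = (
                (lon_e, lat_s),
                (lon_e, lat_n),
                (lon_w, lat_n),
                (lon_w, lat_s),
            )
            slon = lon_w + (lon_e - lon_w) * uu
            slat = lat_s + (lat_n - lat_s) * vv
            value = float(np.mean(field(slon, slat)))
            if cloudy_centers is not None:
                d = np.hypot(
                    (cloudy_centers[:, 0] - lon_c) * east,
                    (cloudy_centers[:, 1] - lat_c) * KM_PER_DEG,
                )
                cloudy = bool((d < cfg.cloud_blob_radius_km).any())
            else:
                cloudy = False
            qa = float(rng.uniform(0.0, 0.5) if cloudy else rng.uniform(0.80, 0.98))
            observations.append(
                PixelObservation(
                    id=f"d{day:04d}_r{irow:03d}_c{icol:03d}",
                    date=cfg.date_of(day),
                    lon=lon_c,
                    lat=lat_c,
                    corners=corners,
                    value=value,
                    qa=qa,
                )
            )
    return observations


def _voronoi_cells(points: np.ndarray, domain) -> list:
    cells = shapely.voronoi_polygons(MultiPoint(points.tolist()), extend_to=domain)
    clipped = [g.intersection(domain) for g in cells.geoms]
    return [g for g in clipped if not g.is_empty and g.area > 0]


def generate_polygons(config: SceneConfig) -> list[AdminPolygon]:
    """Centroidal Voronoi tessellation partitioning the domain.

    A ``core_fraction`` share of the generating points is clustered within
    ``core_sigma_km`` of plume cores, giving small 'urban' cells there and
    coarse cells elsewhere.  Each polygon carries a region id from an
    n x n coarse partition of the domain (a CBSA-like grouping).
    """
    cfg = config
    if cfg.n_polygons < 4:
        raise ValueError("need at least 4 polygons")
    rng = _rng(cfg, _STREAM_POLYGONS)
    domain = box(cfg.lon_min, cfg.lat_min, cfg.lon_max, cfg.lat_max)

    n_core = round(cfg.core_fraction * cfg.n_polygons) if cfg.plumes else 0
    pts = []
    for _ in range(n_core):
        p = cfg.plumes[rng.integers(len(cfg.plumes))]
        pts.append(
            [
                p.lon + rng.normal(0, cfg.core_sigma_km / cfg.east_scale),
                p.lat + rng.normal(0, cfg.core_sigma_km / KM_PER_DEG),
            ]
        )
    n_uniform = cfg.n_polygons - len(pts)
    uni = np.column_stack(
        [
            rng.uniform(cfg.lon_min, cfg.lon_max, n_uniform),
            rng.uniform(cfg.lat_min, cfg.lat_max, n_uniform),
        ]
    )
    points = np.vstack([np.array(pts).reshape(-1, 2), uni])
    points[:, 0] = np.clip(points[:, 0], cfg.lon_min + 1e-6, cfg.lon_max - 1e-6)
    points[:, 1] = np.clip(points[:, 1], cfg.lat_min + 1e-6, cfg.lat_max - 1e-6)

    cells = _voronoi_cells(points, domain)
    for _ in range(cfg.lloyd_iterations):
        centroids = np.array([[c.centroid.x, c.centroid.y] for c in cells])
        cells = _voronoi_cells(centroids, domain)
    cells.sort(key=lambda g: (round(g.centroid.y, 9), round(g.centroid.x, 9)))

    polygons = []
    for i, geom in enumerate(cells):
        cx, cy = geom.centroid.x, geom.centroid.y
        rx = min(int((cx - cfg.lon_min) / cfg.lon_span * cfg.n_region_side), cfg.n_region_side - 1)
        ry = min(int((cy - cfg.lat_min) / cfg.lat_span * cfg.n_region_side), cfg.n_region_side - 1)
        polygons.append(
            AdminPolygon(
                geoid=f"G{i:05d}",
                geometry=geom,
                area_km2=polygon_area_km2(geom),
                region_id=f"R{ry}{rx}",
            )
        )
    return polygons


def _distance_to_core_km(config: SceneConfig, lon: float, lat: float) -> float:
    if not config.plumes:
        return np.inf
    return min(
        float(np.hypot((lon - p.lon) * config.east_scale, (lat - p.lat) * KM_PER_DEG))
        for p in config.plumes
    )


def generate_demographics(
    polygons: Sequence[AdminPolygon], config: SceneConfig
) -> DemographicTable:
    """Group populations per polygon with tunable segregation.

    Minority share interpolates between a uniform base share (s = 0) and a
    profile exp(-d/segregation_length) peaking at plume cores (s = 1); the
    low-income share behaves analogously under ``income_segregation``.
    Total population scales with 1/area, so small urban polygons are dense.
    """
    cfg = config
    s, si = cfg.segregation, cfg.income_segregation
    rows = {}
    for poly in polygons:
        c = poly.geometry.centroid
        d = _distance_to_core_km(cfg, c.x, c.y)
        core = float(np.exp(-d / cfg.segregation_length_km))
        pop = max(1.0, cfg.population_scale / max(poly.area_km2, 1e-3))

        minority_share = np.clip((1 - s) * cfg.base_minority_share + s * core, 0.0, 1.0)
        minority = pop * minority_share
        low_share = np.clip(
            (1 - si) * cfg.base_low_income_share + si * 0.85 * core, 0.0, 0.85
        )
        high_share = max(0.0, 1.0 - low_share - cfg.middle_income_share)
        rows[poly.geoid] = {
            "white": pop - minority,
            "hispanic": 0.45 * minority,
            "black": 0.30 * minority,
            "asian": 0.18 * minority,
            "native_american": 0.07 * minority,
            "income_below_1_24": pop * low_share,
            "income_above_1_5": pop * high_share,
        }
    # populations are expected counts and stay fractional: rounding would
    # break the exact zero-disparity property of the s = 0 configuration
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "geoid"
    return DemographicTable(table)


@dataclass(frozen=True)
class Scene:
    """A fully generated study scene."""

    config: SceneConfig
    polygons: list[AdminPolygon] = field(repr=False)
    demographics: DemographicTable = field(repr=False)

    @property
    def region_map(self) -> pd.Series:
        return pd.Series(
            {p.geoid: p.region_id for p in self.polygons}, name="region_id"
        )

    @property
    def dates(self) -> list[_dt.date]:
        return [self.config.date_of(d) for d in range(self.config.n_days)]

    def observations(self, day: int) -> list[PixelObservation]:
        return generate_swath(self.config, day)

    def with_config(self, **changes) -> "Scene":
        return generate_scene(replace(self.config, **changes))


def generate_scene(config: SceneConfig | None = None) -> Scene:
    """Polygons + demographics for a config; swaths are generated per day."""
    config = config or SceneConfig()
    polygons = generate_polygons(config)
    return Scene(
        config=config,
        polygons=polygons,
        demographics=generate_demographics(polygons, config),
    )
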