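"""Determinism, geometry and statistical structure of the scene generator."""

import numpy as np
import pytest

from swathagg.disparity import disparity_report
from swathagg.oversampler import aggregate_polygons, screen_qa
from swathagg.swath_geometry import KM_PER_DEG, build_local_frame, derive_fwhm
from swathagg.synthetic_data import (
    Plume,
    SceneConfig,
    daily_factors,
    generate_demographics,
    generate_field,
    generate_polygons,
    generate_scene,
    generate_swath,
    stagnation_days,
)

SMALL = dict(n_polygons=40, n_days=5, lloyd_iterations=1)


class TestGenerateField:
    def test_zero_plumes_constant_background(self):
        cfg = SceneConfig(plumes=(), daily_sigma=0.0, **SMALL)
        f = generate_field(cfg, 0)
        lon = np.linspace(cfg.lon_min, cfg.lon_max, 7)
        assert np.allclose(f(lon, np.full_like(lon, cfg.lat_min + 0.3)), cfg.background)

    def test_value_at_plume_center(self):
        plume = Plume(lon=-99.5, lat=34.5, amplitude=6.0, decay_km=10.0)
        cfg = SceneConfig(plumes=(plume,), daily_sigma=0.0, stagnation_fraction=0.0, **SMALL)
        f = generate_field(cfg, 0)
        assert f(plume.lon, plume.lat) == pytest.approx(cfg.background + plume.amplitude)

    def test_seed_determinism(self):
        cfg = SceneConfig(**SMALL)
        f1, f2 = generate_field(cfg, 2), generate_field(cfg, 2)
        assert f1.factor == f2.factor
        other = generate_field(SceneConfig(seed=99, **SMALL), 2)
        assert other.factor != f1.factor

    def test_stagnation_day_sharpens_plume(self):
        plume = Plume(lon=-99.5, lat=34.5, amplitude=6.0, decay_km=10.0)
        base = SceneConfig(plumes=(plume,), daily_sigma=0.0, stagnation_fraction=0.0, **SMALL)
        stag = SceneConfig(plumes=(plume,), daily_sigma=0.0, stagnation_fraction=1.0, **SMALL)
        f0, f1 = generate_field(base, 0), generate_field(stag, 0)
        assert f1(plume.lon, plume.lat) > f0(plume.lon, plume.lat)
        far_lon = plume.lon + 40.0 / base.east_scale
        # relative spatial gradient steepens: the far field is a smaller
        # fraction of the core value on stagnation (accumulation) days
        assert (f1(far_lon, plume.lat) / f1(plume.lon, plume.lat)
                < f0(far_lon, plume.lat) / f0(plume.lon, plume.lat))
        # and the domain-average level rises (accumulation)
        lons = np.linspace(base.lon_min, base.lon_max, 21)
        lats = np.full_like(lons, plume.lat)
        assert f1(lons, lats).mean() > f0(lons, lats).mean()


class TestGenerateSwath:
    def test_cloud_free_swath_survives_screening(self):
        cfg = SceneConfig(cloud_fraction=0.0, **SMALL)
        obs = generate_swath(cfg, 0)
        assert screen_qa(obs) == obs

    def test_cloud_fraction_reflected_in_qa(self):
        cfg = SceneConfig(cloud_fraction=0.25, **SMALL)
        obs = generate_swath(cfg, 1)
        frac = np.mean([o.qa < 0.75 for o in obs])
        assert 0.10 < frac < 0.45

    def test_constant_field_gives_constant_pixels(self):
        cfg = SceneConfig(plumes=(), daily_sigma=0.0, **SMALL)
        obs = generate_swath(cfg, 0)
        assert all(o.value == pytest.approx(cfg.background, rel=1e-12) for o in obs)

    def test_edge_to_nadir_width_matches_growth_factor(self):
        cfg = SceneConfig(swath_halfwidth_km=55.0, **SMALL)
        obs = generate_swath(cfg, 0)
        widths = []
        for o in obs:
            frame = build_local_frame(o)
            widths.append(derive_fwhm(o, frame)[1])
        ratio = max(widths) / min(widths)
        assert ratio == pytest.approx(cfg.across_growth, rel=0.02)

    def test_determinism(self):
        cfg = SceneConfig(**SMALL)
        a, b = generate_swath(cfg, 3), generate_swath(cfg, 3)
        assert a == b


class TestGeneratePolygons:
    def test_partition_covers_domain(self):
        cfg = SceneConfig(**SMALL)
        polys = generate_polygons(cfg)
        domain_km2 = (
            cfg.lon_span * cfg.east_scale * cfg.lat_span * KM_PER_DEG
        )
        assert sum(p.area_km2 for p in polys) == pytest.approx(domain_km2, rel=1e-3)

    def test_four_cells_cover_square_domain(self):
        cfg = SceneConfig(n_polygons=4, core_fraction=0.0, lloyd_iterations=0, n_days=1)
        polys = generate_polygons(cfg)
        assert len(polys) == 4
        area = sum(p.geometry.area for p in polys)
        assert area == pytest.approx(cfg.lon_span * cfg.lat_span, rel=1e-6)

    def test_same_seed_identical_tessellation(self):
        cfg = SceneConfig(**SMALL)
        p1, p2 = generate_polygons(cfg), generate_polygons(cfg)
        assert [p.geometry.wkb for p in p1] == [p.geometry.wkb for p in p2]

    def test_urban_cells_smaller_near_plumes(self):
        cfg = SceneConfig(n_polygons=150, n_days=1)
        polys = generate_polygons(cfg)
        near, far = [], []
        for p in polys:
            c = p.geometry.centroid
            d = min(
                np.hypot((c.x - pl.lon) * cfg.east_scale, (c.y - pl.lat) * KM_PER_DEG)
                for pl in cfg.plumes
            )
            (near if d < 10.0 else far).append(p.area_km2)
        assert np.median(near) < np.median(far)

    def test_region_ids_partition(self):
        polys = generate_polygons(SceneConfig(**SMALL))
        regions = {p.region_id for p in polys}
        assert regions <= {"R00", "R01", "R10", "R11"}
        assert len(regions) > 1


class TestGenerateDemographics:
    def test_no_segregation_uniform_shares_zero_disparity(self):
        cfg = SceneConfig(segregation=0.0, income_segregation=0.0, **SMALL)
        scene = generate_scene(cfg)
        values = {p.geoid: 1.0 + 0.1 * i for i, p in enumerate(scene.polygons)}
        report = disparity_report(
            {"full": values}, scene.demographics, {p.geoid: "R" for p in scene.polygons}
        )
        assert report.racial_disparity_pct.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_full_segregation_minority_peaks_at_core(self):
        cfg = SceneConfig(segregation=1.0, **SMALL)
        polys = generate_polygons(cfg)
        demo = generate_demographics(polys, cfg)
        t = demo.table
        shares = demo.group_population("minority") / demo.group_population("total")
        dist = {}
        for p in polys:
            c = p.geometry.centroid
            dist[p.geoid] = min(
                np.hypot((c.x - pl.lon) * cfg.east_scale, (c.y - pl.lat) * KM_PER_DEG)
                for pl in cfg.plumes
            )
        nearest = min(dist, key=dist.get)
        assert shares[nearest] == shares.max()

    def test_small_polygons_denser(self):
        cfg = SceneConfig(**SMALL)
        polys = generate_polygons(cfg)
        demo = generate_demographics(polys, cfg)
        total = demo.group_population("total")
        areas = {p.geoid: p.area_km2 for p in polys}
        smallest = min(areas, key=areas.get)
        largest = max(areas, key=areas.get)
        assert total[smallest] / areas[smallest] > total[largest] / areas[largest]


class TestSceneClosure:
    def test_constant_field_closure_all_methods(self):
        """Oversampling swaths of a constant field returns the constant."""
        cfg = SceneConfig(
            plumes=(), daily_sigma=0.0, cloud_fraction=0.0,
            n_polygons=25, n_days=2, lloyd_iterations=1,
        )
        scene = generate_scene(cfg)
        obs = []
        for d in range(cfg.n_days):
            obs.extend(screen_qa(generate_swath(cfg, d)))
        for method in ("pgo", "awo"):
            for r in aggregate_polygons(obs, scene.polygons, method):
                assert r.mean_column == pytest.approx(cfg.background, rel=1e-9)

    def test_stagnation_days_have_highest_daily_factors_when_sigma_small(self):
        cfg = SceneConfig(daily_sigma=0.05, stagnation_fraction=0.1, n_days=50, n_polygons=40)
        stag = stagnation_days(cfg)
        assert stag.any() and not stag.all()
        # field maximum on stagnation days exceeds any non-stagnation day's
        peaks = []
        for d in range(cfg.n_days):
            f = generate_field(cfg, d)
            peaks.append(f(cfg.plumes[0].lon, cfg.plumes[0].lat))
        peaks = np.array(peaks)
        assert peaks[stag].min() > peaks[~stag].max()
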