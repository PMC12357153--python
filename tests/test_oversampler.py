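"""QA screening, polygon/grid aggregation, missing-value accounting."""

import datetime as dt

import numpy as np
import pytest
from shapely.geometry import box

from swathagg.oversampler import (
    AdminPolygon,
    GridResult,
    GridSpec,
    TemporalWindow,
    aggregate_grid,
    aggregate_polygons,
    assign_grid_to_polygons,
    count_missing,
    screen_qa,
)
from swathagg.response_kernel import polygon_area_km2
from swathagg.swath_geometry import KM_PER_DEG

from conftest import DATE, make_rect_pixel

DEG = 1.0 / KM_PER_DEG


def admin(geoid, geom, region=None):
    return AdminPolygon(geoid=geoid, geometry=geom, area_km2=polygon_area_km2(geom), region_id=region)


class TestScreenQa:
    def test_strict_inequality_at_threshold(self):
        obs = [make_rect_pixel(qa=q, pid=str(q)) for q in (0.5, 0.75, 0.8)]
        kept = screen_qa(obs, threshold=0.75)
        assert [o.id for o in kept] == ["0.8"]

    def test_empty_input(self):
        assert screen_qa([]) == []

    def test_zero_threshold_keeps_all_positive(self):
        obs = [make_rect_pixel(qa=q) for q in (0.1, 0.9)]
        assert screen_qa(obs, threshold=0.0) == obs


class TestAggregatePolygons:
    @pytest.mark.parametrize("method", ["pgo", "awo"])
    def test_constant_field_conserved(self, method):
        obs = [
            make_rect_pixel(lon=i * 0.05, lat=j * 0.05, value=3.25, pid=f"{i}{j}")
            for i in range(-2, 3)
            for j in range(-2, 3)
        ]
        polys = [
            admin("a", box(-0.02, -0.02, 0.02, 0.02)),
            admin("b", box(0.03, 0.0, 0.06, 0.04)),
        ]
        for r in aggregate_polygons(obs, polys, method):
            assert r.mean_column == pytest.approx(3.25, rel=1e-12)

    def test_equal_weights_average(self):
        # two pixels with the same footprint -> identical weights
        obs = [make_rect_pixel(value=1.0, pid="a"), make_rect_pixel(value=3.0, pid="b")]
        polys = [admin("p", box(-0.01, -0.01, 0.01, 0.01))]
        for method in ("pgo", "awo"):
            (r,) = aggregate_polygons(obs, polys, method)
            assert r.mean_column == pytest.approx(2.0, rel=1e-12)
            assert r.n_obs == 2

    def test_unequal_overlap_weights(self):
        # polygon spans x [-2, 2], y [-1, 1] km (area 8 km^2)
        poly = admin("p", box(-2 * DEG, -1 * DEG, 2 * DEG, 1 * DEG))
        # px1 covers it fully (w = 8); px2 spans y [0, 6] so covers y [0, 1] (w = 4)
        px1 = make_rect_pixel(lon=0.0, lat=0.0, along_km=4.0, across_km=2.0,
                              azimuth_deg=0.0, value=1.0, pid="w1")
        px2 = make_rect_pixel(lon=0.0, lat=3.0 * DEG, along_km=4.0, across_km=6.0,
                              azimuth_deg=0.0, value=3.0, pid="w3")
        (r,) = aggregate_polygons([px1, px2], [poly], "awo")
        assert r.mean_column == pytest.approx((8 * 1 + 4 * 3) / 12, rel=1e-6)

    def test_window_additivity(self):
        rng = np.random.default_rng(3)
        obs = []
        for day in range(4):
            date = DATE + dt.timedelta(days=day)
            for k in range(6):
                obs.append(
                    make_rect_pixel(
                        lon=rng.uniform(-0.05, 0.05), lat=rng.uniform(-0.05, 0.05),
                        value=float(rng.uniform(1, 5)), pid=f"{day}_{k}", date=date,
                    )
                )
        polys = [admin("p", box(-0.02, -0.02, 0.02, 0.02)), admin("q", box(0.0, 0.0, 0.04, 0.03))]
        full = aggregate_polygons(obs, polys, "pgo")
        # combine per-day numerators/denominators
        num = {p.geoid: 0.0 for p in polys}
        den = {p.geoid: 0.0 for p in polys}
        for day in range(4):
            date = DATE + dt.timedelta(days=day)
            win = TemporalWindow(date, date, "daily")
            for r in aggregate_polygons(obs, polys, "pgo", win):
                if r.mean_column is not None:
                    num[r.geoid] += r.mean_column * r.total_weight
                    den[r.geoid] += r.total_weight
        for r in full:
            assert r.mean_column == pytest.approx(num[r.geoid] / den[r.geoid], rel=1e-12)
            assert r.total_weight == pytest.approx(den[r.geoid], rel=1e-12)

    @pytest.mark.parametrize("method", ["pgo", "awo"])
    def test_weighted_mean_bounded_by_contributing_values(self, method):
        rng = np.random.default_rng(11)
        values = rng.uniform(0.5, 9.0, 12)
        obs = [
            make_rect_pixel(
                lon=rng.uniform(-0.08, 0.08), lat=rng.uniform(-0.08, 0.08),
                value=float(v), pid=str(i),
            )
            for i, v in enumerate(values)
        ]
        polys = [admin(f"g{k}", box(-0.03 + 0.02 * k, -0.03, 0.01 + 0.02 * k, 0.02)) for k in range(3)]
        for r in aggregate_polygons(obs, polys, method):
            if r.mean_column is not None:
                assert values.min() - 1e-9 <= r.mean_column <= values.max() + 1e-9

    def test_no_polygons_returns_empty(self):
        assert aggregate_polygons([make_rect_pixel()], [], "pgo") == []

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            aggregate_polygons([], [admin("p", box(0, 0, 1, 1))], "nearest")


class TestAggregateGrid:
    def test_constant_field_constant_grid(self):
        obs = [
            make_rect_pixel(lon=0.005 + 0.01 * i, lat=0.005 + 0.01 * j,
                            along_km=1.2, across_km=1.2, value=4.0, pid=f"{i}{j}")
            for i in range(4) for j in range(4)
        ]
        grid = GridSpec(lon0=0.0, lat0=0.0, resolution=0.01, n_lon=4, n_lat=4)
        res = aggregate_grid(obs, grid)
        assert np.allclose(res.mean, 4.0)

    def test_single_pixel_covering_four_cells(self):
        # 0.02 x 0.02 deg footprint exactly covering a 2x2 block of cells
        km = 0.02 * KM_PER_DEG
        px = make_rect_pixel(lon=0.01, lat=0.01, along_km=km, across_km=km,
                             azimuth_deg=90.0, value=2.5)
        grid = GridSpec(lon0=0.0, lat0=0.0, resolution=0.01, n_lon=2, n_lat=2)
        res = aggregate_grid([px], grid)
        assert np.allclose(res.mean, 2.5)

    def test_two_pixels_in_three_to_one_area_ratio(self):
        # cell [0,0.01)^2; pixel A covers the left 3/4, pixel B the right 1/4
        h = 0.01 * KM_PER_DEG
        pa = make_rect_pixel(lon=0.00375, lat=0.005, along_km=h, across_km=0.0075 * KM_PER_DEG,
                             azimuth_deg=90.0, value=2.0, pid="a")
        pb = make_rect_pixel(lon=0.00875, lat=0.005, along_km=h, across_km=0.0025 * KM_PER_DEG,
                             azimuth_deg=90.0, value=6.0, pid="b")
        grid = GridSpec(lon0=0.0, lat0=0.0, resolution=0.01, n_lon=1, n_lat=1)
        res = aggregate_grid([pa, pb], grid)
        assert res.mean[0, 0] == pytest.approx(3.0, rel=1e-9)

    def test_uncovered_cells_missing(self):
        px = make_rect_pixel(lon=0.005, lat=0.005, along_km=1.0, across_km=1.0)
        grid = GridSpec(lon0=0.0, lat0=0.0, resolution=0.01, n_lon=10, n_lat=10)
        res = aggregate_grid([px], grid)
        assert np.isnan(res.mean[9, 9])


class TestAssignGridToPolygons:
    def _grid_result(self, mean):
        mean = np.asarray(mean, dtype=float)
        spec = GridSpec(lon0=0.0, lat0=0.0, resolution=0.01,
                        n_lon=mean.shape[1], n_lat=mean.shape[0])
        win = TemporalWindow(DATE, DATE, "daily")
        return GridResult(spec=spec, mean=mean, weight=np.ones_like(mean), window=win)

    def test_large_polygon_averages_interior_cells(self):
        res = self._grid_result([[1.0, 3.0], [np.nan, np.nan]])
        poly = admin("big", box(0.0, 0.0, 0.02, 0.01))  # contains the two bottom cells
        (out,) = assign_grid_to_polygons(res, [poly])
        assert out.mean_column == pytest.approx(2.0)
        assert out.n_obs == 2

    def test_tiny_polygon_takes_nearest_cell(self):
        res = self._grid_result([[1.0, 3.0], [5.0, 7.0]])
        poly = admin("tiny", box(0.012, 0.001, 0.013, 0.002))  # inside cell (0, 1)
        (out,) = assign_grid_to_polygons(res, [poly])
        assert out.mean_column == pytest.approx(3.0)

    def test_tie_breaks_to_lowest_row_col(self):
        res = self._grid_result([[1.0, 3.0], [5.0, 7.0]])
        # centroid exactly equidistant from all four cell centres
        poly = admin("mid", box(0.00999, 0.00999, 0.01001, 0.01001))
        (out,) = assign_grid_to_polygons(res, [poly])
        assert out.mean_column == pytest.approx(1.0)

    def test_missing_nearest_cell_propagates(self):
        res = self._grid_result([[np.nan, 3.0], [5.0, 7.0]])
        poly = admin("tiny", box(0.002, 0.002, 0.003, 0.003))
        (out,) = assign_grid_to_polygons(res, [poly])
        assert out.mean_column is None
        assert out.n_obs == 0


class TestCountMissing:
    def test_dense_swath_no_missing(self):
        obs = [
            make_rect_pixel(lon=i * 0.03, lat=j * 0.03, value=2.0, pid=f"{i}{j}")
            for i in range(-2, 3) for j in range(-2, 3)
        ]
        polys = [admin("a", box(-0.02, -0.02, 0.0, 0.0)), admin("b", box(0.0, 0.0, 0.02, 0.02))]
        res = {
            m: aggregate_polygons(obs, polys, m) for m in ("pgo", "awo")
        }
        assert count_missing(res) == {"pgo": 0, "awo": 0}

    def test_all_observations_removed(self):
        polys = [admin("a", box(0, 0, 0.01, 0.01))]
        res = {m: aggregate_polygons([], polys, m) for m in ("pgo", "awo")}
        assert count_missing(res) == {"pgo": 1, "awo": 1}

    def test_cloud_masked_interior_pixel(self):
        """A polygon wholly inside a cloud-masked pixel: AWO has no donor,
        PGO borrows tail weight from the surrounding valid pixels."""
        obs = []
        for i in range(-1, 2):
            for j in range(-1, 2):
                qa = 0.3 if (i, j) == (0, 0) else 0.9  # interior pixel cloud-masked
                obs.append(
                    make_rect_pixel(lon=i * 3.5 * DEG, lat=j * 5.5 * DEG,
                                    value=2.0, qa=qa, pid=f"{i}{j}")
                )
        kept = screen_qa(obs)
        assert len(kept) == 8
        inner = admin("inner", box(-0.5 * DEG, -0.5 * DEG, 0.5 * DEG, 0.5 * DEG))
        outer = admin("outer", box(4 * DEG, 4 * DEG, 6 * DEG, 6 * DEG))
        res = {m: aggregate_polygons(kept, [inner, outer], m) for m in ("pgo", "awo")}
        missing = count_missing(res)
        assert missing["pgo"] < missing["awo"]
        pgo_inner = next(r for r in res["pgo"] if r.geoid == "inner")
        assert pgo_inner.mean_column == pytest.approx(2.0, rel=1e-9)
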