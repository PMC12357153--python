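"""Readers and writers for swath, polygon, demographic and result files.

Supported dialects
------------------
* Swath observations: flat CSV (columns ``id, date, lon, lat, lon0..lon3,
  lat0..lat3, value, qa``) or NetCDF with per-pixel centre/corner arrays.
  NetCDF variable names are resolved through a small editable dialect
  table (default: TEMIS-style names), because product layouts drift
  between processor versions.
* Administrative polygons: GeoJSON FeatureCollections with a GEOID
  property.  Shapefiles are not read directly — convert to GeoJSON first
  (e.g. with ogr2ogr); the reader raises a format error naming the fix.
* Demographics / region maps / results: plain CSV keyed by geoid, with
  missing values encoded as empty fields.

All coordinates are WGS84 lon/lat; areas and distances use the local
equirectangular scaling shared with the geometry module.  Every file this
package writes, it reads back losslessly.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

from .disparity import DemographicTable, INCOME_COLUMNS, RACE_COLUMNS
from .errors import FormatError, ValidationError
from .oversampler import AdminPolygon, PolygonAverage, TemporalWindow
from .response_kernel import polygon_area_km2
from .swath_geometry import PixelObservation, normalize_corners

logger = logging.getLogger(__name__)

SWATH_CSV_COLUMNS = [
    "id", "date", "lon", "lat",
    "lon0", "lat0", "lon1", "lat1", "lon2", "lat2", "lon3", "lat3",
    "value", "qa",
]

#: NetCDF variable-name dialects; edit or extend for other product layouts.
NETCDF_DIALECTS: dict[str, dict[str, str]] = {
    "default": {
        "lon": "longitude",
        "lat": "latitude",
        "lon_bounds": "longitude_bounds",
        "lat_bounds": "latitude_bounds",
        "value": "nitrogendioxide_tropospheric_column",
        "qa": "qa_value",
        "date": "date",
    }
}

RESULT_COLUMNS = [
    "geoid", "window_start", "window_end", "method",
    "mean_column_1e15", "total_weight", "n_obs",
]


# ---------------------------------------------------------------------------
# swath observations
# ---------------------------------------------------------------------------


def _records_from_table(df: pd.DataFrame) -> list[PixelObservation]:
    observations = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            corners = normalize_corners(
                ((row.lon0, row.lat0), (row.lon1, row.lat1),
                 (row.lon2, row.lat2), (row.lon3, row.lat3)),
                float(row.lon), float(row.lat),
            )
            observations.append(
                PixelObservation(
                    id=str(row.id),
                    date=_dt.date.fromisoformat(str(row.date)),
                    lon=float(row.lon),
                    lat=float(row.lat),
                    corners=corners,
                    value=float(row.value),
                    qa=float(row.qa),
                )
            )
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d malformed swath rows", skipped)
    return observations


def read_l2_swath(path: str | Path, dialect: str = "default") -> list[PixelObservation]:
    """Read Level-2 footprints from CSV or NetCDF into normalized records."""
    path = Path(path)
    if path.suffix.lower() == ".nc":
        return _read_swath_netcdf(path, dialect)
    df = pd.read_csv(path)
    missing = [c for c in SWATH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"swath CSV {path} missing column(s): {', '.join(missing)}")
    return _records_from_table(df)


def _read_swath_netcdf(path: Path, dialect: str) -> list[PixelObservation]:
    import xarray as xr

    names = NETCDF_DIALECTS[dialect]
    ds = xr.open_dataset(path)
    try:
        for key, var in names.items():
            if var not in ds and not (key == "date" and "date" in ds.attrs):
                raise FormatError(f"swath NetCDF {path} missing variable: {var}")
        lon = np.asarray(ds[names["lon"]]).ravel()
        lat = np.asarray(ds[names["lat"]]).ravel()
        lonb = np.asarray(ds[names["lon_bounds"]]).reshape(len(lon), 4)
        latb = np.asarray(ds[names["lat_bounds"]]).reshape(len(lon), 4)
        value = np.asarray(ds[names["value"]]).ravel()
        qa = np.asarray(ds[names["qa"]]).ravel()
        dates = np.asarray(ds[names["date"]]).ravel()
        if np.issubdtype(dates.dtype, np.datetime64):  # xarray CF-decoded
            date_strs = [str(d) for d in pd.to_datetime(dates).date]
        else:  # raw days since epoch
            epoch = _dt.date(1970, 1, 1)
            date_strs = [(epoch + _dt.timedelta(days=int(d))).isoformat() for d in dates]
        df = pd.DataFrame(
            {
                "id": [f"px{i:06d}" for i in range(len(lon))],
                "date": date_strs,
                "lon": lon, "lat": lat,
                "lon0": lonb[:, 0], "lat0": latb[:, 0],
                "lon1": lonb[:, 1], "lat1": latb[:, 1],
                "lon2": lonb[:, 2], "lat2": latb[:, 2],
                "lon3": lonb[:, 3], "lat3": latb[:, 3],
                "value": value, "qa": qa,
            }
        )
    finally:
        ds.close()
    return _records_from_table(df)


def write_swath_csv(observations: Sequence[PixelObservation], path: str | Path) -> None:
    rows = []
    for o in observations:
        c = o.corners
        rows.append(
            [o.id, o.date.isoformat(), o.lon, o.lat,
             c[0][0], c[0][1], c[1][0], c[1][1], c[2][0], c[2][1], c[3][0], c[3][1],
             o.value, o.qa]
        )
    pd.DataFrame(rows, columns=SWATH_CSV_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def write_swath_netcdf(
    observations: Sequence[PixelObservation], path: str | Path, dialect: str = "default"
) -> None:
    """Write footprints as a NetCDF3 file (classic format, scipy engine)."""
    import xarray as xr

    names = NETCDF_DIALECTS[dialect]
    epoch = _dt.date(1970, 1, 1)
    n = len(observations)
    corners = np.array([o.corners for o in observations])  # (n, 4, 2)
    ds = xr.Dataset(
        {
            names["lon"]: ("obs", np.array([o.lon for o in observations])),
            names["lat"]: ("obs", np.array([o.lat for o in observations])),
            names["lon_bounds"]: (("obs", "corner"), corners[:, :, 0] if n else np.zeros((0, 4))),
            names["lat_bounds"]: (("obs", "corner"), corners[:, :, 1] if n else np.zeros((0, 4))),
            names["value"]: ("obs", np.array([o.value for o in observations])),
            names["qa"]: ("obs", np.array([o.qa for o in observations])),
            names["date"]: ("obs", np.array([(o.date - epoch).days for o in observations], dtype="int32")),
        }
    )
    ds[names["date"]].attrs["units"] = "days since 1970-01-01"
    ds[names["value"]].attrs["units"] = "1e15 molecules/cm^2"
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------


def read_polygons(path: str | Path, geoid_property: str = "GEOID") -> list[AdminPolygon]:
    """Read GEOID-keyed polygons from a GeoJSON FeatureCollection.

    Geometries are validity-repaired with a zero-width buffer; areas are
    computed in km^2.  Duplicate GEOIDs are an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".shp", ".dbf", ".shx"):
        raise FormatError(
            "Shapefile reading is not supported; convert to GeoJSON "
            "(e.g. `ogr2ogr -f GeoJSON out.geojson in.shp`) and retry"
        )
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    polygons: list[AdminPolygon] = []
    seen: dict[str, int] = {}
    for feat in features:
        props = feat.get("properties") or {}
        geoid = props.get(geoid_property, props.get(geoid_property.lower()))
        if geoid is None:
            raise FormatError(f"feature without {geoid_property!r} property in {path}")
        geoid = str(geoid)
        seen[geoid] = seen.get(geoid, 0) + 1
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            geom = geom.buffer(0)
        polygons.append(
            AdminPolygon(
                geoid=geoid,
                geometry=geom,
                area_km2=polygon_area_km2(geom),
                region_id=props.get("region_id"),
            )
        )
    duplicates = sorted(g for g, k in seen.items() if k > 1)
    if duplicates:
        raise FormatError(f"duplicate GEOID(s) in {path}: {', '.join(duplicates)}")
    logger.info("read %d polygons from %s", len(polygons), path)
    return polygons


def write_polygons_geojson(polygons: Sequence[AdminPolygon], path: str | Path) -> None:
    features = []
    for p in polygons:
        props = {"GEOID": p.geoid, "area_km2": round(p.area_km2, 9)}
        if p.region_id is not None:
            props["region_id"] = p.region_id
        features.append(
            {"type": "Feature", "properties": props,
             "geometry": shapely_mapping(shapely.set_precision(p.geometry, 1e-9))}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# demographics / region map
# ---------------------------------------------------------------------------


def read_demographics(path: str | Path) -> DemographicTable:
    df = pd.read_csv(path, dtype={"geoid": str})
    if "geoid" not in df.columns:
        raise FormatError(f"demographics CSV {path} missing column: geoid")
    missing = [c for c in RACE_COLUMNS + INCOME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"demographics CSV {path} missing column(s): {', '.join(missing)}")
    df = df.set_index("geoid")
    if (df[RACE_COLUMNS + INCOME_COLUMNS] < 0).any().any():
        raise ValidationError(f"negative population count(s) in {path}")
    return DemographicTable(df)


def write_demographics(table: DemographicTable, path: str | Path) -> None:
    table.table.to_csv(path, float_format="%.10g")


def read_region_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype=str)
    for col in ("geoid", "region_id"):
        if col not in df.columns:
            raise FormatError(f"region map CSV {path} missing column: {col}")
    return df.set_index("geoid")["region_id"]


def write_region_map(region_map: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    s = pd.Series(dict(region_map)) if not isinstance(region_map, pd.Series) else region_map
    s.rename("region_id").rename_axis("geoid").to_csv(path)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def results_to_frame(results: Sequence[PolygonAverage]) -> pd.DataFrame:
    rows = [
        {
            "geoid": r.geoid,
            "window_start": r.window.start.isoformat(),
            "window_end": r.window.end.isoformat(),
            "method": r.method,
            "mean_column_1e15": r.mean_column,
            "total_weight": r.total_weight,
            "n_obs": r.n_obs,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values(
        ["geoid", "window_start"], kind="stable", ignore_index=True
    )


def write_results(
    results: Sequence[PolygonAverage],
    path: str | Path,
    mode: str = "csv",
    polygons: Sequence[AdminPolygon] | None = None,
) -> None:
    """Write per-polygon averages as CSV, or join them onto polygon GeoJSON.

    Missing polygons keep their row with an empty mean field and n_obs as
    reported.  Rows are ordered by (geoid, window_start) for stable diffs.
    """
    if not results:
        raise ValidationError("no results to write")
    df = results_to_frame(results)
    if mode == "csv":
        df.to_csv(path, index=False, float_format="%.10g")
        return
    if mode != "geojson-join":
        raise ValueError(f"unknown write mode {mode!r}")
    if polygons is None:
        raise ValidationError("geojson-join mode needs the polygon collection")
    by_geoid: dict[str, list[PolygonAverage]] = {}
    for r in results:
        by_geoid.setdefault(r.geoid, []).append(r)
    features = []
    for p in polygons:
        props: dict = {"GEOID": p.geoid, "area_km2": round(p.area_km2, 9)}
        if p.region_id is not None:
            props["region_id"] = p.region_id
        for r in by_geoid.get(p.geoid, []):
            props[f"mean_column_{r.window.label}_{r.method}"] = r.mean_column
        features.append(
            {"type": "Feature", "properties": props,
             "geometry": shapely_mapping(p.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


def read_results(path: str | Path) -> list[PolygonAverage]:
    df = pd.read_csv(path, dtype={"geoid": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results CSV {path} missing column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        window = TemporalWindow(
            _dt.date.fromisoformat(row.window_start),
            _dt.date.fromisoformat(row.window_end),
            "daily" if row.window_start == row.window_end else "full",
        )
        mean = None if pd.isna(row.mean_column_1e15) else float(row.mean_column_1e15)
        out.append(
            PolygonAverage(
                geoid=row.geoid,
                window=window,
                mean_column=mean,
                total_weight=float(row.total_weight),
                n_obs=int(row.n_obs),
                method=str(row.method),
            )
        )
    return out
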