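"""Pixel-local coordinate frames for swath footprints.

A Level-2 footprint is a quadrilateral traced by four corners in WGS84
lon/lat.  The spatial response function is defined in a pixel-local
Cartesian frame whose axes are the along-track (x) and across-track (y)
directions, in kilometres from the pixel centre.  This module converts
between the two.

Conventions
-----------
* Corners are stored counterclockwise, starting from the corner that lies
  at (-along, -across) relative to the centre.  With that ordering the
  trailing across-track edge is (corner3, corner0) and the leading one is
  (corner1, corner2).
* ``across_unit`` is the +90 deg counterclockwise rotation of
  ``along_unit``; the response function is even in both axes so only
  consistency matters.
* Distances use a local equirectangular tangent plane: km per degree of
  latitude is a constant, km per degree of longitude scales with
  cos(latitude) at the frame origin.  The error at pixel scale (< 10 km)
  is well below 0.2% and largely cancels in relative weights.

Antimeridian-crossing and near-polar (|lat| >= 85 deg) footprints are
rejected: the intended domain is continental, and a tangent-plane frame
is not meaningful there.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError

#: Mean kilometres per degree of great-circle arc (Earth circumference / 360).
KM_PER_DEG = 111.19

#: Latitude beyond which local tangent frames are refused.
MAX_ABS_LAT = 85.0

LonLat = tuple[float, float]


@dataclass(frozen=True)
class PixelObservation:
    """One Level-2 footprint: geometry, retrieved column and quality flag.

    ``value`` is a tropospheric vertical column density in units of
    10^15 molecules/cm^2; ``qa`` is the retrieval quality score in [0, 1].
    """

    id: str
    date: _dt.date
    lon: float
    lat: float
    corners: tuple[LonLat, LonLat, LonLat, LonLat]
    value: float
    qa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qa <= 1.0):
            raise ValueError(f"qa must be in [0, 1], got {self.qa!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"column value must be finite, got {self.value!r}")
        if len(self.corners) != 4:
            raise ValueError("a footprint needs exactly 4 corners")


@dataclass(frozen=True)
class LocalFrame:
    """Local tangent-plane frame anchored at a pixel centre.

    ``along_unit`` / ``across_unit`` are orthonormal 2-vectors expressed in
    local east/north kilometre coordinates.
    """

    origin_lon: float
    origin_lat: float
    east_scale: float  # km per degree longitude at origin latitude
    north_scale: float  # km per degree latitude
    along_unit: tuple[float, float]
    across_unit: tuple[float, float]


def _corners_km(pixel: PixelObservation) -> np.ndarray:
    """Corners as (4, 2) east/north km offsets from the pixel centre."""
    east = KM_PER_DEG * np.cos(np.deg2rad(pixel.lat))
    north = KM_PER_DEG
    c = np.asarray(pixel.corners, dtype=float)
    return np.column_stack(((c[:, 0] - pixel.lon) * east, (c[:, 1] - pixel.lat) * north))


def build_local_frame(pixel: PixelObservation) -> LocalFrame:
    """Construct the along-/across-track frame from a footprint's corners.

    The along-track unit vector points from the midpoint of the trailing
    across-track edge (corners 3-0) to the midpoint of the leading one
    (corners 1-2); the across-track unit vector is its +90 deg
    counterclockwise rotation.

    Raises
    ------
    InvalidGeometryError
        If any edge is (near) zero length, the footprint straddles the
        antimeridian, or |lat| >= 85 deg.
    """
    if abs(pixel.lat) >= MAX_ABS_LAT:
        raise InvalidGeometryError(f"latitude {pixel.lat} out of supported range")
    lons = np.array([c[0] for c in pixel.corners])
    if lons.max() - lons.min() > 180.0:
        raise InvalidGeometryError("footprint straddles the antimeridian")

    km = _corners_km(pixel)
    edges = np.roll(km, -1, axis=0) - km
    if np.any(np.hypot(edges[:, 0], edges[:, 1]) < 1e-9):
        raise InvalidGeometryError("degenerate footprint: zero-length edge")

    leading = 0.5 * (km[1] + km[2])
    trailing = 0.5 * (km[3] + km[0])
    axis = leading - trailing
    norm = float(np.hypot(*axis))
    if norm < 1e-9:
        raise InvalidGeometryError("degenerate footprint: collapsed along-track axis")
    along = (axis[0] / norm, axis[1] / norm)
    across = (-along[1], along[0])  # +90 deg CCW
    return LocalFrame(
        origin_lon=pixel.lon,
        origin_lat=pixel.lat,
        east_scale=KM_PER_DEG * float(np.cos(np.deg2rad(pixel.lat))),
        north_scale=KM_PER_DEG,
        along_unit=along,
        across_unit=across,
    )


def to_pixel_coords(frame: LocalFrame, lon, lat):
    """Project lon/lat point(s) into (x, y) km along-/across-track.

    Accepts scalars or numpy arrays; returns a pair of the same shape.
    Valid only within the local-tangent approximation (a few degrees of
    the origin); callers enforce a truncation radius.
    """
    de = (np.asarray(lon, dtype=float) - frame.origin_lon) * frame.east_scale
    dn = (np.asarray(lat, dtype=float) - frame.origin_lat) * frame.north_scale
    ax, ay = frame.along_unit
    cx, cy = frame.across_unit
    return de * ax + dn * ay, de * cx + dn * cy


def derive_fwhm(pixel: PixelObservation, frame: LocalFrame) -> tuple[float, float]:
    """Footprint extents used as response-function FWHMs, in km.

    FWHM_x (along-track) is the distance between the midpoints of the two
    across-track edges; FWHM_y the distance between the midpoints of the
    two along-track edges.  For a rectangle these are simply its side
    lengths; for a trapezoid the mid-edge distance is the natural extent.
    """
    km = _corners_km(pixel)
    fwhm_x = float(np.hypot(*(0.5 * (km[1] + km[2]) - 0.5 * (km[3] + km[0]))))
    fwhm_y = float(np.hypot(*(0.5 * (km[2] + km[3]) - 0.5 * (km[0] + km[1]))))
    if fwhm_x <= 0 or fwhm_y <= 0:
        raise InvalidGeometryError("non-positive footprint extent")
    return fwhm_x, fwhm_y


def normalize_corners(
    corners: tuple[LonLat, ...], lon: float, lat: float
) -> tuple[LonLat, LonLat, LonLat, LonLat]:
    """Reorder ingested corners to the package's internal convention.

    Keeps the first corner fixed (the dialect mapping decides which product
    corner comes first) and enforces counterclockwise winding in the local
    tangent plane.  Input corners must already trace the quadrilateral
    boundary (no diagonal hops); readers map product corner dimensions
    accordingly.
    """
    east = KM_PER_DEG * np.cos(np.deg2rad(lat))
    c = np.asarray(corners, dtype=float)
    x = (c[:, 0] - lon) * east
    y = (c[:, 1] - lat) * KM_PER_DEG
    # shoelace signed area; negative => clockwise => reverse keeping corner 0
    area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area2 < 0:
        order = [0, 3, 2, 1]
    else:
        order = [0, 1, 2, 3]
    return tuple((float(c[i, 0]), float(c[i, 1])) for i in order)  # type: ignore[return-value]
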