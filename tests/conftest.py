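import datetime as dt

import numpy as np
import pytest

from swathagg.swath_geometry import KM_PER_DEG, PixelObservation

DATE = dt.date(2020, 6, 1)


def make_rect_pixel(
    lon=0.0,
    lat=0.0,
    along_km=5.5,
    across_km=3.5,
    azimuth_deg=90.0,
    value=2.0,
    qa=0.9,
    pid="px",
    date=DATE,
):
    """Rectangular footprint with the along-track axis at ``azimuth_deg``
    (degrees CCW from east; 90 = due north), corners in the package's
    internal order: CCW from the (-along, -across) corner."""
    th = np.deg2rad(azimuth_deg)
    along = np.array([np.cos(th), np.sin(th)])  # (east, north) km
    across = np.array([-along[1], along[0]])  # +90 deg CCW
    offsets = [(-1, -1), (1, -1), (1, 1), (-1, 1)]
    east = KM_PER_DEG * np.cos(np.deg2rad(lat))
    corners = []
    for sa, sc in offsets:
        p = 0.5 * along_km * sa * along + 0.5 * across_km * sc * across
        corners.append((lon + p[0] / east, lat + p[1] / KM_PER_DEG))
    return PixelObservation(
        id=pid, date=date, lon=lon, lat=lat, corners=tuple(corners), value=value, qa=qa
    )


@pytest.fixture
def pixel_factory():
    return make_rect_pixel


@pytest.fixture
def nadir_pixel():
    """TROPOMI-like 5.5 x 3.5 km footprint, track due north, at the equator."""
    return make_rect_pixel()
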