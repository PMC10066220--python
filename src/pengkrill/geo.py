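"""Great-circle geometry helpers shared across the pipeline.

All distances use the haversine formula on a sphere of radius 6371 km.
Local planar coordinates use an equirectangular projection centred on the
colony, adequate at the < 100 km scales of central-place foraging tracks.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_xy_km(lon, lat, lon0, lat0):
    """Project lon/lat to km east/north of a reference point (equirectangular)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    kx = EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return (lon - lon0) * kx, (lat - lat0) * ky


def offset_lonlat(lon0, lat0, dx_km, dy_km):
    """Inverse of :func:`local_xy_km`: lon/lat at (dx, dy) km east/north of origin."""
    kx = EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return lon0 + np.asarray(dx_km, dtype=float) / kx, lat0 + np.asarray(dy_km, dtype=float) / ky
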