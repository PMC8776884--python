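"""Small geodesy helpers (WGS84 degrees, spherical-earth distances)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
NM_PER_DEG_LAT = 60.0
KM_PER_NM = 1.852


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def displace(lat, lon, heading_deg, distance_nm):
    """Flat-earth displacement of (lat, lon) by ``distance_nm`` along ``heading_deg``.

    Heading is compass-style (0 = north, 90 = east). Adequate for the short
    (< 100 nm) legs the track generator produces.
    """
    theta = np.radians(heading_deg)
    dlat = distance_nm * np.cos(theta) / NM_PER_DEG_LAT
    dlon = distance_nm * np.sin(theta) / (NM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return lat + dlat, lon + dlon
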