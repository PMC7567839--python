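"""Spherical-earth helpers shared across modules.

All geodesy in this package is great-circle on a sphere of radius
6371.0088 km (IUGG mean radius). One degree of arc is therefore
pi * R / 180 = 111.195 km.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM: float = 6371.0088
KM_PER_DEG: float = np.pi * EARTH_RADIUS_KM / 180.0  # 111.19492664...


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2).

    Accepts scalars or broadcastable arrays of decimal degrees (WGS84
    lon/lat treated as spherical).
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90.0) or np.any(np.abs(lat2) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.shape else float(d)
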