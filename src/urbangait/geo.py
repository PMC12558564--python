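"""Great-circle geometry on WGS84 geographic coordinates.

All metric computations in the pipeline go through :func:`haversine_m` on a
sphere of radius 6,371,000 m (mean Earth radius); no map projection is used.
At neighborhood scale (~1 km) the spherical error is far below GPS noise.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
#: meters per degree of latitude on the reference sphere (R * pi / 180)
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters between points given in degrees.

    Accepts scalars or numpy arrays (broadcast). Symmetric; zero iff the
    points coincide.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def step_distances_m(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Consecutive haversine step lengths along a polyline; length n-1."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return np.atleast_1d(haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:]))


def meters_to_degrees(d_east_m: float, d_north_m: float, lat_deg: float) -> tuple[float, float]:
    """Local conversion of a metric offset to (dlon, dlat) degrees at a latitude."""
    dlat = d_north_m / M_PER_DEG
    dlon = d_east_m / (M_PER_DEG * np.cos(np.radians(lat_deg)))
    return dlon, dlat


def local_xy_m(lon, lat, lon0: float, lat0: float, lat_ref: float | None = None):
    """Equirectangular local coordinates (meters east/north of an anchor).

    Used only for grid binning (heatmaps), never for speed computation.
    """
    if lat_ref is None:
        lat_ref = lat0
    x = (np.asarray(lon, dtype=float) - lon0) * M_PER_DEG * np.cos(np.radians(lat_ref))
    y = (np.asarray(lat, dtype=float) - lat0) * M_PER_DEG
    return x, y


def kmh_to_mps(v_kmh: float) -> float:
    """Convert km/h to m/s (5 km/h -> 1.39 m/s at 2-decimal rounding)."""
    return v_kmh / 3.6


def mps_to_kmh(v_mps: float) -> float:
    """Convert m/s to km/h (0.74 m/s -> 2.66 km/h at 2-decimal rounding)."""
    return v_mps * 3.6
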