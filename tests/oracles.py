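"""Independent reference implementations used only as test oracles.

These deliberately re-derive results from first principles (direct window
enumeration, an alternative great-circle formula, even-odd ray casting) and
share no code with the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def great_circle_vincenty_m(lon1, lat1, lon2, lat2, radius=6_371_000.0) -> float:
    """Spherical distance via the Vincenty arctan form (stable at all separations)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    num = math.hypot(math.cos(p2) * math.sin(dl),
                     math.cos(p1) * math.sin(p2)
                     - math.sin(p1) * math.cos(p2) * math.cos(dl))
    den = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.atan2(num, den)


def brute_force_windows(t, lon, lat, speed, *, band_low=0.30, band_high=1.39,
                        min_samples=20, min_disp_m=20.0, max_gap_s=2.0):
    """All valid walking windows by direct O(n^2) enumeration.

    A window [i, j] is a run iff every sample speed is in [band_low,
    band_high) and every internal timestamp gap is <= max_gap_s; it is
    maximal iff it cannot be extended by one sample on either side; it is
    valid iff additionally it has >= min_samples samples and first-to-last
    great-circle displacement >= min_disp_m. Valid maximal windows are
    disjoint, returned left to right as (i, j) pairs.
    """
    t = np.asarray(t, float)
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    speed = np.asarray(speed, float)
    n = len(t)

    def ok(k):
        return band_low <= speed[k] < band_high

    out = []
    for i in range(n):
        if not ok(i):
            continue
        left_extendable = i > 0 and ok(i - 1) and (t[i] - t[i - 1]) <= max_gap_s
        if left_extendable:
            continue
        for j in range(i, n):
            if not ok(j) or (j > i and (t[j] - t[j - 1]) > max_gap_s):
                break
            right_extendable = (j + 1 < n and ok(j + 1)
                                and (t[j + 1] - t[j]) <= max_gap_s)
            if right_extendable:
                continue
            if (j - i + 1 >= min_samples
                    and great_circle_vincenty_m(lon[i], lat[i], lon[j], lat[j])
                    >= min_disp_m
                    and not np.any(speed[i:j + 1] >= band_high)):
                out.append((i, j))
            break  # this i has exactly one maximal window
    return out


def point_in_polygon_evenodd(lon, lat, ring) -> bool:
    """Even-odd ray casting; ``ring`` is a closed list of (lon, lat) vertices."""
    inside = False
    pts = list(ring)
    if pts[0] != pts[-1]:
        pts.append(pts[0])
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        if (y1 > lat) != (y2 > lat):
            x_cross = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
            if lon < x_cross:
                inside = not inside
    return inside


def random_speed_stream(rng: np.random.Generator, n: int | None = None):
    """A synthetic speed series with persistent dwell/walk/vehicle states.

    Positions advance by speed*dt along a wandering heading (speed column is
    exactly consistent with the positions); timestamps carry occasional 2 s
    and 3 s gaps so the gap-bridging rules are exercised, and dithering
    (heading reversal) episodes exercise the displacement rule.
    """
    if n is None:
        n = int(rng.integers(30, 201))
    m_per_deg = 6_371_000.0 * np.pi / 180.0
    lon, lat = 103.8 + rng.uniform(-0.01, 0.01), 1.35 + rng.uniform(-0.01, 0.01)
    heading = rng.uniform(0, 2 * np.pi)
    state = int(rng.integers(0, 3))
    dither = rng.random() < 0.3
    t = 0.0
    rows = []
    for _ in range(n):
        if rng.random() < 0.05:
            state = int(rng.integers(0, 3))
        v = [rng.uniform(0.0, 0.30), rng.uniform(0.30, 1.39),
             rng.uniform(1.39, 5.5)][state]
        dt = rng.choice([1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
                        p=[0.9, 0.02, 0.02, 0.01, 0.03, 0.02])
        if dither and rng.random() < 0.5:
            heading += np.pi  # pace back and forth
        elif rng.random() < 0.1:
            heading += rng.uniform(-1, 1)
        step = v * dt
        lon += step * np.cos(heading) / (m_per_deg * np.cos(np.radians(lat)))
        lat += step * np.sin(heading) / m_per_deg
        t += dt
        rows.append((t, lon, lat, v))
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
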