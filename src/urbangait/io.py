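"""Readers and writers for the pipeline's interchange formats.

Zone maps travel as GeoJSON FeatureCollections whose features carry the
master-plan attribute names ``GPR`` (number) and ``LU_DESC`` (string); tracker
streams and tables travel as CSV with ISO-8601 UTC timestamps. All readers
accept real exports using the same headers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .synthetic_world import Zone, ZoneMap


def t_to_iso(t) -> pd.Series:
    """Seconds-since-epoch to ISO-8601 UTC strings."""
    return pd.to_datetime(np.asarray(t, dtype=float), unit="s", utc=True).strftime(
        "%Y-%m-%dT%H:%M:%S.%f").str.rstrip("0").str.rstrip(".")


def iso_to_t(ts: pd.Series) -> np.ndarray:
    """ISO-8601 UTC strings to float seconds since epoch."""
    dt = pd.to_datetime(ts, utc=True, format="ISO8601")
    return dt.astype("int64").to_numpy() / 1e9


def write_zone_map(zone_map: ZoneMap, path: str | Path) -> None:
    """Serialize a zone map as a GeoJSON FeatureCollection.

    Extent and (for grid maps) grid shape are stored as foreign members so
    the round trip is lossless.
    """
    fc = {
        "type": "FeatureCollection",
        "bbox": list(zone_map.extent),
        "grid_shape": list(zone_map.grid_shape) if zone_map.grid_shape else None,
        "features": [{
            "type": "Feature",
            "geometry": mapping(z.polygon),
            "properties": {"zone_id": z.zone_id, "GPR": z.gpr, "LU_DESC": z.land_use},
        } for z in zone_map.zones],
    }
    Path(path).write_text(json.dumps(fc, indent=1))


def read_zone_map(path: str | Path) -> ZoneMap:
    """Load a zone map from GeoJSON, validating required properties.

    A feature missing ``GPR`` or ``LU_DESC`` raises a validation error naming
    the feature index; an empty collection yields an empty map with a warning.
    """
    fc = json.loads(Path(path).read_text())
    features = fc.get("features", [])
    if not features:
        warnings.warn(f"{path}: empty FeatureCollection; zone map has no zones")
        bbox = fc.get("bbox") or [0.0, 0.0, 0.0, 0.0]
        return ZoneMap(zones=[], extent=tuple(bbox), grid_shape=None)
    zones = []
    for i, feat in enumerate(features):
        props = feat.get("properties", {}) or {}
        for key in ("GPR", "LU_DESC"):
            if key not in props:
                raise ValueError(f"feature {i}: missing required property {key!r}")
        poly = shape(feat["geometry"])
        if not isinstance(poly, Polygon):
            raise ValueError(f"feature {i}: geometry must be a Polygon")
        zones.append(Zone(zone_id=int(props.get("zone_id", i)), polygon=poly,
                          gpr=float(props["GPR"]), land_use=str(props["LU_DESC"])))
    if fc.get("bbox"):
        extent = tuple(fc["bbox"])
    else:
        xs = [z.polygon.bounds for z in zones]
        extent = (min(b[0] for b in xs), min(b[1] for b in xs),
                  max(b[2] for b in xs), max(b[3] for b in xs))
    grid_shape = tuple(fc["grid_shape"]) if fc.get("grid_shape") else None
    return ZoneMap(zones=zones, extent=extent, grid_shape=grid_shape)


def write_gps_csv(gps: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"timestamp_utc": t_to_iso(gps["t"]),
                        "lat": gps["lat"], "lon": gps["lon"]})
    out.to_csv(path, index=False, float_format="%.8f")


def read_gps_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({"t": iso_to_t(df["timestamp_utc"]),
                         "lat": df["lat"], "lon": df["lon"]})


def write_accel_csv(accel: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"timestamp_utc": t_to_iso(accel["t"]),
                        "ax": accel["ax"], "ay": accel["ay"], "az": accel["az"]})
    out.to_csv(path, index=False, float_format="%.5f")


def read_accel_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({"t": iso_to_t(df["timestamp_utc"]),
                         "ax": df["ax"], "ay": df["ay"], "az": df["az"]})


def write_truth_csv(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.copy()
    out.insert(0, "timestamp_utc", t_to_iso(out.pop("t")))
    out.to_csv(path, index=False)


def write_roster_csv(roster: pd.DataFrame, path: str | Path) -> None:
    roster.to_csv(path, index=False, float_format="%.6f")


def read_roster_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks_csv(tracks_frame: pd.DataFrame, path: str | Path) -> None:
    out = tracks_frame.copy()
    for col in ("start_ts", "end_ts"):
        out[col] = t_to_iso(out[col]) if len(out) else out[col]
    out.to_csv(path, index=False, float_format="%.6f")
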