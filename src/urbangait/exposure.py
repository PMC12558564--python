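"""Environmental context of walking seconds: zones, buffers, strata, heatmaps.

Every validated walking-track second is assigned to the zone containing it
(point-in-polygon with a fixed lower-left-inclusive edge rule), then pooled
into per-participant exposure records by gross plot ratio or land-use
category: seconds walked (reported as minutes per week) and duration-weighted
mean DGS per stratum. A metric grid heatmap of mean walking speed mirrors the
case-example visualization (blue = slow, red = fast over the walking band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_m, local_xy_m
from .synthetic_world import Zone, ZoneMap
from .track_pipeline import TRACK_BAND_LOW_MPS, MODE_THRESHOLD_MPS


def locate_zone(point: tuple[float, float], zone_map: ZoneMap) -> Zone | None:
    """Zone whose polygon contains the (lon, lat) point, or None outside all.

    Boundary points follow the map's lower-left-inclusive rule so that every
    interior point belongs to exactly one zone.
    """
    return zone_map.zone_at(point[0], point[1])


def within_home_buffer(point: tuple[float, float], home: tuple[float, float],
                       radius_m: float = 1000.0) -> bool:
    """True iff the point lies within a great-circle radius of home.

    The neighborhood buffer of the study design (400-1000 m around the home);
    monotone in the radius by construction.
    """
    if radius_m <= 0:
        raise ValueError("buffer radius must be positive")
    return haversine_m(point[0], point[1], home[0], home[1]) <= radius_m


def assign_zones(steps: pd.DataFrame, zone_map: ZoneMap) -> pd.DataFrame:
    """Attach zone_id, gpr and land_use to per-step walking records.

    Steps outside every zone get zone_id -1 and the sentinel stratum
    'unzoned' (reported separately, never silently dropped).
    """
    out = steps.copy()
    zone_ids = np.empty(len(out), dtype=int)
    gprs = np.full(len(out), np.nan)
    uses = np.empty(len(out), dtype=object)
    lons = out["lon"].to_numpy()
    lats = out["lat"].to_numpy()
    for k in range(len(out)):
        z = zone_map.zone_at(lons[k], lats[k])
        if z is None:
            zone_ids[k], uses[k] = -1, "unzoned"
        else:
            zone_ids[k], gprs[k], uses[k] = z.zone_id, z.gpr, z.land_use
    out["zone_id"] = zone_ids
    out["gpr"] = gprs
    out["land_use"] = uses
    return out


def exposure_table(steps: pd.DataFrame, zone_map: ZoneMap, by: str = "land_use",
                   observed_days: float = 7.0) -> pd.DataFrame:
    """Per-participant exposure records grouped by a zone attribute.

    ``by`` is 'gpr' or 'land_use'. Each record carries the seconds of
    validated walking in the stratum, the same normalized to minutes per week
    (seconds * 7/observed_days / 60), and the duration-weighted mean DGS of
    those seconds. Unzoned seconds appear under the 'unzoned' stratum, so the
    total over strata conserves total walking-track time.
    """
    if by not in ("gpr", "land_use"):
        raise ValueError("by must be 'gpr' or 'land_use'")
    if len(steps) == 0:
        return pd.DataFrame(columns=["participant_id", "stratum",
                                     "seconds_walking", "min_per_wk", "mean_dgs"])
    if by not in steps.columns:
        steps = assign_zones(steps, zone_map)
    work = steps.copy()
    if by == "gpr":
        work["stratum"] = work["gpr"].where(work["zone_id"] >= 0, other=np.nan)
        work["stratum"] = work["stratum"].astype(object).where(
            work["zone_id"] >= 0, other="unzoned")
    else:
        work["stratum"] = work["land_use"]
    work["_wspeed"] = work["speed"] * work["dt"]
    g = work.groupby(["participant_id", "stratum"], sort=True)
    out = g.agg(seconds_walking=("dt", "sum"), _wsum=("_wspeed", "sum")).reset_index()
    out["mean_dgs"] = out["_wsum"] / out["seconds_walking"]
    out["min_per_wk"] = out["seconds_walking"] * (7.0 / observed_days) / 60.0
    return out.drop(columns=["_wsum"])


def participant_stratum_cells(steps: pd.DataFrame, zone_map: ZoneMap,
                              roster: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, zone-attribute) mean-DGS cells for the statistics stage.

    Cells are the finest (participant, gpr, land_use) aggregation of zoned
    walking steps; ``roster`` (id, age, sex, education, group) supplies the
    participant covariates. Unzoned steps are left out of cells (they carry no
    environmental attribute) but remain in :func:`exposure_table` totals.
    """
    if "zone_id" not in steps.columns:
        steps = assign_zones(steps, zone_map)
    zoned = steps[steps["zone_id"] >= 0].copy()
    if len(zoned) == 0:
        return pd.DataFrame(columns=["participant_id", "gpr", "land_use",
                                     "mean_dgs", "seconds", "group", "age",
                                     "sex", "education"])
    zoned["_wspeed"] = zoned["speed"] * zoned["dt"]
    g = zoned.groupby(["participant_id", "gpr", "land_use"])
    cells = g.agg(seconds=("dt", "sum"), _wsum=("_wspeed", "sum")).reset_index()
    cells["mean_dgs"] = cells["_wsum"] / cells["seconds"]
    cells = cells.drop(columns=["_wsum"])
    keep = roster[["id", "age", "sex", "education", "group"]].rename(
        columns={"id": "participant_id"})
    return cells.merge(keep, on="participant_id", how="left")


@dataclass
class HeatmapGrid:
    """Mean walking speed on a metric grid anchored at the extent's lower left."""

    cell_m: float
    extent: tuple[float, float, float, float]
    counts: dict = field(default_factory=dict)   # (row, col) -> visit count
    speeds: dict = field(default_factory=dict)   # (row, col) -> mean speed m/s

    def to_frame(self) -> pd.DataFrame:
        rows = [{"row": rc[0], "col": rc[1], "count": c,
                 "mean_speed": self.speeds[rc]} for rc, c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["row", "col", "count", "mean_speed"])


def build_heatmap(samples: pd.DataFrame, cell_m: float = 25.0,
                  extent: tuple[float, float, float, float] | None = None,
                  ) -> HeatmapGrid:
    """Bin walking samples into a metric grid of visit counts and mean speeds.

    Positions are projected to local meters by equirectangular scaling at the
    extent's mean latitude; cells with no visits carry no speed value. Total
    visit counts equal the number of input samples.
    """
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    if extent is None:
        if len(samples) == 0:
            return HeatmapGrid(cell_m=cell_m, extent=(0, 0, 0, 0))
        extent = (samples["lon"].min(), samples["lat"].min(),
                  samples["lon"].max(), samples["lat"].max())
    grid = HeatmapGrid(cell_m=cell_m, extent=extent)
    if len(samples) == 0:
        return grid
    x0, y0, x1, y1 = extent
    x, y = local_xy_m(samples["lon"].to_numpy(), samples["lat"].to_numpy(),
                      x0, y0, lat_ref=(y0 + y1) / 2.0)
    rows = np.floor(y / cell_m).astype(int)
    cols = np.floor(x / cell_m).astype(int)
    speeds = samples["speed"].to_numpy(dtype=float)
    for r, c, v in zip(rows, cols, speeds):
        key = (int(r), int(c))
        n = grid.counts.get(key, 0)
        mean = grid.speeds.get(key, 0.0)
        grid.counts[key] = n + 1
        grid.speeds[key] = mean + (v - mean) / (n + 1)
    return grid


def heatmap_to_geojson(grid: HeatmapGrid) -> dict:
    """Occupied heatmap cells as a GeoJSON FeatureCollection of grid squares."""
    from .geo import M_PER_DEG
    import math
    x0, y0, x1, y1 = grid.extent
    cos_lat = math.cos(math.radians((y0 + y1) / 2.0))
    dlon = grid.cell_m / (M_PER_DEG * cos_lat)
    dlat = grid.cell_m / M_PER_DEG
    features = []
    for (r, c), count in sorted(grid.counts.items()):
        lon_a, lat_a = x0 + c * dlon, y0 + r * dlat
        ring = [[lon_a, lat_a], [lon_a + dlon, lat_a],
                [lon_a + dlon, lat_a + dlat], [lon_a, lat_a + dlat],
                [lon_a, lat_a]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"row": r, "col": c, "count": count,
                           "mean_speed_mps": grid.speeds[(r, c)]},
        })
    return {"type": "FeatureCollection", "features": features}


def plot_heatmap(grid: HeatmapGrid, path: str) -> None:
    """Render the heatmap to PNG, blue (slow) to red (fast) over the walking band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if grid.counts:
        rs = [rc[0] for rc in grid.counts]
        cs = [rc[1] for rc in grid.counts]
        vals = [grid.speeds[rc] for rc in grid.counts]
        sc = ax.scatter(cs, rs, c=vals, cmap="coolwarm", marker="s", s=36,
                        vmin=TRACK_BAND_LOW_MPS, vmax=MODE_THRESHOLD_MPS)
        fig.colorbar(sc, ax=ax, label="mean walking speed (m/s)")
    ax.set_xlabel(f"east (cells of {grid.cell_m:g} m)")
    ax.set_ylabel(f"north (cells of {grid.cell_m:g} m)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
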