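"""Synthetic zoning maps, cohorts and tracker streams with known ground truth.

This module emulates the study conditions end to end: a high-density urban
neighborhood (~1 km^2) tiled into zones carrying a gross plot ratio (GPR) and
a land-use category; a cohort of community-dwelling older adults (age >= 55)
with MMSE scores and education levels; and one week of 1 Hz outdoor
GPS+accelerometer logs per participant, with walking bouts whose true speed
follows a planted group x environment gait model:

    speed = base(group) + slope(group) * GPR + offset(group, land_use) + noise

clipped to the walking band [0.30, 1.39) m/s. Default slopes are +0.04 m/s
per GPR unit for the cognitively non-impaired (nonCI) group and -0.13 for the
impaired (CI) group. Streams carry realistic degradations — temporally
correlated GPS jitter (first-order Gauss-Markov, stationary sd 3 m), brief
dropouts (<= 2 s), rare position spikes (> 5 m/s apparent speed), vehicular
segments and stationary dwell — and every sample's true mode, zone and bout
membership is recorded so downstream stages can be tested against ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .cohort_stats import classify_cognition, MMSE_CUTOFFS
from .geo import M_PER_DEG, meters_to_degrees
from .track_pipeline import RawStream, TRACK_BAND_LOW_MPS, MODE_THRESHOLD_MPS

#: GPR values observed across the study neighborhoods
GPR_VALUES = (2.1, 2.5, 2.8, 3.0, 3.2, 3.5, 4.0, 4.2, 4.5, 4.9, 5.6)
#: land-use categories carried by the generator (the analyzed strata)
LAND_USES = ("residential", "commercial", "business", "community")

#: ~1.1 km x 1.1 km box in central Singapore, the scale of one study neighborhood
DEFAULT_EXTENT = (103.830, 1.345, 103.840, 1.355)

_CLIP_LOW = TRACK_BAND_LOW_MPS
_CLIP_HIGH = MODE_THRESHOLD_MPS - 0.005


@dataclass
class Zone:
    """One land parcel: a simple polygon with a GPR and a land-use category."""

    zone_id: int
    polygon: Polygon
    gpr: float
    land_use: str


@dataclass
class ZoneMap:
    """A set of zones tiling a WGS84 extent (lon_min, lat_min, lon_max, lat_max).

    Grid-generated maps keep their (n_rows, n_cols) shape for O(1) containment
    lookup; arbitrary polygon sets fall back to shapely. Boundary points are
    assigned lower-left inclusively: a shared edge belongs to the zone whose
    left/bottom edge it is (the extent's own top/right boundary falls to the
    adjacent outermost zone).
    """

    zones: list[Zone]
    extent: tuple[float, float, float, float]
    grid_shape: tuple[int, int] | None = None  # (n_rows, n_cols)

    def zone_at(self, lon: float, lat: float) -> Zone | None:
        x0, y0, x1, y1 = self.extent
        if not (x0 <= lon <= x1 and y0 <= lat <= y1):
            return None
        if self.grid_shape is not None:
            n_rows, n_cols = self.grid_shape
            dx = (x1 - x0) / n_cols
            dy = (y1 - y0) / n_rows
            col = min(int((lon - x0) // dx), n_cols - 1)
            row = min(int((lat - y0) // dy), n_rows - 1)
            return self.zones[row * n_cols + col]
        from shapely.geometry import Point
        p = Point(lon, lat)
        hits = [z for z in self.zones if z.polygon.covers(p)]
        if not hits:
            return None
        # lower-left inclusive tie-break on shared edges
        return max(hits, key=lambda z: (z.polygon.bounds[0], z.polygon.bounds[1]))

    def total_area_deg2(self) -> float:
        return float(sum(z.polygon.area for z in self.zones))

    def gpr_of(self, zone_id: int) -> float:
        return self.zones[zone_id].gpr


@dataclass
class ParticipantProfile:
    """Demographics, cognition and residence of one participant."""

    id: str
    age: float
    sex: str                      # female | male
    education: str                # none | primary | secondary_plus
    mmse: int
    home: tuple[float, float]     # (lon, lat)
    subzone: str

    @property
    def group(self) -> str:
        return classify_cognition(self.education, self.mmse)


@dataclass
class GaitModel:
    """Planted group x environment gait-speed structure.

    Defaults reproduce the study's signed effects: GPR slope +0.04 m/s per
    unit for nonCI, -0.13 for CI; land-use offsets make nonCI faster in
    business/commercial zones and CI faster in community/residential ones.
    Bases are calibrated so each group's expected speed under uniform
    exposure to the observed GPR set (mean 3.664) matches the study's group
    means (nonCI 0.75, CI 0.73 m/s). Noise is a per-bout N(0, noise_sd) draw.
    """

    base_speed_nonCI: float = 0.596
    base_speed_CI: float = 1.214
    gpr_slope_nonCI: float = 0.04
    gpr_slope_CI: float = -0.13
    landuse_offsets: dict = field(default_factory=lambda: {
        "nonCI": {"residential": 0.0, "commercial": 0.03,
                  "business": 0.02, "community": -0.02},
        "CI": {"residential": 0.0, "commercial": -0.03,
               "business": -0.03, "community": 0.03},
    })
    noise_sd: float = 0.05

    def target_speed(self, group: str, gpr: float, land_use: str) -> float:
        """Pre-noise, pre-clip model prediction in m/s."""
        if group == "nonCI":
            v = self.base_speed_nonCI + self.gpr_slope_nonCI * gpr
        elif group == "CI":
            v = self.base_speed_CI + self.gpr_slope_CI * gpr
        else:
            raise ValueError(f"unknown group {group!r}")
        return v + self.landuse_offsets[group][land_use]

    def clipped_speed(self, group: str, gpr: float, land_use: str,
                      noise: float = 0.0) -> float:
        return float(np.clip(self.target_speed(group, gpr, land_use) + noise,
                             _CLIP_LOW, _CLIP_HIGH))

    def validate(self, zone_map: ZoneMap) -> None:
        """Reject configurations whose pre-clip speeds leave [0, 5] m/s."""
        for z in zone_map.zones:
            for group in ("nonCI", "CI"):
                v = self.target_speed(group, z.gpr, z.land_use)
                if not (0.0 <= v <= 5.0):
                    raise ValueError(
                        f"gait model misconfigured: {group} speed {v:.2f} m/s "
                        f"at GPR {z.gpr}, {z.land_use} is outside [0, 5]")


@dataclass
class GroundTruth:
    """Per-sample truth labels and the list of planted walking bouts.

    ``labels``: one row per emitted GPS sample (t, mode, zone_id, speed_true).
    ``bouts``: one row per walking bout (bout_id, start_t, end_t, n_samples,
    true_mean_speed), where true_mean_speed is the true path distance over the
    bout duration — exactly what a perfect pipeline would report as DGS.
    """

    labels: pd.DataFrame
    bouts: pd.DataFrame


def generate_zone_map(seed: int, n_rows: int, n_cols: int,
                      extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
                      ) -> ZoneMap:
    """Partition ``extent`` into an n_rows x n_cols grid of attributed zones.

    GPR values are drawn from the observed neighborhood set and land uses from
    the four analyzed categories, reproducibly from ``seed``.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    x0, y0, x1, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate extent {extent!r}: zero area")
    rng = np.random.default_rng(seed)
    gprs = rng.choice(GPR_VALUES, size=n_rows * n_cols)
    uses = rng.choice(LAND_USES, size=n_rows * n_cols)
    dx = (x1 - x0) / n_cols
    dy = (y1 - y0) / n_rows
    zones = []
    for r in range(n_rows):
        for c in range(n_cols):
            zid = r * n_cols + c
            poly = box(x0 + c * dx, y0 + r * dy, x0 + (c + 1) * dx, y0 + (r + 1) * dy)
            zones.append(Zone(zone_id=zid, polygon=poly,
                              gpr=float(gprs[zid]), land_use=str(uses[zid])))
    return ZoneMap(zones=zones, extent=extent, grid_shape=(n_rows, n_cols))


def generate_cohort(seed: int, n: int, ci_fraction: float,
                    zone_map: ZoneMap) -> list[ParticipantProfile]:
    """Sample a cohort of older adults with a controlled CI fraction.

    Ages are truncated-normal (mean 69.2, SD 7.14, >= 55 y); sex and education
    follow the study cohort's marginals. Exactly round(n * ci_fraction)
    participants receive an MMSE at or below their education-adjusted cut-off
    (hence classify as CI), the rest above it. Homes are uniform in the map
    extent.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not (0.0 <= ci_fraction <= 1.0):
        raise ValueError("ci_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = zone_map.extent

    ages = []
    while len(ages) < n:
        a = rng.normal(69.2, 7.14)
        if a >= 55.0:
            ages.append(a)
    sexes = rng.choice(["female", "male"], size=n, p=[0.64, 0.36])
    educations = rng.choice(["none", "primary", "secondary_plus"],
                            size=n, p=[0.10, 0.42, 0.48])
    n_ci = int(round(n * ci_fraction))
    ci_idx = set(rng.choice(n, size=n_ci, replace=False).tolist())
    subzones = rng.choice(["S1", "S2", "S3"], size=n, p=[18 / 33, 8 / 33, 7 / 33])

    cohort = []
    for i in range(n):
        cutoff = MMSE_CUTOFFS[educations[i]]
        if i in ci_idx:
            mmse = int(rng.integers(max(0, cutoff - 6), cutoff + 1))
        else:
            mmse = int(rng.integers(cutoff + 1, 31))
        home = (float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1)))
        cohort.append(ParticipantProfile(
            id=f"P{i:03d}", age=float(ages[i]), sex=str(sexes[i]),
            education=str(educations[i]), mmse=mmse, home=home,
            subzone=str(subzones[i])))
    return cohort


def _day_schedule(rng: np.random.Generator) -> list[tuple[str, int]]:
    """One outdoor session: dwells, walking bouts and occasional vehicle rides."""
    episodes: list[tuple[str, int]] = []
    n_bouts = int(rng.integers(2, 5))
    for _ in range(n_bouts):
        if rng.random() < 0.3:
            episodes.append(("vehicular", int(rng.integers(60, 181))))
        episodes.append(("stationary", int(rng.integers(60, 241))))
        episodes.append(("walking", int(rng.integers(120, 601))))
    episodes.append(("stationary", int(rng.integers(60, 121))))
    return episodes


def simulate_trajectory(participant: ParticipantProfile, zone_map: ZoneMap,
                        gait: GaitModel, days: int = 7, seed: int = 0, *,
                        jitter_sd_m: float = 3.0,
                        jitter_corr_s: float = 200.0,
                        dropout_rate: float = 1 / 300,
                        spike_rate: float = 1 / 600,
                        accel_hz: float = 10.0,
                        start_epoch: float = 1_700_000_000.0 // 86400 * 86400,
                        ) -> tuple[RawStream, GroundTruth]:
    """Emit 1 Hz outdoor tracker samples for one participant over ``days`` days.

    Each day holds one outdoor session (starting between 08:00 and 10:00 local
    clock offset from ``start_epoch``) of interleaved stationary dwell,
    walking bouts and occasional vehicular rides. Walking follows piecewise-
    linear waypoint paths whose per-second speed is the gait model's clipped
    prediction for the zone currently occupied plus a per-bout noise draw;
    vehicular speed is constant in [2.0, 4.5] m/s. The emitted positions carry
    Gauss-Markov jitter, single-second dropouts and rare spike outliers; the
    accelerometer channel carries a per-bout step oscillation (1.4-2.2 Hz)
    during true walking and broadband low-amplitude noise otherwise.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if zone_map.zone_at(*participant.home) is None:
        raise ValueError("participant home lies outside the zone map")
    gait.validate(zone_map)
    rng = np.random.default_rng(seed)
    group = participant.group
    x0, y0, x1, y1 = zone_map.extent
    margin_x = (x1 - x0) * 1e-3
    margin_y = (y1 - y0) * 1e-3

    gps_frames, acc_frames, label_frames, bout_rows = [], [], [], []
    bout_counter = 0

    for day in range(days):
        session_t0 = start_epoch + day * 86400 + int(rng.integers(8 * 3600, 10 * 3600))
        lon, lat = participant.home
        t_list, lon_list, lat_list = [], [], []
        mode_list, zone_list, speed_list = [], [], []
        day_bouts = []  # (start offset, end offset, accel freq, phase)
        t_off = 0

        for mode, dur in _day_schedule(rng):
            if mode == "stationary":
                for _ in range(dur):
                    z = zone_map.zone_at(lon, lat)
                    t_list.append(t_off); lon_list.append(lon); lat_list.append(lat)
                    mode_list.append("stationary")
                    zone_list.append(-1 if z is None else z.zone_id)
                    speed_list.append(0.0)
                    t_off += 1
            else:
                heading = float(rng.uniform(0.0, 2.0 * math.pi))
                wp_timer = int(rng.integers(30, 121))
                if mode == "walking":
                    bout_noise = float(rng.normal(0.0, gait.noise_sd))
                    step_f = float(rng.uniform(1.4, 2.2))
                    step_phase = float(rng.uniform(0.0, 2.0 * math.pi))
                    bout_start_off = t_off
                else:
                    veh_speed = float(rng.uniform(2.0, 4.5))
                for _ in range(dur):
                    z = zone_map.zone_at(lon, lat)
                    if mode == "walking":
                        zz = z if z is not None else zone_map.zones[0]
                        v = gait.clipped_speed(group, zz.gpr, zz.land_use, bout_noise)
                    else:
                        v = veh_speed
                    if wp_timer <= 0:
                        heading += float(rng.uniform(-1.0, 1.0))
                        wp_timer = int(rng.integers(30, 121))
                    wp_timer -= 1
                    de = v * math.cos(heading)
                    dn = v * math.sin(heading)
                    dlon, dlat = meters_to_degrees(de, dn, lat)
                    if not (x0 + margin_x <= lon + dlon <= x1 - margin_x):
                        heading = math.pi - heading
                        dlon = -dlon
                    if not (y0 + margin_y <= lat + dlat <= y1 - margin_y):
                        heading = -heading
                        dlat = -dlat
                    lon += dlon
                    lat += dlat
                    z = zone_map.zone_at(lon, lat)
                    t_list.append(t_off); lon_list.append(lon); lat_list.append(lat)
                    mode_list.append(mode if mode == "walking" else "vehicular")
                    zone_list.append(-1 if z is None else z.zone_id)
                    speed_list.append(v)
                    t_off += 1
                if mode == "walking":
                    day_bouts.append((bout_start_off, t_off - 1, step_f, step_phase))

        t = session_t0 + np.asarray(t_list, dtype=float)
        lon_arr = np.asarray(lon_list, dtype=float)
        lat_arr = np.asarray(lat_list, dtype=float)
        speed_true = np.asarray(speed_list, dtype=float)
        modes = np.asarray(mode_list)
        zones_arr = np.asarray(zone_list, dtype=int)
        n = len(t)

        # Gauss-Markov position error: stationary sd jitter_sd_m, correlation
        # time jitter_corr_s; isotropic in the local tangent plane
        if jitter_sd_m > 0:
            rho = math.exp(-1.0 / jitter_corr_s)
            innov = rng.normal(0.0, jitter_sd_m * math.sqrt(1 - rho * rho), size=(n, 2))
            err = np.empty((n, 2))
            err[0] = rng.normal(0.0, jitter_sd_m, size=2)
            for k in range(1, n):
                err[k] = rho * err[k - 1] + innov[k]
        else:
            # keep the rng draw sequence independent of the jitter setting
            err = np.zeros((n, 2))
        cos_lat = math.cos(math.radians((y0 + y1) / 2))
        lon_emit = lon_arr + err[:, 0] / (M_PER_DEG * cos_lat)
        lat_emit = lat_arr + err[:, 1] / M_PER_DEG

        # rare spikes: single-sample multipath jumps (> 5 m/s apparent speed)
        if spike_rate > 0 and n > 2:
            spike_mask = rng.random(n) < spike_rate
            spike_mask[[0, -1]] = False
            for k in np.flatnonzero(spike_mask):
                r = float(rng.uniform(12.0, 40.0))
                ang = float(rng.uniform(0.0, 2.0 * math.pi))
                dlo, dla = meters_to_degrees(r * math.cos(ang), r * math.sin(ang),
                                             lat_arr[k])
                lon_emit[k] += dlo
                lat_emit[k] += dla

        # single-second dropouts away from mode boundaries
        keep = np.ones(n, dtype=bool)
        if dropout_rate > 0 and n > 4:
            cand = rng.random(n) < dropout_rate
            for k in np.flatnonzero(cand):
                if (1 < k < n - 2 and keep[k - 1] and keep[k - 2]
                        and modes[k - 1] == modes[k] == modes[k + 1]):
                    keep[k] = False

        gps_frames.append(pd.DataFrame({
            "t": t[keep], "lat": lat_emit[keep], "lon": lon_emit[keep]}))
        label_frames.append(pd.DataFrame({
            "t": t[keep], "mode": modes[keep], "zone_id": zones_arr[keep],
            "speed_true": speed_true[keep]}))

        for (a, b, f, ph) in day_bouts:
            sel = (np.arange(n) >= a) & (np.arange(n) <= b) & keep
            idx = np.flatnonzero(sel)
            dur = t_list[b] - t_list[a]
            true_dist = float(np.sum(speed_true[a + 1:b + 1]))
            bout_rows.append({
                "bout_id": bout_counter, "start_t": session_t0 + t_list[a],
                "end_t": session_t0 + t_list[b], "n_samples": int(idx.size),
                "true_mean_speed": true_dist / dur if dur > 0 else 0.0,
            })
            bout_counter += 1

        # accelerometer channel at accel_hz over the session
        ta = session_t0 + np.arange(0.0, t_list[-1] + 1.0, 1.0 / accel_hz)
        az = 9.81 + rng.normal(0.0, 0.08, size=len(ta))
        for (a, b, f, ph) in day_bouts:
            w = (ta >= session_t0 + t_list[a]) & (ta <= session_t0 + t_list[b] + 1)
            tw = ta[w] - (session_t0 + t_list[a])
            az[w] = (9.81 + 1.2 * np.sin(2 * np.pi * f * tw + ph)
                     + rng.normal(0.0, 0.05, size=int(w.sum())))
        acc_frames.append(pd.DataFrame({
            "t": ta,
            "ax": rng.normal(0.0, 0.05, size=len(ta)),
            "ay": rng.normal(0.0, 0.05, size=len(ta)),
            "az": az,
        }))

    stream = RawStream(gps=pd.concat(gps_frames, ignore_index=True),
                       accel=pd.concat(acc_frames, ignore_index=True))
    truth = GroundTruth(labels=pd.concat(label_frames, ignore_index=True),
                        bouts=pd.DataFrame(bout_rows))
    return stream, truth


def sample_bout_table(cohort: list[ParticipantProfile], zone_map: ZoneMap,
                      gait: GaitModel, seed: int,
                      bouts_per_participant: tuple[int, int] = (14, 29),
                      duration_s: tuple[int, int] = (120, 601)) -> pd.DataFrame:
    """Draw per-bout mean speeds directly from the gait model.

    A lightweight alternative to full per-second simulation for statistical
    experiments: each participant visits a random sequence of zones, and each
    bout's mean speed is the clipped model prediction for its zone plus the
    per-bout noise draw. Returns one row per bout with columns participant_id,
    group, zone_id, gpr, land_use, duration_s, speed_mps plus the
    participant's age/sex/education (for covariate-adjusted fits).
    """
    rng = np.random.default_rng(seed)
    rows = []
    nz = len(zone_map.zones)
    for p in cohort:
        k = int(rng.integers(*bouts_per_participant))
        zone_ids = rng.integers(0, nz, size=k)
        durations = rng.integers(*duration_s, size=k)
        noise = rng.normal(0.0, gait.noise_sd, size=k)
        for zid, dur, eps in zip(zone_ids, durations, noise):
            z = zone_map.zones[int(zid)]
            rows.append({
                "participant_id": p.id, "group": p.group,
                "zone_id": int(zid), "gpr": z.gpr, "land_use": z.land_use,
                "duration_s": float(dur),
                "speed_mps": gait.clipped_speed(p.group, z.gpr, z.land_use,
                                                float(eps)),
                "age": p.age, "sex": p.sex, "education": p.education,
            })
    return pd.DataFrame(rows)


def cohort_to_frame(cohort: list[ParticipantProfile]) -> pd.DataFrame:
    """Roster view: id, age, sex, education, mmse, home_lon, home_lat, subzone."""
    return pd.DataFrame([{
        "id": p.id, "age": p.age, "sex": p.sex, "education": p.education,
        "mmse": p.mmse, "home_lon": p.home[0], "home_lat": p.home[1],
        "subzone": p.subzone,
    } for p in cohort])
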