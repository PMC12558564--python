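"""From raw GPS+accelerometer streams to validated walking tracks and DGS.

The pipeline stages, in order:

1. :func:`align_streams` — restrict both channels to their common calendar dates.
2. :func:`smooth_latlon` — 3-point centered moving average on lat/lon to damp
   multipath jitter.
3. :func:`derive_speed_series` — per-sample ground speed from consecutive
   haversine distances.
4. :func:`remove_speed_spikes` — drop samples faster than 5 m/s and re-link
   neighbors.
5. :func:`segment_walk_tracks` — greedy left-to-right extraction of walking
   bouts: >=20 consecutive in-band (0.30-<1.39 m/s) samples, <=2 s bridged
   gaps, net displacement >=20 m, step-periodic accelerometer signal.
6. :func:`compute_track_dgs` / :func:`participant_dgs` — daily-life gait
   speed as total GPS distance over track duration, pooled across tracks.

Speeds below 1.39 m/s (5 km/h) are walking mode; at or above is vehicular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .geo import haversine_m, step_distances_m

# Pipeline constants (all config-exposed through keyword arguments / PipelineConfig)
MODE_THRESHOLD_MPS = 1.39   # 5 km/h: walking below, vehicular at or above
TRACK_BAND_LOW_MPS = 0.30   # slower samples are dwelling, not track walking
SPIKE_SPEED_MPS = 5.0       # implausible ground speed, removed before anything else
MIN_TRACK_SAMPLES = 20      # consecutive 1 s walking samples to qualify
MIN_NET_DISPLACEMENT_M = 20.0   # rejects in-place dithering
MAX_GAP_S = 2.0             # longest bridgeable timestamp gap (satellite occlusion)
MAX_TRACK_DISTANCE_M = 10_000.0  # longer tracks are implausible for walking
SMOOTH_WINDOW = 3
STEP_BAND_HZ = (1.0, 2.6)   # plausible step frequencies
STEP_PROMINENCE_FRAC = 0.3


@dataclass
class RawStream:
    """Time-aligned per-second GPS samples plus an optional accelerometer channel.

    ``gps`` columns: t (seconds since epoch, strictly increasing), lat, lon.
    ``accel`` columns: t, ax, ay, az (any rate; typically 10 Hz).
    """

    gps: pd.DataFrame
    accel: pd.DataFrame | None = None

    def accel_in(self, t0: float, t1: float) -> pd.DataFrame | None:
        """Accelerometer samples with t in [t0, t1), or None if no channel."""
        if self.accel is None or len(self.accel) == 0:
            return None
        t = self.accel["t"].to_numpy()
        i0, i1 = np.searchsorted(t, [t0, t1])
        return self.accel.iloc[i0:i1]


@dataclass
class WalkTrack:
    """A validated contiguous walking bout within a speed series."""

    start_idx: int
    end_idx: int          # inclusive
    t_start: float
    t_end: float
    n_samples: int        # in-band samples (bridged gaps contribute none)
    distance_m: float     # sum of consecutive haversine steps, gaps included
    net_displacement_m: float
    duration_s: float     # t_end - t_start
    dgs: float            # distance_m / duration_s
    periodicity_ok: bool = True
    excluded: bool = False  # distance_m > 10 km


def _epoch_dates(t: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(t, dtype=float) / 86400.0).astype(np.int64)


def align_streams(gps: pd.DataFrame, accel: pd.DataFrame | None) -> RawStream:
    """Restrict GPS and accelerometer channels to their common calendar dates.

    Each GPS second then carries the accelerometer samples falling in
    [t, t+1) via :meth:`RawStream.accel_in`. Disjoint date ranges yield an
    empty stream with a warning rather than an error.
    """
    gps = gps.sort_values("t").reset_index(drop=True)
    if accel is None or len(accel) == 0:
        return RawStream(gps=gps, accel=None)
    accel = accel.sort_values("t").reset_index(drop=True)
    gps_dates = _epoch_dates(gps["t"].to_numpy())
    acc_dates = _epoch_dates(accel["t"].to_numpy())
    common = np.intersect1d(np.unique(gps_dates), np.unique(acc_dates))
    if common.size == 0:
        warnings.warn("GPS and accelerometer date ranges are disjoint; empty stream")
        return RawStream(gps=gps.iloc[0:0], accel=accel.iloc[0:0])
    return RawStream(
        gps=gps[np.isin(gps_dates, common)].reset_index(drop=True),
        accel=accel[np.isin(acc_dates, common)].reset_index(drop=True),
    )


def smooth_latlon(stream: RawStream, window: int = SMOOTH_WINDOW) -> RawStream:
    """Centered moving average on latitude and longitude.

    Windows shrink symmetrically near the stream edges (down to width 1 at the
    endpoints), so timestamps and stream length are unchanged. ``window`` must
    be odd; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 1")
    gps = stream.gps
    n = len(gps)
    if window == 1 or n < 3:
        return stream
    half = (window - 1) // 2
    out = gps.copy()
    for col in ("lat", "lon"):
        x = gps[col].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(x)])
        idx = np.arange(n)
        h = np.minimum(half, np.minimum(idx, n - 1 - idx))
        out[col] = (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)
    return RawStream(gps=out, accel=stream.accel)


def classify_mode(speed: float) -> str:
    """Walking iff speed < 1.39 m/s (5 km/h); vehicular at or above."""
    if speed < 0:
        raise ValueError(f"negative speed {speed!r}")
    return "walking" if speed < MODE_THRESHOLD_MPS else "vehicular"


def _speeds_from_positions(t: np.ndarray, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    dt = np.diff(t)
    speeds = np.zeros(len(t))
    if len(t) > 1:
        speeds[1:] = step_distances_m(lon, lat) / dt
    return speeds


def derive_speed_series(stream: RawStream,
                        mode_threshold: float = MODE_THRESHOLD_MPS) -> pd.DataFrame:
    """Per-sample ground speed from consecutive haversine distances.

    Speed at sample i is the haversine step from sample i-1 divided by the
    elapsed time; the first sample's speed is 0 (no predecessor). Returns a
    frame with columns t, lat, lon, speed, mode.
    """
    gps = stream.gps
    if len(gps) < 2:
        raise ValueError("need at least 2 GPS samples to derive speeds")
    t = gps["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    lat = gps["lat"].to_numpy(dtype=float)
    lon = gps["lon"].to_numpy(dtype=float)
    speed = _speeds_from_positions(t, lon, lat)
    return pd.DataFrame({
        "t": t, "lat": lat, "lon": lon, "speed": speed,
        "mode": np.where(speed < mode_threshold, "walking", "vehicular"),
    })


def remove_speed_spikes(series: pd.DataFrame,
                        max_speed: float = SPIKE_SPEED_MPS,
                        mode_threshold: float = MODE_THRESHOLD_MPS) -> pd.DataFrame:
    """Drop samples faster than ``max_speed`` and re-link their neighbors.

    A single left-to-right pass: each sample's effective speed is its stored
    value while the stream is intact, or — after a removal — the haversine
    step from the last *kept* sample over the elapsed time. Samples whose
    effective speed exceeds the cap are dropped, so a one-sample position
    spike removes exactly one sample (its return step re-links at walking
    speed across a bridgeable gap) and no surviving speed exceeds the cap.
    """
    t = series["t"].to_numpy(dtype=float)
    lat = series["lat"].to_numpy(dtype=float)
    lon = series["lon"].to_numpy(dtype=float)
    speed = series["speed"].to_numpy(dtype=float)
    keep: list[int] = []
    eff: list[float] = []
    last = -1  # index of last kept sample; -1 while none kept
    for k in range(len(t)):
        if last < 0:
            s = speed[k]
        elif last == k - 1:
            s = speed[k]
        else:
            s = haversine_m(lon[last], lat[last], lon[k], lat[k]) / (t[k] - t[last])
        if s > max_speed:
            continue
        keep.append(k)
        eff.append(float(s))
        last = k
    out = series.iloc[keep].reset_index(drop=True)
    if len(out):
        eff_arr = np.asarray(eff)
        out = out.assign(speed=eff_arr,
                         mode=np.where(eff_arr < mode_threshold,
                                       "walking", "vehicular"))
    return out


def check_step_periodicity(accel_t: np.ndarray, accel_mag: np.ndarray,
                           band_hz: tuple[float, float] = STEP_BAND_HZ,
                           prominence_frac: float = STEP_PROMINENCE_FRAC) -> bool:
    """True iff the accelerometer magnitude shows step-like periodicity.

    The dominant periodicity is read off the detrended magnitude's
    autocorrelation as the earliest positive-lag peak whose height reaches
    ``prominence_frac`` of the zero-lag value — i.e. the fundamental period,
    which for a periodic signal always precedes its harmonic multiples. The
    check passes iff that fundamental lies inside the step band (1.0-2.6 Hz
    by default). Gait oscillations at typical cadence pass; white noise (no
    prominent peak) and out-of-band vibration (fundamental outside the band)
    fail.
    """
    x = np.asarray(accel_mag, dtype=float)
    t = np.asarray(accel_t, dtype=float)
    if len(x) < 8:
        return False
    fs = 1.0 / float(np.median(np.diff(t)))
    x = sp_signal.detrend(x)
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    if acf[0] <= 0:
        return False
    peaks, _ = sp_signal.find_peaks(acf[1:])
    if peaks.size == 0:
        return False
    peaks = peaks + 1  # lags
    prominent = peaks[acf[peaks] >= prominence_frac * acf[0]]
    if prominent.size == 0:
        return False
    freq = fs / prominent[0]
    return bool(band_hz[0] <= freq <= band_hz[1])


def accel_magnitude(accel: pd.DataFrame) -> np.ndarray:
    """Scalar magnitude from a 3-axis (or already-scalar) accelerometer frame."""
    if "mag" in accel.columns:
        return accel["mag"].to_numpy(dtype=float)
    return np.sqrt(accel["ax"].to_numpy() ** 2 + accel["ay"].to_numpy() ** 2
                   + accel["az"].to_numpy() ** 2)


def compute_track_dgs(distance_m: float, duration_s: float,
                      max_distance_m: float = MAX_TRACK_DISTANCE_M) -> tuple[float, bool]:
    """DGS = total GPS distance / track duration; >10 km tracks flagged excluded."""
    if duration_s <= 0:
        raise ValueError("track duration must be positive")
    return distance_m / duration_s, bool(distance_m > max_distance_m)


def segment_walk_tracks(series: pd.DataFrame,
                        accel: pd.DataFrame | None = None,
                        *,
                        band_low: float = TRACK_BAND_LOW_MPS,
                        mode_threshold: float = MODE_THRESHOLD_MPS,
                        min_samples: int = MIN_TRACK_SAMPLES,
                        min_displacement_m: float = MIN_NET_DISPLACEMENT_M,
                        max_gap_s: float = MAX_GAP_S,
                        max_distance_m: float = MAX_TRACK_DISTANCE_M,
                        band_hz: tuple[float, float] = STEP_BAND_HZ,
                        prominence_frac: float = STEP_PROMINENCE_FRAC,
                        missing_accel_ok: bool = True) -> list[WalkTrack]:
    """Greedy left-to-right extraction of validated walking tracks.

    A candidate opens at the first sample with speed in [band_low,
    mode_threshold) and extends while samples stay in band and consecutive
    timestamps differ by at most ``max_gap_s``. A closed candidate survives iff
    it has >= ``min_samples`` in-band samples, net (first-to-last great-circle)
    displacement >= ``min_displacement_m``, no internal sample at or above the
    vehicular threshold, and — when an accelerometer segment is available —
    step-like periodicity. Bridged gaps contribute distance and duration but
    no sample count. Tracks longer than ``max_distance_m`` are kept but
    flagged excluded.

    With no accelerometer data the periodicity check passes by default
    (``missing_accel_ok``); set it False to discard such candidates instead.
    """
    if len(series) == 0:
        return []
    t = series["t"].to_numpy(dtype=float)
    lat = series["lat"].to_numpy(dtype=float)
    lon = series["lon"].to_numpy(dtype=float)
    speed = series["speed"].to_numpy(dtype=float)
    in_band = (speed >= band_low) & (speed < mode_threshold)
    n = len(t)
    acc_t = acc_mag = None
    if accel is not None and len(accel) > 0:
        acc_t = accel["t"].to_numpy(dtype=float)
        acc_mag = accel_magnitude(accel)

    tracks: list[WalkTrack] = []
    i = 0
    while i < n:
        if not in_band[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_band[j + 1] and (t[j + 1] - t[j]) <= max_gap_s:
            j += 1
        count = j - i + 1
        if count >= min_samples:
            net = haversine_m(lon[i], lat[i], lon[j], lat[j])
            # internal spike guard: cannot fire for in-band runs, but kept so the
            # rule holds for any caller-constructed band configuration
            no_spike = not np.any(speed[i:j + 1] >= mode_threshold)
            if net >= min_displacement_m and no_spike:
                ok = True
                if acc_t is not None:
                    k0, k1 = np.searchsorted(acc_t, [t[i], t[j] + 1.0])
                    if k1 - k0 >= 8:
                        ok = check_step_periodicity(acc_t[k0:k1], acc_mag[k0:k1],
                                                    band_hz=band_hz,
                                                    prominence_frac=prominence_frac)
                    else:
                        ok = missing_accel_ok
                elif not missing_accel_ok:
                    ok = False
                if ok:
                    dist = float(np.sum(step_distances_m(lon[i:j + 1], lat[i:j + 1])))
                    dgs, excluded = compute_track_dgs(dist, t[j] - t[i], max_distance_m)
                    tracks.append(WalkTrack(
                        start_idx=i, end_idx=j, t_start=t[i], t_end=t[j],
                        n_samples=count, distance_m=dist,
                        net_displacement_m=float(net),
                        duration_s=float(t[j] - t[i]), dgs=dgs,
                        periodicity_ok=True, excluded=excluded,
                    ))
        i = j + 1
    return tracks


def participant_dgs(tracks: list[WalkTrack], pooled: bool = True) -> float:
    """Per-participant daily-life gait speed over non-excluded tracks.

    Pooled (default): total distance over total duration, i.e. a duration-
    weighted mean of track speeds. ``pooled=False`` gives the unweighted mean
    of per-track DGS instead; the two differ on heterogeneous tracks. Returns
    NaN (with a warning) when no valid track exists.
    """
    valid = [tr for tr in tracks if not tr.excluded]
    if not valid:
        warnings.warn("no valid walking tracks; participant DGS is missing")
        return float("nan")
    if pooled:
        return sum(tr.distance_m for tr in valid) / sum(tr.duration_s for tr in valid)
    return float(np.mean([tr.dgs for tr in valid]))


def track_step_table(series: pd.DataFrame, tracks: list[WalkTrack],
                     participant_id: str = "") -> pd.DataFrame:
    """Per-step (1 s, or bridged-gap) records of all non-excluded tracks.

    Each row is one step ending at a track sample: its end position, step
    speed and elapsed time ``dt``. Summing speed*dt per track reproduces the
    track distance exactly, and summing dt reproduces its duration — the
    identity the exposure aggregation relies on.
    """
    t = series["t"].to_numpy(dtype=float)
    rows = []
    for k, tr in enumerate(tracks):
        if tr.excluded:
            continue
        sl = slice(tr.start_idx + 1, tr.end_idx + 1)
        dt = np.diff(t[tr.start_idx:tr.end_idx + 1])
        rows.append(pd.DataFrame({
            "participant_id": participant_id,
            "track_id": k,
            "t": t[sl],
            "lat": series["lat"].to_numpy()[sl],
            "lon": series["lon"].to_numpy()[sl],
            "speed": series["speed"].to_numpy()[sl],
            "dt": dt,
        }))
    if not rows:
        return pd.DataFrame(columns=["participant_id", "track_id", "t", "lat",
                                     "lon", "speed", "dt"])
    return pd.concat(rows, ignore_index=True)


_TRACK_COLUMNS = ["participant_id", "track_id", "start_ts", "end_ts",
                  "n_samples", "distance_m", "net_displacement_m",
                  "duration_s", "dgs_mps", "excluded_flag", "periodicity_flag"]


def tracks_to_frame(tracks: list[WalkTrack], participant_id: str = "") -> pd.DataFrame:
    """Tabular view of a track list (one row per track)."""
    if not tracks:
        return pd.DataFrame(columns=_TRACK_COLUMNS)
    return pd.DataFrame([{
        "participant_id": participant_id,
        "track_id": k,
        "start_ts": tr.t_start,
        "end_ts": tr.t_end,
        "n_samples": tr.n_samples,
        "distance_m": tr.distance_m,
        "net_displacement_m": tr.net_displacement_m,
        "duration_s": tr.duration_s,
        "dgs_mps": tr.dgs,
        "excluded_flag": tr.excluded,
        "periodicity_flag": tr.periodicity_ok,
    } for k, tr in enumerate(tracks)])


def process_stream(stream: RawStream, *, smooth_window: int = SMOOTH_WINDOW,
                   max_speed: float = SPIKE_SPEED_MPS,
                   **segment_kwargs) -> tuple[pd.DataFrame, list[WalkTrack]]:
    """Run smoothing, speed derivation, spike removal and segmentation.

    Returns the cleaned speed series and the validated track list.
    """
    sm = smooth_latlon(stream, window=smooth_window)
    series = derive_speed_series(sm)
    series = remove_speed_spikes(series, max_speed=max_speed)
    tracks = segment_walk_tracks(series, accel=sm.accel, **segment_kwargs)
    return series, tracks
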