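import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import urbangait.track_pipeline as tp
from urbangait.geo import M_PER_DEG
from conftest import make_straight_series
from oracles import brute_force_windows, random_speed_stream


# ---------------------------------------------------------------- alignment

def _gps_frame(t0, n, dt=1.0):
    t = t0 + dt * np.arange(n)
    return pd.DataFrame({"t": t, "lat": np.full(n, 1.35), "lon": np.full(n, 103.8)})


def _accel_frame(t0, n, hz=10.0):
    t = t0 + np.arange(n) / hz
    z = np.full(n, 9.81)
    return pd.DataFrame({"t": t, "ax": 0.0, "ay": 0.0, "az": z})


class TestAlignStreams:
    def test_identical_time_base_keeps_all_gps(self):
        stream = tp.align_streams(_gps_frame(0.0, 120), _accel_frame(0.0, 1200))
        assert len(stream.gps) == 120

    def test_disjoint_dates_flagged_empty(self):
        with pytest.warns(UserWarning, match="disjoint"):
            stream = tp.align_streams(_gps_frame(0.0, 60), _accel_frame(86400.0, 600))
        assert len(stream.gps) == 0

    def test_each_gps_second_carries_at_most_rate_accel_samples(self):
        stream = tp.align_streams(_gps_frame(0.0, 60), _accel_frame(0.0, 600))
        counts = [len(stream.accel_in(t, t + 1.0)) for t in stream.gps["t"]]
        assert max(counts) <= 10 and sum(counts) == 600


# ---------------------------------------------------------------- smoothing

class TestSmoothing:
    def test_constant_position_unchanged(self):
        stream = tp.RawStream(gps=_gps_frame(0.0, 50))
        out = tp.smooth_latlon(stream, window=3)
        pd.testing.assert_frame_equal(out.gps, stream.gps)

    def test_three_point_mean_of_triangle(self):
        gps = pd.DataFrame({"t": [0.0, 1.0, 2.0], "lat": [0.0, 3.0, 0.0],
                            "lon": [10.0, 10.0, 10.0]})
        out = tp.smooth_latlon(tp.RawStream(gps=gps), window=3)
        assert out.gps["lat"].tolist() == [0.0, 1.0, 0.0]  # edges use width 1

    def test_linear_ramp_interior_invariant(self):
        n = 30
        gps = pd.DataFrame({"t": np.arange(n, dtype=float),
                            "lat": np.full(n, 1.0),
                            "lon": np.linspace(103.0, 103.1, n)})
        out = tp.smooth_latlon(tp.RawStream(gps=gps), window=3)
        np.testing.assert_allclose(out.gps["lon"], gps["lon"], atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            tp.smooth_latlon(tp.RawStream(gps=_gps_frame(0.0, 10)), window=4)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(3, 40), st.integers(0, 2 ** 31 - 1))
    def test_smoothing_stays_within_input_envelope(self, n, seed):
        rng = np.random.default_rng(seed)
        gps = pd.DataFrame({"t": np.arange(n, dtype=float),
                            "lat": rng.uniform(1.3, 1.4, n),
                            "lon": rng.uniform(103.8, 103.9, n)})
        out = tp.smooth_latlon(tp.RawStream(gps=gps), window=3).gps
        for col in ("lat", "lon"):
            assert out[col].min() >= gps[col].min() - 1e-12
            assert out[col].max() <= gps[col].max() + 1e-12


# ------------------------------------------------------------- speed series

class TestSpeedSeries:
    def test_stationary_stream_all_zero_speed(self):
        series = tp.derive_speed_series(tp.RawStream(gps=_gps_frame(0.0, 30)))
        assert (series["speed"] == 0).all()
        assert (series["speed"] < tp.TRACK_BAND_LOW_MPS).all()

    def test_one_meter_per_second(self, straight_series):
        ref = make_straight_series(10, 1.0)
        series = tp.derive_speed_series(
            tp.RawStream(gps=ref[["t", "lat", "lon"]]))
        np.testing.assert_allclose(series["speed"][1:], 1.0, rtol=1e-6)
        assert series["speed"][0] == 0.0

    def test_dropout_gap_uses_elapsed_time(self):
        # 2.0 m apart at 2 s spacing -> 1.0 m/s
        ref = make_straight_series(5, 1.0, dt=2.0)
        ref["lon"] = 103.835 + 2.0 * np.arange(5) / (M_PER_DEG * np.cos(np.radians(1.35)))
        series = tp.derive_speed_series(tp.RawStream(gps=ref[["t", "lat", "lon"]]))
        np.testing.assert_allclose(series["speed"][1:], 1.0, rtol=1e-6)

    def test_non_increasing_timestamps_rejected(self):
        gps = _gps_frame(0.0, 5)
        gps.loc[3, "t"] = gps.loc[2, "t"]
        with pytest.raises(ValueError, match="increasing"):
            tp.derive_speed_series(tp.RawStream(gps=gps))


class TestModeClassification:
    @pytest.mark.parametrize("speed,mode", [
        (1.38, "walking"), (1.39, "vehicular"), (0.0, "walking"),
        (0.29, "walking"), (5.1, "vehicular"),
    ])
    def test_threshold(self, speed, mode):
        assert tp.classify_mode(speed) == mode

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            tp.classify_mode(-0.1)


class TestSpikeRemoval:
    def test_clean_series_unchanged(self):
        series = make_straight_series(30, 1.0)
        out = tp.remove_speed_spikes(series)
        pd.testing.assert_frame_equal(out, series.reset_index(drop=True))

    def test_single_spike_removed_and_relinked(self):
        series = make_straight_series(30, 1.0)
        # displace one sample to make an 8 m/s spike
        series.loc[10, "lat"] += 8.0 / M_PER_DEG
        series = tp.derive_speed_series(tp.RawStream(gps=series[["t", "lat", "lon"]]))
        assert series["speed"].max() > 5.0
        out = tp.remove_speed_spikes(series)
        assert len(out) == 29
        assert out["speed"].max() <= 5.0
        # re-linked speed across the removed gap stays near walking speed
        assert out["speed"][1:].between(0.5, 1.5).all()

    def test_all_spikes_empties_series(self):
        series = make_straight_series(10, 6.0)
        series["speed"] = 6.0
        assert len(tp.remove_speed_spikes(series)) == 0


# -------------------------------------------------------------- segmentation

class TestSegmentation:
    def test_nineteen_samples_insufficient(self):
        tracks = tp.segment_walk_tracks(make_straight_series(19, 1.0))
        assert tracks == []

    def test_straight_minute_walk_single_track(self):
        series = make_straight_series(61, 1.0)
        tracks = tp.segment_walk_tracks(series)
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.n_samples == 61
        assert tr.net_displacement_m == pytest.approx(60.0, rel=1e-4)
        assert tr.dgs == pytest.approx(1.0, rel=1e-6)
        assert not tr.excluded

    def test_dithering_rejected_by_displacement(self):
        # pace back and forth inside a ~5 m segment
        n = 30
        t = np.arange(n, dtype=float)
        offsets = np.tile([0, 1, 2, 3, 4, 5, 4, 3, 2, 1], 3)[:n]
        lon = 103.835 + offsets * 0.5 / (M_PER_DEG * np.cos(np.radians(1.35)))
        series = pd.DataFrame({"t": t, "lat": 1.35, "lon": lon,
                               "speed": 0.5, "mode": "walking"})
        assert tp.segment_walk_tracks(series) == []

    def test_bridged_gap_contributes_time_not_count(self):
        series = make_straight_series(40, 1.0)
        series = series.drop(index=20).reset_index(drop=True)  # 2 s gap
        tracks = tp.segment_walk_tracks(series)
        assert len(tracks) == 1
        assert tracks[0].n_samples == 39
        assert tracks[0].duration_s == pytest.approx(39.0)
        assert tracks[0].distance_m == pytest.approx(39.0, rel=1e-4)

    def test_long_gap_splits_candidates(self):
        a = make_straight_series(25, 1.0)
        b = make_straight_series(25, 1.0, t0=28.0, lon0=103.836)
        series = pd.concat([a, b], ignore_index=True)
        tracks = tp.segment_walk_tracks(series)
        assert len(tracks) == 2

    def test_vehicular_sample_invalidates_candidate(self):
        series = make_straight_series(30, 1.0)
        series.loc[15, "speed"] = 1.39  # exactly at the threshold
        assert tp.segment_walk_tracks(series) == []

    def test_sub_band_sample_terminates_candidate(self):
        series = make_straight_series(50, 1.0)
        series.loc[25, "speed"] = 0.1  # dwell second: walking mode but out of band
        tracks = tp.segment_walk_tracks(series)
        assert len(tracks) == 2
        assert tracks[0].end_idx == 24 and tracks[1].start_idx == 26

    def test_threshold_sharpness_any_sample(self):
        base = make_straight_series(40, 1.0)
        whole = tp.segment_walk_tracks(base)
        assert len(whole) == 1
        for k in range(5, 35, 7):
            series = base.copy()
            series.loc[k, "speed"] = 1.39
            tracks = tp.segment_walk_tracks(series)
            # the perturbed sample belongs to no track and the original
            # full-extent track is gone
            assert all(not (tr.start_idx <= k <= tr.end_idx) for tr in tracks)
            assert all((tr.start_idx, tr.end_idx) != (0, 39) for tr in tracks)

    def test_appending_samples_is_monotone(self):
        prev = None
        for n in range(25, 90, 10):
            tracks = tp.segment_walk_tracks(make_straight_series(n, 1.0))
            assert len(tracks) == 1
            tr = tracks[0]
            if prev is not None:
                assert tr.n_samples >= prev.n_samples
                assert tr.net_displacement_m >= prev.net_displacement_m
            prev = tr

    def test_empty_input_gives_empty_list(self):
        empty = make_straight_series(0, 1.0)
        assert tp.segment_walk_tracks(empty) == []

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t, lon, lat, speed = random_speed_stream(rng)
        series = pd.DataFrame({"t": t, "lat": lat, "lon": lon, "speed": speed})
        got = [(tr.start_idx, tr.end_idx) for tr in tp.segment_walk_tracks(series)]
        expect = brute_force_windows(t, lon, lat, speed)
        assert got == expect


# -------------------------------------------------------------- periodicity

class TestStepPeriodicity:
    def _times(self, dur=40.0, hz=10.0):
        return np.arange(0.0, dur, 1.0 / hz)

    def test_in_band_sinusoid_passes(self):
        t = self._times()
        rng = np.random.default_rng(0)
        mag = 9.81 + 1.2 * np.sin(2 * np.pi * 1.8 * t) + rng.normal(0, 0.05, len(t))
        assert tp.check_step_periodicity(t, mag)

    def test_white_noise_fails(self):
        t = self._times()
        mag = 9.81 + np.random.default_rng(1).normal(0, 0.5, len(t))
        assert not tp.check_step_periodicity(t, mag)

    def test_out_of_band_oscillation_fails(self):
        t = self._times()
        rng = np.random.default_rng(2)
        mag = 9.81 + 1.2 * np.sin(2 * np.pi * 5.0 * t) + rng.normal(0, 0.05, len(t))
        assert not tp.check_step_periodicity(t, mag)

    def test_missing_accel_passes_through_by_default(self):
        series = make_straight_series(30, 1.0)
        assert len(tp.segment_walk_tracks(series, accel=None)) == 1
        assert tp.segment_walk_tracks(series, accel=None, missing_accel_ok=False) == []

    def test_aperiodic_accel_discards_candidate(self):
        series = make_straight_series(40, 1.0)
        t = np.arange(0.0, 40.0, 0.1)
        noise = pd.DataFrame({"t": t, "ax": 0.0, "ay": 0.0,
                              "az": 9.81 + np.random.default_rng(3).normal(0, 0.5, len(t))})
        assert tp.segment_walk_tracks(series, accel=noise) == []


# ----------------------------------------------------------------- DGS math

class TestDgs:
    def test_track_dgs_arithmetic(self):
        dgs, excluded = tp.compute_track_dgs(90.0, 120.0)
        assert dgs == pytest.approx(0.75)
        assert not excluded

    def test_over_ten_km_excluded(self):
        dgs, excluded = tp.compute_track_dgs(10_050.0, 9000.0)
        assert excluded

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            tp.compute_track_dgs(10.0, 0.0)

    def _track(self, dist, dur):
        return tp.WalkTrack(0, 0, 0.0, dur, int(dur) + 1, dist,
                            dist, dur, dist / dur)

    def test_participant_dgs_is_duration_weighted(self):
        tracks = [self._track(60.0, 100.0), self._track(140.0, 100.0)]
        # pooled 200 m / 200 s = 1.0, not the 1.0 = mean(0.6, 1.4) coincidence:
        assert tp.participant_dgs(tracks) == pytest.approx(1.0)
        tracks = [self._track(60.0, 100.0), self._track(300.0, 300.0)]
        assert tp.participant_dgs(tracks) == pytest.approx(360.0 / 400.0)
        assert tp.participant_dgs(tracks, pooled=False) == pytest.approx(0.8)

    def test_excluded_tracks_ignored_and_empty_flagged(self):
        good = self._track(80.0, 100.0)
        bad = self._track(10_500.0, 9000.0)
        bad.excluded = True
        assert tp.participant_dgs([good, bad]) == pytest.approx(0.8)
        with pytest.warns(UserWarning, match="no valid"):
            assert np.isnan(tp.participant_dgs([bad]))

    def test_step_table_reconstructs_track_totals(self):
        series = make_straight_series(61, 1.0)
        tracks = tp.segment_walk_tracks(series)
        steps = tp.track_step_table(series, tracks, "P1")
        assert len(steps) == 60
        tr = tracks[0]
        assert (steps["speed"] * steps["dt"]).sum() == pytest.approx(tr.distance_m)
        assert steps["dt"].sum() == pytest.approx(tr.duration_s)
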