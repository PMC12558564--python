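"""End-to-end run: simulate -> process -> exposure -> stats -> report.

Every stage draws its randomness from seeds spawned deterministically from
the single config seed, so the entire run is a pure function of the config;
the manifest records the config hash and a checksum per text artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ug_io
from .config import PipelineConfig
from .cohort_stats import make_report
from .exposure import (assign_zones, build_heatmap, exposure_table,
                       heatmap_to_geojson, participant_stratum_cells,
                       plot_heatmap)
from .synthetic_world import (GaitModel, cohort_to_frame, generate_cohort,
                              generate_zone_map, simulate_trajectory)
from .track_pipeline import (participant_dgs, process_stream, track_step_table,
                             tracks_to_frame)

log = logging.getLogger("urbangait")


def _spawned_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 gait: GaitModel | None = None) -> dict:
    """Run the full study pipeline into ``outdir``; returns the manifest.

    Stages fail loudly with their stage name; artifacts written before a
    failure are preserved for inspection.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gait = gait or GaitModel()
    manifest: dict = {"config": config.to_dict(), "config_hash": config.hash(),
                      "stages": {}, "files": {}}
    stage = "simulate"
    try:
        seeds = _spawned_seeds(config.seed, 3 + config.n_participants)
        zone_map = generate_zone_map(seeds[0], config.map_rows, config.map_cols)
        ug_io.write_zone_map(zone_map, outdir / "zone_map.geojson")
        cohort = generate_cohort(seeds[1], config.n_participants,
                                 config.ci_fraction, zone_map)
        roster = cohort_to_frame(cohort)
        roster["group"] = [p.group for p in cohort]

        if config.write_streams:
            (outdir / "streams").mkdir(exist_ok=True)
        all_tracks, all_steps, dgs_rows = [], [], []
        n_samples_total = 0
        stage = "process"
        for p, pseed in zip(cohort, seeds[3:]):
            stream, truth = simulate_trajectory(
                p, zone_map, gait, days=config.days, seed=pseed,
                jitter_sd_m=config.jitter_sd_m,
                jitter_corr_s=config.jitter_corr_s,
                dropout_rate=config.dropout_rate, spike_rate=config.spike_rate)
            n_samples_total += len(stream.gps)
            if config.write_streams:
                ug_io.write_gps_csv(stream.gps, outdir / "streams" / f"{p.id}_gps.csv")
                ug_io.write_accel_csv(stream.accel,
                                      outdir / "streams" / f"{p.id}_accel.csv")
                ug_io.write_truth_csv(truth.labels,
                                      outdir / "streams" / f"{p.id}_truth.csv")
            series, tracks = process_stream(
                stream, smooth_window=config.smooth_window,
                max_speed=config.max_speed,
                band_low=config.band_low, mode_threshold=config.mode_threshold,
                min_samples=config.min_samples,
                min_displacement_m=config.min_displacement,
                max_gap_s=config.max_gap,
                max_distance_m=config.max_distance_km * 1000.0)
            all_tracks.append(tracks_to_frame(tracks, participant_id=p.id))
            all_steps.append(track_step_table(series, tracks, participant_id=p.id))
            dgs_rows.append({"id": p.id, "dgs": participant_dgs(tracks)
                             if tracks else float("nan"),
                             "n_tracks": len(tracks)})
            log.info("%s: %d samples, %d tracks", p.id, len(stream.gps), len(tracks))
        tracks_frame = pd.concat(all_tracks, ignore_index=True)
        steps = pd.concat(all_steps, ignore_index=True)
        ug_io.write_tracks_csv(tracks_frame, outdir / "tracks.csv")
        cohort_frame = roster.merge(pd.DataFrame(dgs_rows), on="id")
        ug_io.write_roster_csv(cohort_frame, outdir / "roster.csv")
        manifest["stages"]["process"] = {
            "n_samples": int(n_samples_total), "n_tracks": int(len(tracks_frame)),
            "n_participants": len(cohort)}

        stage = "exposure"
        if len(steps):
            steps = assign_zones(steps, zone_map)
        for by in ("gpr", "land_use"):
            tab = exposure_table(steps, zone_map, by=by,
                                 observed_days=config.days)
            if len(tab) == 0:
                pd.DataFrame(columns=["stratum"]).to_csv(
                    outdir / f"exposure_by_{by}.csv", index=False)
                continue
            tab = tab.merge(cohort_frame[["id", "group"]],
                            left_on="participant_id", right_on="id").drop(columns="id")
            grp = (tab.groupby(["stratum", "group"])
                   .apply(lambda g: pd.Series({
                       "mean_dgs": float(np.average(g["mean_dgs"],
                                                    weights=g["seconds_walking"])),
                       "min_per_wk": float(g["min_per_wk"].mean())}),
                       include_groups=False)
                   .unstack("group"))
            grp.columns = [f"{a}_{b}" for a, b in grp.columns]
            grp.reset_index().to_csv(outdir / f"exposure_by_{by}.csv", index=False)
        # case-example heatmap: one participant per group
        for grp_name in ("CI", "nonCI"):
            ids = cohort_frame.loc[cohort_frame["group"] == grp_name, "id"]
            if len(ids) == 0 or len(steps) == 0:
                continue
            sub = steps[steps["participant_id"] == ids.iloc[0]]
            grid = build_heatmap(sub, cell_m=config.cell_m, extent=zone_map.extent)
            (outdir / f"heatmap_{grp_name}.geojson").write_text(
                json.dumps(heatmap_to_geojson(grid)))
            plot_heatmap(grid, str(outdir / f"heatmap_{grp_name}.png"))

        stage = "stats"
        cells = participant_stratum_cells(steps, zone_map, cohort_frame)
        report = make_report(
            cohort_frame.rename(columns={"id": "participant_id"}), cells,
            alpha=config.alpha, adjust=config.adjust)
        for name, frame in report.items():
            frame.to_csv(outdir / f"report_{name}.csv", index=False)
        def _clean(x):
            x = float(x)
            return None if np.isnan(x) else x

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            summary = {
                "config_hash": config.hash(),
                "n_participants": len(cohort),
                "n_tracks": int(len(tracks_frame)),
                "dgs_mean_overall": _clean(np.nanmean(cohort_frame["dgs"])),
            }
            for grp_name in ("nonCI", "CI"):
                sub = cohort_frame.loc[cohort_frame["group"] == grp_name, "dgs"]
                summary[f"dgs_mean_{grp_name}"] = (_clean(np.nanmean(sub))
                                                   if len(sub) else None)
        assoc = report["associations"]
        for _, row in assoc.iterrows():
            if not row.get("missing", True):
                summary[f"gpr_slope_{row['group']}"] = float(row["beta_raw"])
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    except Exception as err:  # annotate failures with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    for f in sorted(outdir.rglob("*")):
        if f.is_file():
            rel = str(f.relative_to(outdir))
            if f.suffix in {".csv", ".json", ".geojson", ".yaml"}:
                manifest["files"][rel] = _checksum(f)
            else:
                manifest["files"][rel] = "(binary, unchecksummed)"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
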