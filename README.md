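# urbangait

Daily-life gait speed (DGS) from wearable hybrid GPS+accelerometer logs,
linked to urban environmental typologies — gross plot ratio (GPR) and land
use — for cohorts of older adults with and without cognitive impairment.

Free-living gait speed is an ecologically valid marker of functional and
cognitive health, but it is shaped by *where* people walk: built density and
land-use context impose different navigational and sensory demands,
especially on cognitively impaired (CI) walkers. `urbangait` implements, as
a tested and reusable pipeline, the full computation that links per-second
outdoor tracker logs to zoning attributes:

1. **Track pipeline** — align GPS and accelerometer channels by date, smooth
   lat/lon with a 3-point moving average, derive 1 s ground speed from
   haversine distances, remove spikes (> 5.0 m/s), classify travel mode
   (walking < 1.39 m/s = 5 km/h, vehicular otherwise), and extract validated
   walking tracks: ≥ 20 consecutive in-band (0.30 – < 1.39 m/s) samples,
   ≤ 2 s bridged gaps, net displacement ≥ 20 m, step-periodic accelerometer
   signal (autocorrelation fundamental in 1.0 – 2.6 Hz), GPS distance
   ≤ 10 km. DGS = total GPS distance / track duration, pooled per
   participant as Σdistance / Σduration.
2. **Exposure** — point-in-polygon assignment of every walking second to a
   zone (GPR value, land-use category), 1 km home buffers, per-stratum
   time-spent (min/wk) and duration-weighted mean DGS, and metric-grid
   speed heatmaps.
3. **Cohort statistics** — education-adjusted MMSE classification
   (no formal education ≤ 25, primary ≤ 27, secondary+ ≤ 29 → CI), Pearson
   *r* with Fisher-z 95% CIs, simple and covariate-adjusted OLS with raw and
   standardized β, one-way ANOVA, Mann–Whitney *U*, Cohen's *d*, and stratum
   mean differences with Welch intervals.
4. **Synthetic world** — a first-class generator of zoning maps, cohorts and
   noisy 1 Hz tracker streams with known ground truth and a planted
   group × environment gait model

   speed = base(group) + β(group)·GPR + offset(group, land use) + ε,

   β = +0.04 m/s per GPR unit (nonCI) and −0.13 (CI), clipped to the
   walking band, so that every downstream stage is testable without any
   external data.

## Worked example

```python
import urbangait as ug

zm = ug.generate_zone_map(seed=1, n_rows=4, n_cols=4)        # ~1 km² neighborhood
cohort = ug.generate_cohort(seed=7, n=6, ci_fraction=0.5, zone_map=zm)
p = cohort[0]                      # P000, nonCI (MMSE 28, primary education)

stream, truth = ug.simulate_trajectory(p, zm, ug.GaitModel(), days=2, seed=11)
series, tracks = ug.process_stream(stream)
print(len(stream.gps), len(tracks), round(ug.participant_dgs(tracks), 3))
```

prints `2435 8 0.803`: two outdoor days yield 2,435 GPS seconds from which
the pipeline recovers 8 validated walking tracks, e.g.

```
track:  112 s,   83.0 m, dgs 0.741 m/s
track:  274 s,  217.1 m, dgs 0.792 m/s
track:  316 s,  236.2 m, dgs 0.748 m/s
```

and a pooled participant DGS of 0.803 m/s — the duration-weighted mean
speed of this (simulated) nonCI walker, a typical community-ambulation
speed. With jitter, dropouts and spikes disabled the recovered tracks match
the generator's planted bouts exactly and each track's DGS equals the
planted speed to < 1e-6 m/s.

The same stages are available from the shell:

```bash
urbangait simulate --seed 1 --n 6 --days 2 --outdir demo
urbangait process --gps demo/streams/P000_gps.csv \
                  --accel demo/streams/P000_accel.csv --outdir demo/proc
urbangait run-all --seed 1 --outdir demo/full     # simulate → … → report
```

`run-all` writes the zone map (GeoJSON), tracks and exposure tables (CSV),
association/stratum report tables, case-example heatmaps (PNG + GeoJSON)
and a manifest with the config hash and per-file checksums; identical
configs give identical checksums.

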