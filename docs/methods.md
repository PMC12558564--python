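# Methods

## The quantity of interest

Daily-life gait speed (DGS) is the average speed of validated outdoor
walking tracks: for one track, total GPS path distance divided by track
duration; for a participant, the duration-weighted pool Σdistance/Σduration
over all non-excluded tracks (a flag switches to the unweighted mean of
track speeds; the two differ on heterogeneous tracks). The analysis links
DGS to two zoning attributes of the walked environment: gross plot ratio
(GPR, the floor-area-to-parcel-area ratio, a built-density measure) and
land-use category (residential, commercial, business, community).

## Track extraction

Given 1 Hz positions, the pipeline applies, in order:

1. **Date alignment** of GPS and accelerometer channels (disjoint date
   ranges give an empty stream with a warning, not an error).
2. **3-point centered moving average** on latitude and longitude, with
   shrinking windows at the stream edges (width 1 at the endpoints; the
   edge rule is ours — any centered variant differs only in the two
   boundary samples). Smoothing damps multipath jitter; `window=1`
   disables it.
3. **Ground speed** at sample *i* = haversine(p_{i−1}, p_i)/(t_i − t_{i−1})
   on a sphere of radius 6,371,000 m (mean Earth radius; any common radius
   choice agrees to < 0.1%). The first sample's speed is defined as 0.
4. **Spike removal**: samples whose speed exceeds 5.0 m/s are dropped in a
   single left-to-right pass in which each sample's speed is recomputed
   against the last *kept* sample. A one-sample position spike therefore
   removes exactly one sample and re-links its neighbors across a
   bridgeable 2 s gap; no surviving speed exceeds the cap.
5. **Mode classification**: walking iff speed < 1.39 m/s (5 km/h),
   vehicular otherwise. Classification operates on smoothed, spike-filtered
   speeds — spike removal must precede it, else > 5 m/s artifacts would
   count as vehicular travel.
6. **Segmentation**: a greedy left-to-right scan opens a candidate at the
   first sample in the track band [0.30, 1.39) m/s and extends it while
   samples stay in band and consecutive timestamps differ by ≤ 2 s. A
   closed candidate becomes a track iff it has ≥ 20 in-band samples, net
   (first-to-last great-circle) displacement ≥ 20 m (rejects in-place
   dithering), no internal sample at or above 1.39 m/s, and — where
   accelerometer data exist — step periodicity (below). Bridged gaps
   contribute distance and duration but no sample count. Samples slower
   than 0.30 m/s are walking *mode* but terminate a candidate: the track
   band is stricter than the mode threshold. Tracks with GPS distance
   > 10 km are kept but flagged excluded as implausible for walking.
   Under these rules candidates are maximal runs, so greedy selection is
   provably equivalent to enumerating all windows and keeping maximal
   valid ones left to right — the equivalence is asserted against an
   independent brute-force enumerator in the test suite.
7. **Step periodicity**: the detrended accelerometer magnitude's
   autocorrelation is scanned for its earliest positive-lag peak reaching
   30% of the zero-lag value; the candidate passes iff that fundamental
   lies in 1.0–2.6 Hz. The earliest-prominent-peak rule deliberately avoids
   the harmonic ambiguity of a global-maximum rule: when the step period is
   a non-integer number of samples, autocorrelation multiples of the period
   can exceed the fundamental's sampled height. Both the band and the
   prominence fraction are configuration-exposed. Missing accelerometer
   data passes the check by default (logged); a flag discards such
   candidates instead.

All thresholds (1.39, 0.30, 5.0, 20 samples, 20 m, 2 s, 10 km, window 3)
live in `PipelineConfig`, are CLI-exposed, and are embedded via config hash
in every run manifest.

## Exposure

Each walking-track second is assigned to the zone containing its end
position. Point-in-polygon is exact for grid maps (index arithmetic) and
shapely-based otherwise; boundary points follow a fixed lower-left-inclusive
rule (a shared edge belongs to the zone whose left/bottom edge it is), so
every interior point belongs to exactly one zone. Time spent per stratum is
normalized to minutes per week as seconds × 7/observed_days ÷ 60, using the
full observation window even if some days hold no data. Stratum mean DGS is
the duration-weighted mean of step speeds, so re-weighting stratum means by
their seconds reproduces the participant's pooled DGS exactly — a
conservation identity asserted in the tests. Seconds outside every zone
accumulate in an explicit `unzoned` stratum; by default only
validated-track seconds count (a flag admits all outdoor seconds).
Heatmaps bin positions on a metric grid (default 25 m cells, local
equirectangular scaling at the extent's mean latitude) storing visit count
and mean — not maximum — speed per cell, rendered blue→red over
[0.30, 1.39] m/s.

## Cognitive classification and statistics

CI status is a deterministic function of MMSE and education with
Singapore-normed cut-offs: no formal education ≤ 25, primary ≤ 27,
secondary or higher ≤ 29; above the cut-off is nonCI.

Statistics mirror a small-cohort observational analysis, with
scipy/statsmodels as engines: Pearson *r* with Fisher-z 95% CI
(SE = 1/√(n−3)) and t-distribution p-values; OLS with intercept reporting
both the raw slope (m/s per GPR unit) and the standardized β (refit on
z-scored variables; equal to *r* in the simple model — asserted to 1e-12);
one-way ANOVA (F = t² for two groups — asserted); Mann–Whitney *U*
(minimum-U convention; exact null when n_x·n_y ≤ 400 without ties,
otherwise normal approximation with tie and continuity corrections);
Cohen's *d* with n−1-weighted pooled SD; Welch intervals for stratum mean
differences (the t-variant is our choice; it is the robust default).
α = .05 two-sided throughout. No multiplicity adjustment is applied, but a
Benjamini–Hochberg column accompanies every p-value table for transparency.
Sex and education enter adjusted models as indicators (reference: female,
no formal education).

The unit of analysis for the association tables is the per-(participant,
stratum) mean-DGS cell: a 33-participant cohort cannot produce the reported
F-statistic magnitudes at participant level, and per-cell analysis is the
reading consistent with them. The replicated recovery experiment (below)
instead uses one row per participant — pooled DGS against duration-weighted
mean GPR — which is the cleaner estimand-matched design.

## The synthetic world

The generator is first-class, tested code, and its defaults define the
study conditions:

- **Zone map**: an n×m grid tiling a ~1.1 km × 1.1 km WGS84 extent
  (the scale of one study neighborhood); each cell draws its GPR uniformly
  from the observed set {2.1, 2.5, 2.8, 3.0, 3.2, 3.5, 4.0, 4.2, 4.5, 4.9,
  5.6} and its land use uniformly from the four analyzed categories. Real
  zoning has 31 categories and spatially correlated attributes; only the
  analyzed strata are modeled and attributes are independent across cells.
- **Cohort**: ages truncated-normal (mean 69.2, SD 7.14, ≥ 55 y), 64%
  female, education marginals (10/42/48%) near the study cohort's. Exactly
  round(n·ci_fraction) participants draw an MMSE at or below their
  education-adjusted cut-off. Homes are uniform in the extent.
- **Gait model**: speed = base(group) + β(group)·GPR +
  offset(group, land use) + ε, clipped to [0.30, 1.39) m/s, with planted
  β = +0.04 (nonCI) and −0.13 (CI) m/s per GPR unit and offsets making
  nonCI faster in business/commercial zones and CI faster in
  community/residential ones. Bases (0.596, 1.214 m/s) are calibrated so
  each group's expected speed under uniform exposure to the GPR set
  (mean 3.664) matches the observed group means 0.75/0.73 m/s. ε is one
  N(0, 0.05 m/s) draw per bout. Configurations whose pre-clip speeds leave
  [0, 5] m/s are rejected as misconfigured.
- **Trajectories**: one outdoor session per day (start 08:00–10:00), 2–4
  walking bouts of 120–600 s on piecewise-linear waypoint paths (heading
  updates every 30–120 s, reflection at the extent boundary), separated by
  stationary dwell and occasional vehicular rides at 2.0–4.5 m/s.
  Per-second walking speed is the clipped model prediction for the zone
  currently occupied.
- **Degradations**: GPS error is a first-order Gauss–Markov process with
  stationary sd 3 m (consistent with 15 m accuracy as a ~5σ envelope) and
  correlation time 200 s. The temporal correlation matters: per-second
  *white* noise at 3 m would give apparent stationary speeds near 4 m/s,
  which no real receiver produces and which would destroy every walking
  track; correlated error is the standard GPS error model. Dropouts delete
  single seconds (bridgeable 2 s gaps, ~1/300 rate); spikes displace single
  positions by 12–40 m (> 5 m/s apparent speed, ~1/600 rate). The
  accelerometer channel (10 Hz) carries a per-bout sinusoid at 1.4–2.2 Hz
  during true walking and broadband low-amplitude noise otherwise — a
  signal model sufficient for a periodicity check, not a biomechanical one.
- **Ground truth** records every sample's true mode, zone and bout
  membership; each bout's true mean speed is its true path distance over
  duration — exactly what a perfect pipeline would report.

What passing tests on this world do *not* show about real data: no urban-
canyon bias fields, indoor/outdoor ambiguity, map-matching error, device
duty-cycling, or behavioral confounding between where people walk and how
fast they walk beyond the planted additive structure.

## Replicated slope recovery

Each replicate draws a fresh 6×6 map, a cohort of 200 (half CI), and
14–28 bouts per participant directly from the gait model (bout-level
sampling; the per-second GPS round trip is validated separately by the
exact noise-free recovery test and the jitter-robustness test, and 50 full
per-second simulations would add nothing but runtime). Per group we regress
participant pooled DGS on duration-weighted mean GPR, adjusting for
land-use time shares with HC3 robust standard errors, and record whether
the planted slope falls inside the fitted 95% CI. The land-use adjustment
is required for a correctly specified model: the generating process has
additive land-use effects, and within one replicate all participants share
one finite map whose sample offset–GPR covariance otherwise acts as a
common confounder that the within-replicate CI cannot see (unadjusted
coverage runs ~5–10 points low). Robust SEs account for pooling over
unequal bout counts. Across 50 replicates the planted slopes are recovered
unbiasedly and covered in ≥ 90% per group.

## Numerical choices and degenerate inputs

- Earth radius fixed at 6,371,000 m; all metric math via haversine, no
  projection (heatmap binning alone uses equirectangular scaling).
- Timestamp gap semantics: consecutive-sample Δt of exactly 1 s is normal;
  Δt in (1, 2] s is a bridged gap; Δt > 2 s closes a candidate.
- Target speeds clip to [0.30, 1.385] m/s — 5 mm/s inside the band's open
  upper end so float round-trips through position arithmetic cannot
  misclassify a boundary sample.
- Boundary-point zone assignment is exact only on exactly representable
  grid edges; generic float coordinates make edge hits measure-zero.
- Empty inputs: empty streams yield empty track lists; participants with
  no valid track get NaN DGS with a warning; empty strata are flagged
  missing rather than imputed; an all-spike series empties cleanly.
- Full determinism: every stage draws from seeds spawned from one master
  seed; two runs of the same config produce byte-identical text artifacts
  (checksummed in the manifest; PNGs are excluded from checksumming).

## Known limitations

- **Band-floor dropout.** When planted speeds approach the 0.30 m/s track
  floor (the CI group in GPR-5.6 zones under the planted slope), 3 m GPS
  noise pushes apparent speeds out of band and most such bouts are lost;
  recovered group means are then biased toward faster walkers. This is
  inherent to threshold-based segmentation, asserted explicitly as a
  failure-mode test, and visible in the acceptance output (the recovered
  CI mean exceeds its planted value while the planted slope is recovered
  correctly by the bout-level experiment).
- GPS path noise inflates track distance slightly (+0.02–0.04 m/s at
  default jitter); the 3-point smoother bounds but does not remove it.
- The exposure tables take zone labels verbatim from the map; no attempt
  is made to reconcile externally inconsistent labelings of the same
  strata.
- Mann–Whitney exactness is unavailable under ties (the corrected normal
  approximation is used regardless of sample size).
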