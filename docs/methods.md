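# Methods

This note documents the statistical procedures implemented in `mhwbloom`,
the choices made where conventions diverge, and what the synthetic-data
experiments do and do not demonstrate.

## Day-of-year climatology

For each of 365 calendar-day slots, all non-missing observations within a
centred window of ±`window_halfwidth` days (default 5, an 11-day window)
across every reference year are pooled. The slot mean, the requested
percentiles (linear interpolation between order statistics by default; the
rule is configurable because threshold values are sensitive to it) and the
sample standard deviation are computed on the pool. Each resulting annual
curve — mean, dispersion and every percentile — is then smoothed with a
centred moving mean of `smooth_window` days (default 31), circular across
the year boundary.

Choices worth noting:

- **Smoother parity.** A "30-day moving window" has no centre; we use a
  31-day centred window and require the width to be odd.
- **Exactness on degenerate input.** The smoother is a sliding-window mean,
  not a convolution with a 1/31 kernel: a constant series must reproduce its
  own value *exactly*, otherwise strict threshold comparison manufactures
  spurious exceedance from float rounding.
- **Leap days.** The climatology has 365 slots; 29 February contributes to
  and reads from the 28 February slot, so thresholds are year-invariant.
- **Missing data** are dropped from pools, never imputed; a slot only errors
  if its pool is entirely empty.
- **Reference periods are explicit.** Long records are often analysed
  against one baseline (e.g. 1982–2018 for trends) and compound analyses
  against a shorter one matching the ocean-colour era (e.g. 1998–2018);
  `build_climatology` therefore always takes the reference period as an
  argument.
- The standard deviation used for standardized anomalies is pooled and
  smoothed through the same pipeline as the mean.

## Extreme-event detection

A day is exceedant when its value is strictly above the upper-percentile
threshold (high polarity) or strictly below the lower one (low polarity);
missing days are never exceedant and therefore break runs. Maximal exceedant
runs of at least `min_duration` days become candidate events; candidates
separated by at most `max_gap` non-exceedant days are merged
(filter-by-duration first, then merge — short runs cannot be rescued by
merging). Detection presets:

| preset | thresholds | min duration | gap joining |
|---|---|---|---|
| SST, trend analysis | 90th / 10th | 5 d | 2 d |
| SST, compound analysis | 92nd / 8th | 10 d | 2 d |
| Chl-a | 90th / 10th | 3 d | 0 d |

Gap joining follows the common heatwave-toolbox convention of 2 days for
SST. For Chl-a it is disabled by default: with a 3-day minimum duration,
2-day joins would let merge artifacts dominate the event catalog. Chl-a
detection is meant to run on the quality-controlled, gap-interpolated
series (see below). Runs truncated by the series boundary count if their
observed length qualifies and are flagged `edge_truncated`.

Intensities are departures from the climatological **mean** (not the
threshold): `max_intensity` is the most extreme signed departure,
`mean_intensity` and `cumulative_intensity` average/sum departures over the
whole merged span (gap days included; missing days excluded and counted).

## Compound events and season classification

Within a regional blooming window (NRS January–March, NCRS/SCRS
December–February, SRS October–January, basin October–March; cross-year
windows end in the following calendar year and are labelled by the starting
year), an SST extreme and a Chl-a extreme match if their spans share a
calendar day (*concurrent*) or if the Chl-a event starts 1..7 days after the
SST event's last day (*lagged*; the lag anchors on the event **end**, a
reading of "following" that is configurable). Each blooming period is one
case, classified with deterministic precedence:

`expected` (≥1 MHW–LChl-a or MCS–HChl-a match) > `opposite` (matches exist,
all in the unexpected direction) > `sst_only` (SST extreme, no matching
Chl-a extreme) > `none`. A case with matches in both directions classifies
`expected` with an `ambiguous` flag. Seasons with Chl-a extremes but no SST
extreme are tracked (`chl_only`) but excluded from the denominator of the
expected-response percentage, which counts only seasons with at least one
SST extreme. Events join a window on any calendar-day intersection; their
metrics are not re-clipped to the window.

## Trends in event days

Annual event days are the days of detected events falling inside the
resolved window of each season (out-of-window days of straddling events are
not counted). The trend is ordinary least squares of annual days on season
year, reported per decade (10× the per-year slope), with a two-sided t test
on the slope (n−2 degrees of freedom) at α = 0.05. No serial-correlation
correction is applied — a known limitation; with autocorrelated annual
counts the test is anti-conservative. Zero-residual fits (flat pixels,
perfect lines) have an undefined t statistic and are returned with slope
intact, p = 1 and a `degenerate` flag rather than raising, because trend
maps routinely contain such pixels.

## Mixed layer depth

The MLD criterion is a 0.2 °C temperature difference relative to the
temperature at 10 m. The reference temperature is linearly interpolated at
exactly 10 m (profiles starting slightly deeper, within 5 m, clamp to their
shallowest level). The MLD is the shallowest depth below the reference where
the deficit reaches 0.2 °C, located by linear interpolation between the
bracketing levels — a midpoint rule was rejected because its error scales
with grid spacing. If the deficit never reaches the criterion the deepest
level is returned with flag `bottom_reached`; profiles with no usable
surface level return a missing MLD. Depth is positive downward and inputs
must already be on depth (not pressure) levels; salinity is carried but
unused by the temperature criterion. MLD anomalies are reported with
*deeper = positive*.

## Synthetic data: what it emulates and what it does not

The generator produces multi-decadal daily series on a real Gregorian
calendar. SST is a cosine seasonal cycle (default 27 ± 3 °C peaking
mid-August) plus an optional linear warming trend plus AR(1) Gaussian
residuals — `noise_sd` (default 0.5 °C) is the *stationary* standard
deviation and `ar1_coef` (default 0.7) the lag-1 autocorrelation. Chl-a is a
strictly positive winter-bloom curve (background 0.15 mg/m³ rising to
~0.5 mg/m³ around 1 February) with mean-corrected multiplicative lognormal
noise (cv 0.3, chosen because ocean-colour series are positive and
right-skewed), 10% random missing days, and rare spurious spikes drawn
uniformly in (10, 20] mg/m³ so the quality-control cap is exercised.
Injected episodes add ±amplitude to SST over their span; their Chl-a
response multiplies the bloom curve (default ×0.5 for warm, ×2.0 for cold)
over the span shifted by the coupling lag (default 3 days). Because the
coupling acts on the mean level — additively in log space — expected span
means are analytically checkable.

Deliberately **not** emulated: ocean dynamics of any kind, coupling of MLD
to surface forcing, spatially correlated noise (gridded fields add
independent pixel noise plus whole-day coverage dropout), cloud-driven
seasonal missingness, or sensor drift. Passing tests therefore demonstrate
correctness of the *algorithms* under controlled statistical structure, not
skill on real satellite records.

## Validation experiments (`mhwbloom.benchmarks`)

- **Null calibration** (defaults, 20 event-free years): the fraction of days
  above the in-sample 90th-percentile threshold is 10% within ±1.5
  percentage points; loose-criterion events (90th, ≥5 d) are rare but
  reliably nonzero under persistent residuals, and the strict criterion
  (92nd, ≥10 d) finds strictly fewer.
- **Boundary recovery** (200 replicates): one episode of duration 12 and
  amplitude 4× the Gaussian 90th-percentile margin is injected per
  replicate into serially *independent* noise; recovery requires start and
  end each within ±1 day of truth. Independence here is a deliberate design
  choice, not a simplification of convenience: under persistent noise an
  adjacent warm day genuinely belongs to the exceedance run, so the ±1-day
  "truth" is ill-defined — the probability of two consecutive spurious
  exceedant days next to the event is ~4.7% per side at lag-1
  autocorrelation 0.7 versus 1% when independent. The experiment isolates
  the detector's localisation error from that intrinsic ambiguity; boundary
  precision on strongly autocorrelated real series is accordingly lower.
- **Coupled response** (200 replicates, full defaults including persistent
  SST noise, noisy/missing Chl-a): one strong episode (2.5 °C, 20 d) inside
  the January–March window with the default coupled response must classify
  its season `expected` through the entire chain (generation, QC,
  climatologies, both detections, matching, classification).
- **Trend coverage** (200 replicates): 37 years of linear-plus-noise annual
  counts (true slope 15 days/decade, noise sd 8 days); the 95% CI of the
  OLS slope must cover the truth in ≥90% of replicates, and the estimator
  is checked against the closed-form solution to 1e-10.
- **MLD round-trip** (100 profiles, 5 m grid): the temperature criterion
  locates the layer base at truth + Δt/gradient metres; with gradients
  0.05–0.15 °C/m this bias (1.3–4 m) stays below one grid spacing.

Experiment sizes match what the library is expected to handle interactively;
all randomness flows from a single integer seed.

## Known limitations

- The t test on trends ignores serial correlation of annual counts.
- Detection uses a fixed-baseline climatology; under a strong warming trend
  the fixed baseline converts mean warming into extra heatwave days (this is
  the point of trend analysis, but "detrended-baseline" event definitions
  are out of scope).
- Region boundaries are configuration inputs; the shipped latitude-band
  boxes are illustrative, not an authoritative regionalisation.
- Area weighting of spatial means defaults to unweighted pixels; cosine
  weighting is available but secondary at modest latitude spans.
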