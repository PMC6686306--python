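# Methods

`pelagis` re-implements, as one tested pipeline, the computational chain used
to study year-round distribution and activity budgets of a resident,
colony-based pelagic seabird population tracked with combined light-level /
saltwater-immersion loggers. This note documents the models, their
assumptions, the tunable parameters, and the numerical choices, in the order
the pipeline runs them.

## Solar and lunar geometry

All twilight-based computations share one low-precision solar model:
declination from a three-harmonic Fourier series in day of year (error below
~0.3°, with zero crossings on the actual equinox dates), the equation of time
from the classic three-term approximation (|error| < 1 min), and elevation
from `sin e = sin φ sin δ + cos φ cos δ cos H`. The same model drives both the
synthetic light renderer and the geolocation solver, so round-trip tests
measure algorithmic error rather than ephemeris mismatch. Real twilight times
carry minute-scale deviations (refraction, atmospheric variability) that this
model ignores; they are far below the ~186 km accuracy scale of threshold
geolocation.

The moon's illuminated fraction is a synodic cosine:
`frac = (1 − cos(2π·age/29.530588))/2`, with age counted from the new moon of
2000-01-06 18:14 UTC. Phase error against a full ephemeris is under one day —
irrelevant to a cyclic smooth with k = 3. An external per-date almanac table
can override the formula. The trend models use lunar *age* (days, 0 = new
moon) as the cyclic covariate, matching the day-1-new-moon / day-15-full-moon
axis convention; the illuminated fraction is carried alongside for reporting.

## Threshold geolocation

Light series (integer 0–64, one maximum per 5- or 10-min interval) are
inverted to two positions per day by the threshold method:

- **Twilights.** Dawn/dusk are the linearly interpolated times at which light
  crosses the threshold (default 10). Linear interpolation is adequate at
  5–10-min sampling; higher-order schemes would fit sampling noise.
- **Interference screening.** Lit or dark segments shorter than 120 min
  indicate shading at the nest or sensor interference; the bounding crossing
  pair is cancelled and the affected twilight pairs are flagged
  `interference-suspect` and excluded from position derivation. This replaces
  the manual inspection of light curves used with vendor software by an
  automated, reproducible rule.
- **Longitude** from the dawn–dusk midpoint (local apparent noon):
  `λ = 15°/h · (12:00 UTC − t_noon) − EoT`, normalized to (−180, 180].
- **Latitude** from day length: with half-arc `ω₀` (7.5° per hour of day
  length) solve `sin a = sin φ sin δ + cos φ cos δ cos ω₀` for φ by bracketed
  root finding on [−89°, 89°] (1° sign-change scan + Brent). `a` is the tag's
  calibrated sun elevation angle (−3.5° for one tag model, −4.0° for the
  other). With two roots, the one nearer the previous accepted fix wins;
  without history the configured hemisphere (default south) decides. When
  |δ| < 1.5° (near an equinox) latitude is unidentifiable and the fix is
  flagged `latitude-indeterminate`.
- **Midnight fixes** use the dusk–next-dawn interval with `ω₀ = 180° − night
  half-arc`; they are dated by the earlier day. The vendor software's
  noon/midnight date pairing convention is not recoverable, so this convention
  is simply documented.
- **Filtering.** Fixes within ±10 days of 20 March / 22 September are flagged
  `equinox-excluded`; an iterative filter flags fixes implying sustained speed
  above 85 km/h to both neighbours. Flags annotate rows; nothing is deleted.

## Immersion activity analysis

Wet/dry event durations (3-s sensor resolution) are modelled, per individual,
as a two-process exponential mixture
`f(t) = p·λ_f e^(−λ_f t) + (1−p)·λ_s e^(−λ_s t)`, λ_f > λ_s: a fast process
(rapid switching while actively foraging) and a slow process (prolonged flight
or floating). The maximum-likelihood fit uses L-BFGS-B on the unconstrained
parameterization `(logit p, log λ_f, logit(λ_s/λ_f))` with eight starts (one
moment-based). The bout-ending criterion (BEC) is the equal-likelihood
crossover `ln(p·λ_f / ((1−p)·λ_s)) / (λ_f − λ_s)`. A fit is *degenerate* —
and raises an error rather than returning a number — when the rate ratio
falls below 1.5, the mixing proportion hits its boundary, or the BEC is
non-positive; all three are signatures of single-process data. Per-individual
BECs are averaged into one population criterion; with no data the packaged
study average of 53.16 min is used. Wet and dry durations are pooled for the
fit: one shared criterion classifies both states, so a pooled population is
the consistent reading (per-state fitting is available).

Before fitting, immersion changes shorter than 1.5 min are *absorbed* rather
than deleted — the two flanking same-state events merge across the short one,
shortest first — so the series stays alternating and total time is conserved
exactly. Whether the original exclusion preceded the bout fit is unstated;
merging-then-fitting is the default order here.

Classification is three strict-inequality rules: dry > 16 h → on land
(such events occur only at the nest); otherwise dry > criterion → sustained
flight; wet > criterion → floating; everything else → foraging. Boundary
cases (exactly the criterion, exactly 16 h) fall to the less extreme class.

Daily budgets intersect events with the daylight interval [dawn, dusk] of each
date and the following darkness interval [dusk, next dawn], using the
individual's own detected twilights (dates lacking a clean pair borrow the
nearest pair's clock times and are flagged). Proportions of
foraging/flight/float are **of at-sea time**; land time is reported in a
separate column. The three proportions therefore close to 1 exactly wherever
at-sea time is positive (a total-time denominator is available as a toggle).
Breeding stages come from a fixed colony calendar (hatching 12–24 Dec 2012,
brooding to 26 Jan, rearing to 7 Apr, nonbreeding ending 5 Sep 2013),
configurable. The individual return date is the start of the first on-land
event on or after the season boundary minus a 30-day look-back that admits
early returners.

## Spatial analysis

Fixes are projected into an azimuthal equidistant plane centred on the colony
(spherical Earth, R = 6371.0088 km): distance and azimuth from the colony are
preserved exactly, which is what the kernel and rotation analyses need.
Utilization distributions are fixed-bandwidth isotropic Gaussian KDEs
(h = 100 km) on a grid padded ≥ 3h beyond the points, renormalized to
integrate to 1. The study grid of 1,000-m cells is supported, but analyses
default to 5–25 km cells: with h = 100 km the density is insensitive to cell
sizes below ~h/10, and the coarse grid is purely a performance choice.
Percent-volume isopleths take cells in decreasing density order until the
target mass is reached, including ties at the critical density (so a uniform
distribution's isopleth is the whole support). The 50% mask is nested in the
90% mask by construction.

Pairwise overlap is the Utilization Distribution Overlap Index,
`UDOI = A_overlap · Σ UD₁·UD₂ · cell_area`, with `A_overlap` the area of
intersection of the two chosen isopleths (default 0.90; a positive-density
full-grid variant is available — which domain the original analysis used is
not recoverable). UDOI is 0 for disjoint ranges and 1 for identical uniform
ones.

Segregation between groups is tested by correlating (Pearson, upper triangle)
the overlap matrix with a 0/1 different-group membership matrix, then
rebuilding the null 1,000 times (tests scale this to 200) with every
individual's point cloud independently rotated by a uniform angle about the
colony — an exact isometry in the projected plane that preserves each range's
shape and colony distance while destroying inter-individual correspondence.
The p-value is the *lower-tail* proportion of null correlations below the
observed one, exactly as defined for this statistic; no ±1 small-sample
correction is added. Monthly analyses use calendar months, with March and
September truncated to their first 10 days (the remainder sits in the equinox
exclusion windows).

Representativeness of the tracked sample follows the standard bootstrap: for
each subsample size k, pool k individuals' points into one UD and score its
90% isopleth by the inclusion rate of the held-out individuals' points; a
Michaelis–Menten curve `a·k/(b+k)` fitted to mean inclusion vs k gives
`100 · predicted(n)/a`. Distances to the colony are great-circle (haversine)
per-fix, averaged per individual; group comparisons resample *individuals*
(percentile bootstrap CI) and report a two-sided permutation p-value from
label shuffling.

## Activity trend models

For each activity × light period, the daily proportion is modelled on the
logit scale with binomial-form variance and a free dispersion (quasi-binomial):

    logit E[y] = α + β·status + f_status(days since laying) + f_cyc(lunar age)
                 + b_bird [+ g_bird(days)]

- `f_status`: one penalized smooth per breeding status — cubic B-splines with
  12 basis functions on the observed day range and a second-difference
  penalty. This is a specified, simplified stand-in for thin-plate regression
  splines at the same basis dimension; the knot count matches, the penalty
  null space (linear trends) matches, and the exact penalty construction of
  the original software is deliberately not replicated.
- `f_cyc`: periodic cubic B-splines (k = 3) over the 29.53-day lunar cycle,
  built from wrapped cardinal B-splines — value and derivative match exactly
  at the cycle seam — with a circular second-difference penalty.
- `b_bird`: per-individual random intercepts as a ridge-penalized block.
- `g_bird` (optional, off by default): per-individual deviation smooths on a
  shared rank-5 B-spline basis, each with its own smoothing parameter; the
  shared-smoothness variant is intentionally not offered because it conflates
  individual and group wiggliness.

Spline bases are partitions of unity, so after column-centring the all-ones
coefficient direction lies in both the design and penalty null spaces; it is
removed by an explicit orthogonal reparameterization (sum-to-zero constraint
absorption), which keeps the penalized system positive definite without ad
hoc ridging.

Fitting is penalized IRLS on the logit scale with exposure weights (the
period's at-sea minutes as binomial denominator — the original weighting
basis is unstated, and unweighted fitting is a toggle). Dispersion is the
Pearson statistic over residual degrees of freedom `n − edf`. Smoothing
parameters minimize GCV `n·X²/(n − edf)²` by a per-term log-grid search
refined by golden section, inside a two-pass backfitting-style outer loop.
Effective degrees of freedom per term are the trace of the corresponding
block of `(XᵀWX + S)⁻¹XᵀWX`. Pointwise intervals and per-term Wald-type F
statistics use the penalized ("Bayesian") covariance `φ(XᵀWX + S)⁻¹` with
rank = rounded edf; as for any penalized fit these are approximate, and the
CI-coverage and calibration properties are checked by simulation rather than
assumed.

The moon-cycle window comparison averages each individual's proportions over
two one-lunar-cycle windows (early chick-rearing 28 Jan–25 Feb 2013;
nonbreeding 24 Jun–21 Jul 2013) and compares them with the individual as the
resampling unit: a paired sign-flip permutation for the window factor, and
the bootstrap/permutation group comparison for status and sex within windows.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
the analyses are validated under. Defaults mirror the deployment: 48
successful + 12 failed breeders (22F/26M and 6/6), laying 11 Oct 2012 ± 2 d,
68-day incubation (hatching mid-December), failures 26 Dec ± 29 d truncated
to [laying+5 d, end of rearing], colony at 51.85°S 61.30°W, records from
20 Oct 2012. Return dates are drawn per status × sex (failed males
27 Aug ± 9 d; males 7 Sep ± 10 d; females ~12–16 Sep ± 12 d), reflecting the
earlier return of failed males.

- **Movement** is a discretized 2-D Ornstein–Uhlenbeck walk about the colony
  in the projected plane (30-min steps, 5-day reversion timescale). The
  per-axis stationary SD is `scale/√(π/2)` so the long-run mean colony
  distance equals the configured range scale (500 km free-ranging, 250 km
  while still attending the colony). Colony shifts are scheduled per stage
  (per-day start probability × exponential shift length, means 36 h
  incubation, ~20 h brooding/rearing, > 16 h wherever attendance implies
  multi-hour nest sitting); the bird homes in a straight line at bounded
  speed ahead of each shift, and all steps are clipped to the 80 km/h speed
  cap so implied speeds never trip the 85 km/h filter.
- **Behaviour** is semi-Markov with exponential sojourns, state probabilities
  and mean durations specific to stage × light period (rearing raises
  foraging for successful birds; the nonbreeding season shifts darkness time
  into floating). Foraging is rendered as rapid wet/dry alternation
  (means 4 / 2.5 min). At night the odds of the active states scale with the
  moon's illuminated fraction (±50% from new to full moon), giving the trend
  models a real cyclic signal to recover. Failure switches a bird to
  nonbreeding parameters the day it happens. A bird at sea settles on the
  water at least every 10 h (counting only wet phases long enough to survive
  the short-event merge as interruptions), encoding the study premise that
  dry events longer than 16 h occur only on land. Exponential sojourns make
  the bout mixture exactly well-specified, so recovery tests have closed-form
  targets.
- **Light** is a logistic map of solar elevation with midpoint anchored so
  the curve passes through the detection threshold exactly at the calibrated
  sun angle, rounded to the integer 0–64 scale; optional interference sets
  random twilight-adjacent samples to low values. **Immersion** collapses
  behaviour to wet (foraging-wet, float) vs dry (foraging-dry, flight, land),
  merges runs and quantizes to the sensor resolution (each event conserved to
  within one quantum).

What the generator does *not* emulate: weather- and prey-driven movement,
tag clock drift, light-sensor fouling beyond simple twilight interference,
latitude-dependent light attenuation, molt, energetics, or inter-annual
variation. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under the stated statistical assumptions,
not the field accuracy of threshold geolocation or immersion classification
on real tags.

## Problem sizes and determinism

End-to-end runs and the acceptance script use a scaled cohort — 12 successful
+ 6 failed birds, 11 months at 10-min light and 1-min immersion resolution,
25-km analysis grid, 200 rotation iterations — chosen so a complete run
remains a few minutes on one core while keeping every structural feature of
the full-size study (which is reachable by configuration: 60 birds, 3-s
immersion, 1-km cells, 1,000 iterations). Calibration simulations use 200
replicates × 200 iterations. One global seed is fanned out to per-stage child
seeds via `numpy.random.SeedSequence` spawning; rerunning any configuration
with the same seed reproduces every artifact byte-identically (the manifest
records a config hash and per-stage row counts to make this checkable).

## Known limitations

- Threshold latitude degrades gracefully but inevitably near the equinoxes;
  the ±10-day exclusion window and the |δ| < 1.5° indeterminacy flag are
  blunt instruments by design.
- The GCV-based smoothing selection can undersmooth in small cohorts, as GCV
  is known to; REML selection is out of scope.
- Wald F statistics for penalized smooths and pointwise CIs are approximate;
  their simulation-checked calibration is good but not exact.
- The UDOI depends on the integration domain; both isopleth-restricted
  (default) and full-grid variants are provided because the original choice
  is not recoverable from the text.
- `bootstrap_group_difference` treats individuals as exchangeable within
  groups; it does not model within-individual temporal autocorrelation
  (budgets are first averaged per individual precisely to sidestep this).
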