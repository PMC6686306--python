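# pelagis

Year-round biologging analysis for resident, colony-based pelagic seabirds —
populations (such as Falklands black-browed albatrosses) that stay within a
few hundred kilometres of their breeding colony instead of migrating, so the
same combined light-level / saltwater-immersion logger record covers
incubation, chick-rearing and the whole nonbreeding season. The package is
aimed at movement ecologists who want the full chain from raw logger channels
to population-level inference as reproducible, seeded, tested code:

1. **Threshold light-level geolocation** — two positions per day. Dawn and
   dusk are the interpolated times the light record crosses a threshold
   (default 10 on the 0–64 tag scale); longitude follows from the dawn–dusk
   midpoint, `λ = 15°/h · (12:00 UTC − t_noon) − EoT`, and latitude from day
   length by solving `sin a = sin φ sin δ + cos φ cos δ cos ω₀` for φ at the
   tag's calibrated sun elevation angle `a` (−3.5°/−4.0°). Interference is
   screened automatically and fixes near the equinoxes (latitude-blind
   periods) or implying speeds above 85 km/h are flagged, never deleted.
2. **Immersion bout analysis** — wet/dry event durations are modelled as a
   two-process exponential mixture `f(t) = p·λ_f e^{−λ_f t} + (1−p)·λ_s
   e^{−λ_s t}` fitted by maximum likelihood; the bout-ending criterion
   `BEC = ln(p·λ_f / ((1−p)·λ_s)) / (λ_f − λ_s)` separates rapid wet–dry
   switching (foraging) from prolonged states. Events longer than the
   criterion are sustained flight (dry) or floating (wet); dry events over
   16 h are incubation/brooding shifts on land. Daily budgets are split into
   daylight and darkness at the tag's own twilights.
3. **Spatial segregation** — monthly kernel utilization distributions
   (Gaussian KDE, 100-km smoothing), 50/90% percent-volume isopleths, the
   Utilization Distribution Overlap Index (UDOI) between all pairs, and a
   rotation-randomization test: the observed correlation between pairwise
   overlap and group membership is compared with a null built by rotating
   each individual's range independently around the colony (p = lower-tail
   proportion of null correlations below the observed one). Plus a
   sample-size representativeness bootstrap and distance-to-colony
   comparisons.
4. **Activity trend models** — quasi-binomial penalized-spline models of
   daily activity proportions: per-status group smooths of days-since-laying
   (12 basis functions), a cyclic lunar smooth (k = 3), per-bird random
   intercepts and optional per-bird deviation smooths, with GCV smoothing
   selection, Wald F statistics per smooth, and a moon-cycle-window bootstrap
   comparison of breeding vs nonbreeding activity.
5. **A seeded synthetic-data generator** that emulates the whole deployment —
   breeding metadata, central-place movement, semi-Markov behaviour, and
   forward-rendered light and immersion channels — so every analysis step can
   be validated against known ground truth.

The model-fitting components follow the statsmodels convention: a model
object built from data whose `fit()` returns a results object
(`BoutMixtureModel → BoutMixtureResults`, `ActivityTrendModel →
ActivityTrendResults`) with estimates, uncertainties and `summary()`.

## Worked example

Simulate one bird's year, geolocate it, and run the bout analysis:

```python
import numpy as np
from pelagis import (SimulationConfig, simulate_cohort, simulate_movement,
                     simulate_behavior, render_light, render_immersion,
                     detect_twilights, derive_positions, filter_positions,
                     merge_short_events, fit_bout_model, classify_events)
from pelagis.geo import haversine_km

cfg = SimulationConfig(n_successful=1, n_failed=0, seed=42)
bird = simulate_cohort(cfg)[0]
path = simulate_movement(bird, cfg, seed=1)
light = render_light(path, light_interval_min=10.0, noise=0.0, seed=2)
immersion = render_immersion(simulate_behavior(path, bird, cfg, seed=3),
                             resolution_s=cfg.immersion_resolution_s)

fixes = filter_positions(derive_positions(detect_twilights(light),
                                          sun_angle=-3.5,
                                          individual_id=bird.individual_id))
clean = [f for f in fixes if not f.flags and np.isfinite(f.lat)]
t = [f.time.astype(float) for f in clean]
err = haversine_km(np.array([f.lat for f in clean]),
                   np.array([f.lon for f in clean]),
                   np.interp(t, path.times.astype(float), path.lat),
                   np.interp(t, path.times.astype(float), path.lon))
print(f"{len(fixes)} fixes, {len(clean)} clean; "
      f"median error vs truth: {np.median(err):.0f} km")

merged = merge_short_events(immersion, min_duration_min=1.5)
result = fit_bout_model(merged.durations_s / 60.0, seed=0)
print(result.summary())
```

prints

```
699 fixes, 613 clean; median error vs truth: 89 km
Two-process exponential mixture (wet/dry bout analysis)
--------------------------------------------------------
events                         8168
log-likelihood            -32554.05
p (fast fraction)            0.8284
lambda_fast [1/min]          0.1424
lambda_slow [1/min]         0.00307
bout criterion [min]          38.84
converged                      True
```

A year of twice-daily fixes recovers the moving bird's track with a median
great-circle error of 89 km — inside the ~186 km accuracy expected of
threshold geolocation — with the 10-day equinox windows and interference
flagged out. The mixture cleanly separates a fast process (mean event
1/0.1424 ≈ 7 min: active foraging) from a slow one (mean ≈ 5.4 h: flight or
floating), and the 38.8-min criterion is then the duration threshold used by
`classify_events` to label every event foraging / flight / float / land.

The same chain runs end to end from the shell:

```sh
pelagis run --config run.toml --seed 1
```

which writes fixes, labelled events, daily budgets, monthly overlap and
segregation tests, representativeness curves, fitted trend curves and the
window comparison into the output directory, together with a manifest
(config hash, per-stage seeds and row counts) that makes the run
byte-reproducible.

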