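"""End-to-end orchestration: simulate -> geolocate -> activity -> spatial -> trends.

A single seeded, configured run with every intermediate artifact written to
disk and a JSON manifest (config hash, child seeds, per-stage row counts,
warnings) that makes reruns byte-reproducible.  One global seed is fanned out
to per-stage child seeds through numpy's SeedSequence spawning, so any stage
can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import fileio, geolocation, spatial, trends
from . import simulate as sim
from .moon import moon_fraction

logger = logging.getLogger(__name__)

STAGES = ("simulate", "geolocate", "activity", "spatial", "trends")


@dataclass
class RunConfig:
    """All pipeline parameters in one validated place.

    Defaults are the scaled synthetic cohort used for end-to-end runs: 12
    successful + 6 failed birds, 10-min light sampling, 1-min immersion
    resolution, coarse (10 km) analysis grid and 200 randomization iterations.
    The full study-scale settings (48+12 birds, 3-s immersion, 1 km cells,
    1,000 iterations) are reachable by overriding fields.
    """

    out_dir: str = "pelagis_run"
    seed: int = 0
    stages: tuple = STAGES
    n_successful: int = 12
    n_failed: int = 6
    light_interval_min: float = 10.0
    immersion_resolution_s: float = 60.0
    light_noise: float = 0.0
    # geolocation
    light_threshold: float = 10.0
    sun_angle: float = -3.5
    max_speed_kmh: float = 85.0
    equinox_window_days: int = 10
    # activity
    criterion: str | float = "auto"  # "auto" = per-individual ML fits, else minutes
    land_threshold_hr: float = 16.0
    merge_min: float = 1.5
    bout_fit_floor: int = 100
    # spatial
    bandwidth_km: float = 100.0
    cell_km: float = 10.0
    rotation_iters: int = 200
    bootstrap_iters: int = 200
    representativeness_iters: int = 50
    months: tuple = ("2013-02", "2013-03", "2013-04", "2013-05", "2013-06", "2013-07", "2013-08", "2013-09")
    # colony-distance summaries cover February to the start of September
    distance_window: tuple = (np.datetime64("2013-02-01"), np.datetime64("2013-09-10"))
    # trends
    trend_activities: tuple = trends.ACTIVITIES
    trend_periods: tuple = trends.PERIODS
    individual_smooths: bool = False
    window_a: tuple = (np.datetime64("2013-01-28"), np.datetime64("2013-02-25"))
    window_b: tuple = (np.datetime64("2013-06-24"), np.datetime64("2013-07-21"))
    make_figures: bool = True

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if isinstance(self.criterion, str) and self.criterion != "auto":
            raise ValueError("criterion must be 'auto' or a number of minutes")
        if self.bandwidth_km <= 0 or self.cell_km <= 0:
            raise ValueError("bandwidth and cell size must be positive")
        # stages that consume upstream artifacts need them enabled or on disk
        deps = {
            "simulate": (),
            "geolocate": ("simulate",),
            "activity": ("simulate",),
            "spatial": ("simulate", "geolocate"),
            "trends": ("simulate", "activity"),
        }
        for s in self.stages:
            missing = [n for n in deps[s] if n not in self.stages and not self._artifacts_exist(n)]
            if missing:
                raise ValueError(f"stage '{s}' needs artifacts from disabled stages {missing}")

    def _artifacts_exist(self, stage: str) -> bool:
        d = Path(self.out_dir)
        probe = {
            "simulate": d / "cohort.csv",
            "geolocate": d / "fixes.csv",
            "activity": d / "budgets.csv",
            "spatial": d / "segregation_tests.csv",
            "trends": d / "trend_curves.csv",
        }
        return probe[stage].exists()

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    child_seeds: dict
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    runtime_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of the reproducible manifest content (runtimes excluded)."""
        payload = json.dumps(
            {
                "config": self.config_hash,
                "seed": self.seed,
                "child_seeds": self.child_seeds,
                "counts": self.counts,
                "outputs": self.outputs,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def child_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds spawned from the global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31 - 1)) for s, c in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write the manifest."""
    config.validate()
    from importlib.metadata import version as _v

    try:
        pkg_version = _v("pelagis")
    except Exception:  # noqa: BLE001 - not installed
        pkg_version = "0+unknown"
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed)
    manifest = RunManifest(config.config_hash(), pkg_version, config.seed, seeds)

    runners = {
        "simulate": _stage_simulate,
        "geolocate": _stage_geolocate,
        "activity": _stage_activity,
        "spatial": _stage_spatial,
        "trends": _stage_trends,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            runners[stage](config, out, seeds[stage], manifest)
        except Exception as e:
            raise RuntimeError(f"stage '{stage}' failed: {e}") from e
        manifest.runtime_s[stage] = round(time.perf_counter() - t0, 2)
        logger.info("stage %s done in %.1f s", stage, manifest.runtime_s[stage])

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _sim_config(config: RunConfig, seed: int) -> sim.SimulationConfig:
    return sim.SimulationConfig(
        n_successful=config.n_successful,
        n_failed=config.n_failed,
        light_interval_min=config.light_interval_min,
        immersion_resolution_s=config.immersion_resolution_s,
        light_noise=config.light_noise,
        sun_angle=config.sun_angle,
        light_threshold=config.light_threshold,
        seed=seed,
    )


def _stage_simulate(config: RunConfig, out: Path, seed: int, manifest: RunManifest) -> None:
    sc = _sim_config(config, seed)
    records = sim.simulate_cohort(sc)
    fileio.write_cohort_csv(records, out / "cohort.csv")
    (out / "light").mkdir(exist_ok=True)
    (out / "immersion").mkdir(exist_ok=True)
    (out / "paths").mkdir(exist_ok=True)
    rng = np.random.SeedSequence(seed).spawn(len(records))
    n_events = 0
    for r, ss in zip(records, rng):
        s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3))
        path = sim.simulate_movement(r, sc, s1)
        behav = sim.simulate_behavior(path, r, sc, s2)
        light = sim.render_light(
            path, sc.light_interval_min, sc.light_noise, s3, sc.sun_angle, sc.light_threshold
        )
        imm = sim.render_immersion(behav, sc.immersion_resolution_s)
        fileio.write_path_csv(path, out / "paths" / f"{r.individual_id}.csv")
        fileio.write_light_csv(light, out / "light" / f"{r.individual_id}.csv")
        fileio.write_immersion_csv(imm, out / "immersion" / f"{r.individual_id}.csv")
        n_events += len(imm)
    moon = moon_fraction(pd.date_range(pd.Timestamp(sc.study_start), pd.Timestamp(sc.study_end)))
    fileio.write_moon_csv(moon, out / "moon.csv")
    manifest.counts["simulate"] = {"birds": len(records), "immersion_events": int(n_events)}
    manifest.outputs["simulate"] = ["cohort.csv", "light/", "immersion/", "paths/", "moon.csv"]


def _stage_geolocate(config: RunConfig, out: Path, seed: int, manifest: RunManifest) -> None:
    records = fileio.read_cohort_csv(out / "cohort.csv")
    all_fixes = []
    n_pairs = n_suspect = 0
    for r in records:
        series = fileio.read_light_csv(out / "light" / f"{r.individual_id}.csv", r.individual_id)
        pairs = geolocation.detect_twilights(series, config.light_threshold)
        n_pairs += len(pairs)
        n_suspect += sum(p.quality != "clean" for p in pairs)
        fixes = geolocation.derive_positions(pairs, config.sun_angle, r.individual_id)
        fixes = geolocation.filter_positions(
            fixes, window_days=config.equinox_window_days, max_speed_kmh=config.max_speed_kmh
        )
        all_fixes.extend(fixes)
    df = geolocation.fixes_to_frame(all_fixes)
    df.to_csv(out / "fixes.csv", index=False)
    fileio.write_fixes_geojson(df, out / "fixes.geojson")
    flagged = int((df["flags"] != "").sum())
    manifest.counts["geolocate"] = {
        "twilight_pairs": n_pairs,
        "interference_suspect_pairs": n_suspect,
        "fixes": len(df),
        "flagged_fixes": flagged,
    }
    manifest.outputs["geolocate"] = ["fixes.csv", "fixes.geojson"]


def _stage_activity(config: RunConfig, out: Path, seed: int, manifest: RunManifest) -> None:
    records = fileio.read_cohort_csv(out / "cohort.csv")
    moon = fileio.read_moon_csv(out / "moon.csv") if (out / "moon.csv").exists() else None
    bout_fits = []
    merged = {}
    n_dropped = 0
    for r in records:
        series = fileio.read_immersion_csv(out / "immersion" / f"{r.individual_id}.csv", r.individual_id)
        m = act.merge_short_events(series, config.merge_min)
        n_dropped += len(series) - len(m)
        merged[r.individual_id] = m
        if config.criterion == "auto":
            try:
                bout_fits.append(act.fit_bout_model(m.durations_s / 60.0, min_events=config.bout_fit_floor, seed=seed))
            except (act.DegenerateFitError, ValueError) as e:
                manifest.warnings.append(f"bout fit skipped for {r.individual_id}: {e}")
    if config.criterion == "auto":
        criterion = act.population_criterion(bout_fits) if bout_fits else act.STUDY_CRITERION_MIN
    else:
        criterion = float(config.criterion)

    events_frames, budget_frames, returns = [], [], []
    for r in records:
        light = fileio.read_light_csv(out / "light" / f"{r.individual_id}.csv", r.individual_id)
        twilights = geolocation.detect_twilights(light, config.light_threshold)
        events = act.classify_events(merged[r.individual_id], criterion, config.land_threshold_hr)
        budgets = act.compute_daily_budgets(events, twilights, r, moon)
        events_frames.append(events)
        budget_frames.append(budgets)
        ret = act.extract_return_date(events)
        returns.append({"individual_id": r.individual_id, "status": r.status, "sex": r.sex, "return_date": ret})
    events_df = pd.concat(events_frames, ignore_index=True)
    budgets_df = pd.concat(budget_frames, ignore_index=True)
    events_df.to_csv(out / "events.csv", index=False)
    budgets_df.to_csv(out / "budgets.csv", index=False)
    pd.DataFrame(returns).to_csv(out / "return_dates.csv", index=False)
    if config.make_figures:
        from . import plots

        plots.plot_dry_events(events_df, records, out / "dry_events.png", config.land_threshold_hr)
        manifest.outputs.setdefault("figures", []).append("dry_events.png")
    manifest.counts["activity"] = {
        "criterion_min": round(float(criterion), 2),
        "bout_fits": len(bout_fits),
        "merged_short_events": int(n_dropped),
        "events": len(events_df),
        "budget_rows": len(budgets_df),
        "returns_detected": int(sum(r["return_date"] is not None for r in returns)),
    }
    manifest.outputs["activity"] = ["events.csv", "budgets.csv", "return_dates.csv"]


def _month_points(df: pd.DataFrame, month: str, colony: tuple) -> dict:
    """Clean fixes of one calendar month projected about the colony.

    March and September are truncated to their first 10 days (the remainder
    falls in the equinox exclusion windows anyway).
    """
    ts = pd.to_datetime(df["timestamp"])
    sel = ts.dt.strftime("%Y-%m") == month
    if month.endswith("-03") or month.endswith("-09"):
        sel &= ts.dt.day <= 10
    sub = df[sel & (df["flags"].fillna("") == "") & df["lat"].notna()]
    return spatial.project_points(sub, colony, month=month)


def _stage_spatial(config: RunConfig, out: Path, seed: int, manifest: RunManifest) -> None:
    colony = sim.SimulationConfig().colony
    records = fileio.read_cohort_csv(out / "cohort.csv")
    status = {r.individual_id: r.status for r in records}
    sex = {r.individual_id: r.sex for r in records}
    df = pd.read_csv(out / "fixes.csv")
    df["flags"] = df.get("flags", "").fillna("")
    h = config.bandwidth_km * 1000.0
    cell = config.cell_km * 1000.0
    rng = np.random.SeedSequence(seed)
    rows = []
    for month in config.months:
        pts = _month_points(df, month, colony)
        pts = {k: v for k, v in pts.items() if len(v) >= spatial.MIN_POINTS_PER_UD}
        for labels, label_name in ((status, "breeding_performance"), (sex, "sex")):
            lab = {k: labels[k] for k in pts}
            counts = pd.Series(list(lab.values())).value_counts()
            if len(counts) < 2 or counts.min() < 2:
                manifest.warnings.append(f"segregation test skipped ({month}, {label_name}): group too small")
                continue
            for level in (0.50, 0.90):
                res = spatial.rotation_randomization_test(
                    pts,
                    lab,
                    n_iter=config.rotation_iters,
                    h=h,
                    cell=cell,
                    domain_level=level,
                    seed=int(rng.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)),
                )
                rows.append(
                    {
                        "month": month,
                        "grouping": label_name,
                        "ud_level": level,
                        "r_obs": res.r_obs,
                        "r_rand_mean": float(res.r_rand.mean()),
                        "r_rand_sd": float(res.r_rand.std()),
                        "p_value": res.p_value,
                        "n_iter": res.n_iter,
                        "n_birds": len(pts),
                    }
                )
    seg = pd.DataFrame(rows)
    seg.to_csv(out / "segregation_tests.csv", index=False)

    clean = df[(df["flags"] == "") & df["lat"].notna()]
    ts = pd.to_datetime(clean["timestamp"])
    in_window = (ts >= pd.Timestamp(config.distance_window[0])) & (ts <= pd.Timestamp(config.distance_window[1]))
    dist = spatial.distance_to_colony(clean[in_window].reset_index(drop=True), colony)
    dist_df = dist.rename_axis("individual_id").reset_index()
    dist_df["status"] = dist_df["individual_id"].map(status)
    dist_df["sex"] = dist_df["individual_id"].map(sex)
    dist_df.to_csv(out / "colony_distance.csv", index=False)
    dist_tests = []
    for factor in ("status", "sex"):
        res = spatial.bootstrap_group_difference(
            dist_df["mean_km"], dist_df[factor], n_iter=config.bootstrap_iters, seed=seed + 1
        )
        dist_tests.append({"factor": factor, **{k: v for k, v in res.items() if k != "groups"},
                           "group_a": res["groups"][0], "group_b": res["groups"][1]})
    pd.DataFrame(dist_tests).to_csv(out / "colony_distance_tests.csv", index=False)

    all_pts = spatial.project_points(clean, colony)
    all_pts = {k: v for k, v in all_pts.items() if len(v) >= spatial.MIN_POINTS_PER_UD}
    curve, pct = spatial.representativeness_bootstrap(
        all_pts, n_iter=config.representativeness_iters, h=h, cell=cell, seed=seed + 2
    )
    curve.to_csv(out / "representativeness_curve.csv", index=False)
    manifest.counts["spatial"] = {
        "segregation_tests": len(seg),
        "individuals_with_ud": len(all_pts),
        "representativeness_pct": None if pct is None else round(pct, 1),
    }
    manifest.outputs["spatial"] = [
        "segregation_tests.csv",
        "colony_distance.csv",
        "colony_distance_tests.csv",
        "representativeness_curve.csv",
    ]


def _stage_trends(config: RunConfig, out: Path, seed: int, manifest: RunManifest) -> None:
    records = fileio.read_cohort_csv(out / "cohort.csv")
    budgets = pd.read_csv(out / "budgets.csv", parse_dates=["date"])
    data = trends.build_dataset(budgets, records)
    curves, stats_rows, moon_rows = [], [], []
    for activity_name in config.trend_activities:
        for period in config.trend_periods:
            model = trends.ActivityTrendModel(
                data, activity=activity_name, period=period,
                include_individual_smooths=config.individual_smooths,
            )
            res = model.fit()
            days = np.linspace(model.x_range[0], model.x_range[1], 200)
            for st in model.statuses:
                c = res.predict_group_curve(st, days)
                c.insert(0, "activity", activity_name)
                c.insert(1, "period", period)
                c.insert(2, "status", st)
                curves.append(c)
            mc = res.predict_moon_curve(np.linspace(0, 29.53, 100))
            mc.insert(0, "activity", activity_name)
            mc.insert(1, "period", period)
            moon_rows.append(mc)
            t = res.test_smooth_terms()
            t.insert(0, "activity", activity_name)
            t.insert(1, "period", period)
            t["dispersion"] = res.dispersion
            stats_rows.append(t)
    curves_df = pd.concat(curves, ignore_index=True)
    moon_df = pd.concat(moon_rows, ignore_index=True)
    curves_df.to_csv(out / "trend_curves.csv", index=False)
    moon_df.to_csv(out / "moon_curves.csv", index=False)
    pd.concat(stats_rows, ignore_index=True).to_csv(out / "trend_terms.csv", index=False)
    if config.make_figures:
        from . import plots

        plots.plot_trend_curves(curves_df, out / "trend_curves.png")
        plots.plot_moon_curves(moon_df, out / "moon_curves.png")
        manifest.outputs.setdefault("figures", []).extend(["trend_curves.png", "moon_curves.png"])

    summary, tests = trends.window_comparison(
        budgets, records, config.window_a, config.window_b, n_iter=config.bootstrap_iters, seed=seed
    )
    summary.to_csv(out / "window_summary.csv", index=False)
    tests.to_csv(out / "window_tests.csv", index=False)
    manifest.counts["trends"] = {
        "dataset_rows": len(data),
        "models": len(config.trend_activities) * len(config.trend_periods),
        "window_tests": len(tests),
    }
    manifest.outputs["trends"] = [
        "trend_curves.csv",
        "moon_curves.csv",
        "trend_terms.csv",
        "window_summary.csv",
        "window_tests.csv",
    ]
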