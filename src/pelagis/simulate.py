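"""Synthetic cohorts of resident central-place foragers and their logger channels.

The generator emulates a year-round geolocator deployment on a colony of
albatross-like seabirds that stay within a few hundred km of the colony all
year: breeding metadata (laying/hatching/failure dates, sex, status), movement
as a mean-reverting (Ornstein–Uhlenbeck) walk in a local planar frame centred
on the colony with forced colony attendance during breeding shifts, behaviour
as a semi-Markov sequence with exponential sojourns whose parameters depend on
breeding stage and light period, and the two logger channels rendered forward
from those ground truths: maximum light level every 5–10 min via the shared
solar-geometry routine, and wet/dry immersion at 3-s resolution.

Exponential sojourn times make the downstream bout-criterion mixture model
exactly well-specified, so parameter-recovery tests have closed-form targets;
the shared solar model makes the light round trip a near-exact oracle for the
geolocation solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .activity import ImmersionSeries, StageCalendar
from .geo import azimuthal_equidistant_inverse
from .geolocation import LIGHT_MAX, LightSeries
from .moon import moon_fraction  # re-exported: the generator owns the moon table
from .solar import solar_elevation

__all__ = [
    "SimulationConfig",
    "BreedingRecord",
    "TruePath",
    "BehaviorSequence",
    "StateRates",
    "simulate_cohort",
    "simulate_movement",
    "simulate_behavior",
    "render_light",
    "render_immersion",
    "moon_fraction",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class StateRates:
    """At-sea macro-state mix and mean sojourns (minutes) for one stage x period."""

    p_forage: float
    p_flight: float
    p_float: float
    forage_mean: float  # mean duration of a foraging bout (rapid wet/dry switching)
    flight_mean: float
    float_mean: float

    def probs(self) -> np.ndarray:
        p = np.array([self.p_forage, self.p_flight, self.p_float], dtype=float)
        return p / p.sum()


def _default_rates() -> dict:
    """Stage x light-period behaviour rates.

    Breeding birds are more active (commuting flight, intensive foraging);
    rearing adds extra foraging effort; the nonbreeding season shifts time into
    floating, especially in darkness.  Values are field-plausible means chosen
    once for the study conditions; they are configuration, not fitted numbers.
    """
    return {
        ("incubation", "daylight"): StateRates(0.35, 0.40, 0.25, 45.0, 120.0, 90.0),
        ("incubation", "darkness"): StateRates(0.20, 0.25, 0.55, 30.0, 80.0, 180.0),
        ("hatching", "daylight"): StateRates(0.35, 0.40, 0.25, 45.0, 120.0, 90.0),
        ("hatching", "darkness"): StateRates(0.20, 0.25, 0.55, 30.0, 80.0, 180.0),
        ("brooding", "daylight"): StateRates(0.40, 0.40, 0.20, 50.0, 130.0, 80.0),
        ("brooding", "darkness"): StateRates(0.22, 0.23, 0.55, 30.0, 80.0, 170.0),
        ("rearing", "daylight"): StateRates(0.50, 0.32, 0.18, 55.0, 110.0, 80.0),
        ("rearing", "darkness"): StateRates(0.30, 0.20, 0.50, 35.0, 70.0, 160.0),
        ("nonbreeding", "daylight"): StateRates(0.30, 0.30, 0.40, 40.0, 100.0, 140.0),
        ("nonbreeding", "darkness"): StateRates(0.15, 0.15, 0.70, 25.0, 60.0, 220.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the kind of 2012/13 Falkland Islands deployment the
    analysis chain targets: 48 successful + 12 failed breeders, mean laying
    11 Oct 2012 (SD 2 d), hatching mid-December after a 68-day incubation,
    stage calendar to 5 Sep 2013, colony at 51.85 S 61.30 W.
    """

    n_successful: int = 48
    n_failed: int = 12
    colony: tuple = (-51.85, -61.30)  # (lat, lon) degrees
    study_start: np.datetime64 = np.datetime64("2012-10-20")
    study_end: np.datetime64 = np.datetime64("2013-10-05")
    mean_laying_date: np.datetime64 = np.datetime64("2012-10-11")
    laying_sd_days: float = 2.0
    incubation_days: int = 68
    calendar: StageCalendar = field(default_factory=StageCalendar)
    mean_failure_date: np.datetime64 = np.datetime64("2012-12-26")
    failure_sd_days: float = 29.0
    female_fraction_successful: float = 22.0 / 48.0
    female_fraction_failed: float = 0.5
    # movement
    home_range_km: float = 500.0
    trip_range_km: float = 250.0  # ranging scale while still attending the colony
    step_minutes: float = 30.0
    ou_timescale_days: float = 5.0
    max_speed_kmh: float = 80.0
    # colony attendance: per-day probability that a shift starts, and mean shift hours
    attendance_prob: dict = field(
        default_factory=lambda: {
            "incubation": 0.50,
            "hatching": 0.60,
            "brooding": 0.60,
            "rearing": 0.12,
            "nonbreeding": 0.0,
            "return": 0.35,
        }
    )
    shift_hours: dict = field(
        default_factory=lambda: {
            "incubation": 36.0,
            "hatching": 22.0,
            "brooding": 20.0,
            "rearing": 20.0,
            "return": 24.0,
        }
    )
    # return to the colony at the end of the nonbreeding season: (mean date, SD days)
    return_date_by_group: dict = field(
        default_factory=lambda: {
            ("failed", "male"): (np.datetime64("2013-08-27"), 9.0),
            ("failed", "female"): (np.datetime64("2013-09-12"), 12.0),
            ("successful", "male"): (np.datetime64("2013-09-07"), 10.0),
            ("successful", "female"): (np.datetime64("2013-09-16"), 12.0),
        }
    )
    # behaviour
    behavior_rates: dict = field(default_factory=_default_rates)
    forage_wet_mean_min: float = 4.0
    forage_dry_mean_min: float = 2.5
    moon_activity_effect: float = 0.5  # night forage/flight odds scaling over the lunar cycle
    # at sea a bird settles on the water within this long at the latest, so dry
    # events longer than the on-land threshold can only arise at the nest
    max_sea_dry_hours: float = 10.0
    # loggers
    light_interval_min: float = 10.0
    immersion_resolution_s: float = 3.0
    light_noise: float = 0.0
    sun_angle: float = -3.5
    light_threshold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_successful <= 0 or self.n_failed < 0:
            raise ConfigurationError("need n_successful > 0 and n_failed >= 0")
        if not (np.datetime64(self.mean_laying_date) < self.calendar.hatching_start):
            raise ConfigurationError("mean laying date must precede the hatching window")
        if not np.datetime64(self.study_start) < np.datetime64(self.study_end):
            raise ConfigurationError("study_start must precede study_end")
        for (stage, period), r in self.behavior_rates.items():
            if min(r.flight_mean, r.float_mean) <= max(self.forage_wet_mean_min, self.forage_dry_mean_min):
                raise ConfigurationError(
                    f"flight/float means must exceed foraging-phase means ({stage}, {period})"
                )
        for stage in ("incubation", "brooding"):
            if self.shift_hours[stage] <= 16.0:
                raise ConfigurationError("breeding attendance shifts must average > 16 hr")
        if self.light_interval_min not in (5.0, 10.0):
            logger.warning("unusual light interval %.1f min (tags record every 5 or 10 min)", self.light_interval_min)
        if not 0.0 <= self.light_noise <= 1.0:
            raise ConfigurationError("light_noise must be a probability")


@dataclass
class BreedingRecord:
    individual_id: str
    sex: str  # "male" | "female"
    status: str  # "successful" | "failed"
    laying_date: np.datetime64
    hatching_date: np.datetime64 | None = None
    failure_date: np.datetime64 | None = None
    return_date: np.datetime64 | None = None  # ground truth for round-trip tests

    def __post_init__(self) -> None:
        if self.status == "failed":
            if self.failure_date is None or self.failure_date < self.laying_date:
                raise ValueError("failed birds need a failure date on/after laying")
        elif self.failure_date is not None:
            raise ValueError("successful birds must not carry a failure date")


@dataclass
class TruePath:
    """Ground-truth movement track in the study window."""

    individual_id: str
    times: np.ndarray  # datetime64[s]
    lat: np.ndarray
    lon: np.ndarray
    colony: tuple
    colony_windows: list  # realized (start, end) datetime64 pairs at the colony

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BehaviorSequence:
    """Contiguous behaviour events (state, start offset, duration)."""

    individual_id: str
    origin: np.datetime64
    states: np.ndarray  # foraging-wet/foraging-dry/flight/float/land
    offsets_s: np.ndarray  # event start, seconds since origin
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        if len(self.states) and not np.allclose(
            self.offsets_s[1:], self.offsets_s[:-1] + self.durations_s[:-1], atol=1e-6
        ):
            raise ValueError("behaviour events must be contiguous")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def starts(self) -> np.ndarray:
        return self.origin.astype("datetime64[s]") + np.round(self.offsets_s).astype("timedelta64[s]")

    @property
    def total_seconds(self) -> float:
        return float(self.durations_s.sum())


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> list[BreedingRecord]:
    """Draw breeding records for the configured cohort (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[BreedingRecord] = []
    mean_laying = np.datetime64(config.mean_laying_date, "D")
    rearing_end = config.calendar.rearing_end

    def draw_group(n: int, status: str, female_fraction: float, offset: int) -> None:
        n_female = int(round(n * female_fraction))
        sexes = np.array(["female"] * n_female + ["male"] * (n - n_female), dtype=object)
        rng.shuffle(sexes)
        for j in range(n):
            lay = mean_laying + np.timedelta64(int(round(rng.normal(0.0, config.laying_sd_days))), "D")
            hatch = lay + np.timedelta64(config.incubation_days, "D")
            fail = None
            if status == "failed":
                lo = (lay + np.timedelta64(5, "D") - np.datetime64(config.mean_failure_date)).astype(int)
                hi = (rearing_end - np.datetime64(config.mean_failure_date)).astype(int)
                dev = np.clip(rng.normal(0.0, config.failure_sd_days), lo, hi)
                fail = np.datetime64(config.mean_failure_date) + np.timedelta64(int(round(dev)), "D")
                hatch = hatch if fail >= hatch else None
            sex = sexes[j]
            mean_ret, sd_ret = config.return_date_by_group[(status, str(sex))]
            ret = np.datetime64(mean_ret, "D") + np.timedelta64(int(round(rng.normal(0.0, sd_ret))), "D")
            ret = min(max(ret, config.calendar.rearing_end + np.timedelta64(30, "D")), np.datetime64(config.study_end, "D"))
            records.append(
                BreedingRecord(
                    individual_id=f"bird{offset + j:03d}",
                    sex=str(sex),
                    status=status,
                    laying_date=lay,
                    hatching_date=hatch,
                    failure_date=fail,
                    return_date=ret,
                )
            )

    draw_group(config.n_successful, "successful", config.female_fraction_successful, 0)
    draw_group(config.n_failed, "failed", config.female_fraction_failed, config.n_successful)
    return records


def cohort_to_frame(records: list[BreedingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "sex": [r.sex for r in records],
            "status": [r.status for r in records],
            "laying_date": [pd.Timestamp(r.laying_date) for r in records],
            "hatching_date": [pd.Timestamp(r.hatching_date) if r.hatching_date is not None else pd.NaT for r in records],
            "failure_date": [pd.Timestamp(r.failure_date) if r.failure_date is not None else pd.NaT for r in records],
            "return_date": [pd.Timestamp(r.return_date) if r.return_date is not None else pd.NaT for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Attendance schedule and movement
# ---------------------------------------------------------------------------


def _attendance_stage(record: BreedingRecord, config: SimulationConfig, day: np.datetime64) -> str | None:
    """Stage key governing colony attendance on ``day`` (None = no attendance)."""
    cal = config.calendar
    if record.failure_date is not None and day >= record.failure_date:
        attending = False
    else:
        attending = day < cal.rearing_end
    if attending:
        return cal.stage_of(day) if cal.stage_of(day) != "nonbreeding" else None
    if record.return_date is not None and day >= record.return_date:
        return "return"
    return None


def _schedule_attendance(record: BreedingRecord, config: SimulationConfig, rng) -> list:
    """Scheduled colony shifts as (start, end) datetime64[s] pairs."""
    day = np.datetime64(config.study_start, "D")
    end = np.datetime64(config.study_end, "D")
    windows = []
    busy_until = np.datetime64(config.study_start, "s")
    while day < end:
        stage = _attendance_stage(record, config, day)
        if stage is not None and rng.random() < config.attendance_prob.get(stage, 0.0):
            start = day.astype("datetime64[s]") + np.timedelta64(int(rng.integers(0, 86400)), "s")
            if start >= busy_until:
                dur_h = max(rng.exponential(config.shift_hours[stage]), 2.0)
                stop = start + np.timedelta64(int(dur_h * 3600), "s")
                stop = min(stop, end.astype("datetime64[s]"))
                # a failed bird abandons at failure even mid-shift
                if record.failure_date is not None and day < record.failure_date:
                    stop = min(stop, np.datetime64(record.failure_date, "s"))
                if stop > start:
                    windows.append((start, stop))
                    busy_until = stop
        day += np.timedelta64(1, "D")
    return windows


def simulate_movement(record: BreedingRecord, config: SimulationConfig, seed: int) -> TruePath:
    """Mean-reverting central-place movement with forced colony attendance.

    Between colony shifts the bird follows a discretized Ornstein–Uhlenbeck
    walk around the colony (stationary per-axis SD = scale/sqrt(pi/2), so the
    long-run mean colony distance equals the configured range scale); ahead of
    each scheduled shift it homes in a straight line at bounded speed, sits at
    the colony for the shift, and resumes ranging afterwards.  Step lengths are
    clipped so implied speed never exceeds the configured maximum.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    windows = _schedule_attendance(record, config, rng)
    dt_s = config.step_minutes * 60.0
    t0 = np.datetime64(config.study_start, "s")
    t1 = np.datetime64(config.study_end, "s")
    n = int((t1 - t0) / np.timedelta64(int(dt_s), "s")) + 1
    times = t0 + (np.arange(n) * dt_s).astype("timedelta64[s]")

    theta = 1.0 / (config.ou_timescale_days * 86400.0)  # 1/s
    decay = np.exp(-theta * dt_s)
    sd_free = config.home_range_km / np.sqrt(np.pi / 2.0)
    sd_trip = config.trip_range_km / np.sqrt(np.pi / 2.0)
    max_step = config.max_speed_kmh * dt_s / 3600.0  # km per step
    v_home = 0.9 * config.max_speed_kmh

    rearing_end_s = config.calendar.rearing_end.astype("datetime64[s]")
    fail_s = np.datetime64(record.failure_date, "s") if record.failure_date is not None else None

    pos = np.zeros((n, 2))
    noise = rng.standard_normal((n, 2))
    wi = 0
    for k in range(1, n):
        t = times[k]
        while wi < len(windows) and t >= windows[wi][1]:
            wi += 1
        p = pos[k - 1]
        dist = float(np.hypot(p[0], p[1]))
        in_window = wi < len(windows) and windows[wi][0] <= t < windows[wi][1]
        hours_to_next = (
            (windows[wi][0] - t) / np.timedelta64(3600, "s") if wi < len(windows) else np.inf
        )
        must_home = in_window or (dist / v_home >= hours_to_next)
        if must_home:
            if dist <= max_step:
                pos[k] = 0.0
            else:
                pos[k] = p * (1.0 - max_step / dist)
            continue
        attending_phase = (t < rearing_end_s) and (fail_s is None or t < fail_s)
        sd = sd_trip if attending_phase else sd_free
        step_sd = sd * np.sqrt(max(1.0 - decay**2, 0.0))
        prop = p * decay + step_sd * noise[k]
        d = prop - p
        norm = float(np.hypot(d[0], d[1]))
        if norm > max_step:
            prop = p + d * (max_step / norm)
        pos[k] = prop

    at_colony = (np.abs(pos[:, 0]) < 1e-9) & (np.abs(pos[:, 1]) < 1e-9)
    colony_windows = []
    k = 0
    while k < n:
        if at_colony[k]:
            j = k
            while j + 1 < n and at_colony[j + 1]:
                j += 1
            if j > k:  # at least one full step on land
                colony_windows.append((times[k], times[j]))
            k = j + 1
        else:
            k += 1

    lat, lon = azimuthal_equidistant_inverse(pos[:, 0] * 1000.0, pos[:, 1] * 1000.0, *config.colony)
    return TruePath(record.individual_id, times, lat, lon, config.colony, colony_windows)


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------


def _daylight_lookup(config: SimulationConfig, grid_min: float = 5.0):
    """Boolean day/night lookup at the colony on a fixed time grid."""
    t0 = np.datetime64(config.study_start, "s")
    t1 = np.datetime64(config.study_end, "s")
    step = np.timedelta64(int(grid_min * 60), "s")
    grid = np.arange(t0, t1 + step, step)
    elev = solar_elevation(grid, config.colony[0], config.colony[1])
    is_day = elev > config.sun_angle

    def lookup(offset_s: float) -> bool:
        i = int(offset_s // (grid_min * 60.0))
        return bool(is_day[min(max(i, 0), len(is_day) - 1)])

    return lookup


def _behavior_stage(record: BreedingRecord, config: SimulationConfig, day: np.datetime64) -> str:
    """Stage governing at-sea behaviour rates (failure switches to nonbreeding)."""
    if record.failure_date is not None and day >= np.datetime64(record.failure_date, "D"):
        return "nonbreeding"
    return config.calendar.stage_of(day)


def simulate_behavior(
    path: TruePath, record: BreedingRecord, config: SimulationConfig, seed: int
) -> BehaviorSequence:
    """Semi-Markov behaviour sequence consistent with the movement path.

    On-land events exactly fill the path's realized colony windows; at sea the
    bird alternates foraging bouts (rapid wet/dry switching with short
    exponential phases), sustained flight and floating, with stage- and
    light-period-specific state probabilities and mean durations.  At night the
    odds of active states scale with the moon's illuminated fraction.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    origin = path.times[0]
    end_s = float((path.times[-1] - origin) / np.timedelta64(1, "s"))
    windows_s = [
        (float((a - origin) / np.timedelta64(1, "s")), float((b - origin) / np.timedelta64(1, "s")))
        for (a, b) in path.colony_windows
    ]
    is_day = _daylight_lookup(config)
    moon = moon_fraction(pd.date_range(pd.Timestamp(config.study_start), pd.Timestamp(config.study_end)))
    moon_by_day = moon.to_numpy()
    day0 = np.datetime64(config.study_start, "D")

    states: list[str] = []
    offs: list[float] = []
    durs: list[float] = []

    def emit(state: str, start: float, dur: float) -> None:
        if dur <= 0:
            return
        states.append(state)
        offs.append(start)
        durs.append(dur)

    max_dry_s = config.max_sea_dry_hours * 3600.0
    wet_reset_s = 180.0  # a wet phase this long survives the short-event merge

    def emit_sea(t: float, stop: float) -> None:
        """Fill [t, stop) with at-sea behaviour."""
        dry_run = 0.0
        while t < stop - 1e-9:
            day = (origin + np.timedelta64(int(t), "s")).astype("datetime64[D]")
            stage = _behavior_stage(record, config, day)
            period = "daylight" if is_day(t) else "darkness"
            rates = config.behavior_rates[(stage, period)]
            probs = rates.probs()
            if period == "darkness" and config.moon_activity_effect:
                frac = moon_by_day[min(max(int((day - day0).astype(int)), 0), len(moon_by_day) - 1)]
                gain = 1.0 + config.moon_activity_effect * (2.0 * frac - 1.0)
                probs = probs * np.array([gain, gain, 1.0])
                probs = probs / probs.sum()
            macro = rng.choice(3, p=probs)
            dry_budget = max_dry_s - dry_run
            if dry_budget <= 0:  # must settle on the water
                macro = 2
            if macro == 0:  # foraging bout: rapid wet/dry alternation
                bout = min(rng.exponential(rates.forage_mean * 60.0), stop - t, max(dry_budget, 60.0))
                bt = t
                wet = bool(rng.random() < 0.5)
                while bt < t + bout - 1e-9:
                    mean = config.forage_wet_mean_min if wet else config.forage_dry_mean_min
                    d = min(rng.exponential(mean * 60.0), t + bout - bt)
                    emit("foraging-wet" if wet else "foraging-dry", bt, d)
                    if wet and d >= wet_reset_s:
                        dry_run = 0.0
                    else:
                        dry_run += d
                    bt += d
                    wet = not wet
                t += bout
            else:
                state = "flight" if macro == 1 else "float"
                mean = rates.flight_mean if macro == 1 else rates.float_mean
                d = min(rng.exponential(mean * 60.0), stop - t)
                if state == "flight":
                    d = min(d, max(dry_budget, 60.0))
                emit(state, t, d)
                if state == "float" and d >= wet_reset_s:
                    dry_run = 0.0
                else:
                    dry_run += d
                t += d

    t = 0.0
    for a, b in windows_s:
        if a > t:
            emit_sea(t, a)
        emit("land", max(a, t), b - max(a, t))
        t = max(b, t)
    if t < end_s:
        emit_sea(t, end_s)

    return BehaviorSequence(
        individual_id=record.individual_id,
        origin=origin,
        states=np.array(states, dtype=object),
        offsets_s=np.array(offs),
        durations_s=np.array(durs),
    )


# ---------------------------------------------------------------------------
# Logger channels
# ---------------------------------------------------------------------------


def light_from_elevation(elevation_deg, sun_angle: float = -3.5, threshold: float = 10.0, steepness: float = 1.2):
    """Saturating monotone map from solar elevation to the 0–64 tag light scale.

    Logistic in elevation, anchored so the curve passes through ``threshold``
    exactly at ``sun_angle`` — the calibration convention of threshold
    geolocation.
    """
    e_mid = sun_angle - float(logit(threshold / LIGHT_MAX)) / steepness
    return LIGHT_MAX * expit(steepness * (np.asarray(elevation_deg, dtype=float) - e_mid))


def render_light(
    path: TruePath,
    light_interval_min: float = 10.0,
    noise: float = 0.0,
    seed: int = 0,
    sun_angle: float = -3.5,
    threshold: float = 10.0,
) -> LightSeries:
    """Forward-render the light channel along a true path.

    One integer sample per interval; light is a logistic function of solar
    elevation at the (linearly interpolated) true position, clipped to [0, 64].
    With ``noise`` > 0, that fraction of twilight-adjacent samples is replaced
    by low values, mimicking shading interference at dawn/dusk.
    """
    rng = np.random.default_rng(seed)
    step = np.timedelta64(int(light_interval_min * 60), "s")
    times = np.arange(path.times[0], path.times[-1] + step, step)
    tt = (times - path.times[0]) / np.timedelta64(1, "s")
    pt = (path.times - path.times[0]) / np.timedelta64(1, "s")
    lat = np.interp(tt, pt, path.lat)
    lon = np.interp(tt, pt, path.lon)
    elev = solar_elevation(times, lat, lon)
    light = light_from_elevation(elev, sun_angle=sun_angle, threshold=threshold)
    light = np.clip(np.rint(light), 0, LIGHT_MAX).astype(int)
    if noise > 0:
        twilight = (elev > -12.0) & (elev < 12.0)
        hit = twilight & (rng.random(len(light)) < noise)
        light[hit] = rng.integers(0, 6, size=int(hit.sum()))
    return LightSeries(path.individual_id, times, light, light_interval_min)


_WET_STATES = {"foraging-wet", "float"}


def render_immersion(behavior: BehaviorSequence, resolution_s: float = 3.0) -> ImmersionSeries:
    """Collapse behaviour to the wet/dry immersion channel.

    Foraging-wet and floating are wet; foraging-dry, flight and land are dry.
    Consecutive same-state events merge; durations are quantized to the sensor
    resolution (nearest multiple, minimum one quantum), conserving each event's
    duration to within one quantum.
    """
    if len(behavior) == 0:
        return ImmersionSeries(behavior.individual_id, np.array([], dtype=object), np.array([], dtype="datetime64[s]"), np.array([]))
    wd = np.where(np.isin(behavior.states.astype(str), list(_WET_STATES)), "wet", "dry")
    # merge consecutive same-state runs
    new_run = np.concatenate([[True], wd[1:] != wd[:-1]])
    run_ids = np.cumsum(new_run) - 1
    n_runs = run_ids[-1] + 1
    dur = np.zeros(n_runs)
    np.add.at(dur, run_ids, behavior.durations_s)
    run_states = wd[new_run]
    dur_q = np.maximum(np.rint(dur / resolution_s), 1.0) * resolution_s
    offsets = np.concatenate([[0.0], np.cumsum(dur_q)[:-1]])
    starts = behavior.origin.astype("datetime64[s]") + np.round(behavior.offsets_s[0] + offsets).astype("timedelta64[s]")
    return ImmersionSeries(behavior.individual_id, run_states.astype(object), starts, dur_q)
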