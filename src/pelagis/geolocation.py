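"""Threshold light-level geolocation.

Positions are estimated twice daily from archival-tag light curves: the time the
light record crosses a fixed threshold (default 10 on the 0–64 tag scale) marks
dawn and dusk; longitude follows from the midpoint of the two (local apparent
noon/midnight), and latitude from day (or night) length given the calibrated sun
elevation angle of the tag.  Interference in the light curve is screened by
segment-length checks at twilight detection and by an iterative speed filter,
and fixes near the equinoxes — when day length carries no latitude information —
are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geo import haversine_km, normalize_longitude
from .solar import equation_of_time, solar_declination

logger = logging.getLogger(__name__)

LIGHT_MAX = 64
DEFAULT_THRESHOLD = 10.0
DEFAULT_SUN_ANGLE = -3.5  # degrees below horizon at threshold crossing
EQUINOX_WINDOW_DAYS = 10
DEFAULT_MAX_SPEED_KMH = 85.0


@dataclass
class LightSeries:
    """Raw light channel of one individual: max light level per sampling interval."""

    individual_id: str
    times: np.ndarray  # datetime64[s], strictly increasing
    light: np.ndarray  # integers in [0, 64]
    interval_min: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.light = np.asarray(self.light)
        if self.times.shape != self.light.shape:
            raise ValueError("times and light must have equal length")
        if len(self.times) and not (np.diff(self.times) > np.timedelta64(0, "s")).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(self.light) and (self.light.min() < 0 or self.light.max() > LIGHT_MAX):
            raise ValueError(f"light levels must lie in [0, {LIGHT_MAX}]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "light": self.light})


@dataclass
class TwilightPair:
    """One dawn–dusk pair bounding a lit period."""

    date: np.datetime64  # date of the local noon (UTC calendar date of midpoint)
    dawn: np.datetime64
    dusk: np.datetime64
    quality: str = "clean"  # "clean" | "interference-suspect"


@dataclass
class GeoFix:
    """A twice-daily position estimate with quality flags."""

    individual_id: str
    time: np.datetime64
    lat: float  # NaN when latitude indeterminate
    lon: float
    fix_type: str  # "noon" | "midnight"
    flags: set = field(default_factory=set)


def _crossings(times: np.ndarray, light: np.ndarray, threshold: float):
    """Interpolated threshold crossing times and directions (+1 up, -1 down)."""
    above = light >= threshold
    idx = np.nonzero(above[1:] != above[:-1])[0]
    if len(idx) == 0:
        return np.array([], dtype="datetime64[s]"), np.array([], dtype=int)
    l0 = light[idx].astype(float)
    l1 = light[idx + 1].astype(float)
    frac = (threshold - l0) / (l1 - l0)
    dt = (times[idx + 1] - times[idx]) / np.timedelta64(1, "s")
    t = times[idx] + (frac * dt).astype("timedelta64[s]")
    direction = np.where(above[idx + 1], 1, -1)
    return t, direction


def detect_twilights(
    series: LightSeries,
    threshold: float = DEFAULT_THRESHOLD,
    min_segment_min: float = 120.0,
) -> list[TwilightPair]:
    """Detect dawn/dusk threshold crossings in a light series.

    Dawn is the linearly interpolated time of an upward crossing of ``threshold``
    and dusk of the following downward crossing.  Light (or dark) segments
    shorter than ``min_segment_min`` indicate interference (e.g. shading at the
    nest); the crossings bounding them are cancelled pairwise and the pairs of
    the affected span are flagged ``interference-suspect`` so they are excluded
    from position derivation.
    """
    if len(series.times) == 0:
        raise ValueError("empty light series")
    t, direction = _crossings(series.times, series.light.astype(float), threshold)
    if len(t) == 0:
        logger.warning("no threshold crossings for %s (constant light)", series.individual_id)
        return []

    keep = np.ones(len(t), dtype=bool)
    suspect_times: list[np.datetime64] = []
    # iteratively cancel crossing pairs bounding short segments
    changed = True
    while changed:
        changed = False
        live = np.nonzero(keep)[0]
        for a, b in zip(live[:-1], live[1:]):
            seg_min = (t[b] - t[a]) / np.timedelta64(60, "s")
            if seg_min < min_segment_min:
                keep[a] = keep[b] = False
                suspect_times.extend([t[a], t[b]])
                changed = True
                break

    t = t[keep]
    direction = direction[keep]
    pairs: list[TwilightPair] = []
    suspect = np.array(suspect_times, dtype="datetime64[s]") if suspect_times else None
    for i in range(len(t) - 1):
        if direction[i] == 1 and direction[i + 1] == -1:
            dawn, dusk = t[i], t[i + 1]
            mid = dawn + (dusk - dawn) // 2
            quality = "clean"
            pad = np.timedelta64(6, "h")
            if suspect is not None and ((suspect >= dawn - pad) & (suspect <= dusk + pad)).any():
                quality = "interference-suspect"
            day_h = (dusk - dawn) / np.timedelta64(3600, "s")
            if not (1.0 <= day_h <= 23.0):
                quality = "interference-suspect"
            pairs.append(TwilightPair(date=mid.astype("datetime64[D]"), dawn=dawn, dusk=dusk, quality=quality))
    return pairs


def estimate_longitude(pair: TwilightPair) -> float:
    """Longitude from the midpoint of dawn and dusk (local apparent noon)."""
    if pair.dusk <= pair.dawn:
        raise ValueError("dusk must follow dawn")
    noon = pair.dawn + (pair.dusk - pair.dawn) // 2
    return _longitude_at(noon, apparent_hour=12.0)


def _longitude_at(instant: np.datetime64, apparent_hour: float) -> float:
    """Longitude at which local apparent time equals ``apparent_hour`` at ``instant``."""
    day = instant.astype("datetime64[D]")
    utc_h = (instant - day) / np.timedelta64(3600, "s")
    eot_h = float(equation_of_time(instant)) / 60.0
    return float(normalize_longitude(15.0 * (apparent_hour - utc_h - eot_h)))


def estimate_latitude(
    half_arc_deg: float,
    date,
    sun_angle: float = DEFAULT_SUN_ANGLE,
    prev_lat: float | None = None,
    hemisphere: str = "south",
    equinox_decl_deg: float = 1.5,
) -> tuple[float, set]:
    """Latitude from the sun's half-arc (hour angle at the threshold crossing).

    Solves sin(a) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(omega0) for phi
    by bracketed root finding on [-89, 89] degrees.  ``half_arc_deg`` is half the
    day length expressed as an hour angle (7.5 deg per hour); for midnight fixes
    pass 180 minus half the night arc.  When two roots exist the one nearer
    ``prev_lat`` is chosen (fallback: the configured hemisphere).  Near the
    equinox (|delta| below ``equinox_decl_deg``) latitude is unidentifiable and
    the fix is flagged indeterminate.
    """
    flags: set = set()
    delta = float(solar_declination(np.datetime64(date, "s")))
    if abs(delta) < equinox_decl_deg:
        return float("nan"), {"latitude-indeterminate"}
    d, a, w = np.deg2rad(delta), np.deg2rad(sun_angle), np.deg2rad(half_arc_deg)

    def f(phi_deg: float) -> float:
        p = np.deg2rad(phi_deg)
        return np.sin(p) * np.sin(d) + np.cos(p) * np.cos(d) * np.cos(w) - np.sin(a)

    grid = np.linspace(-89.0, 89.0, 179)
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1]))
    if not roots:
        return float("nan"), {"latitude-indeterminate"}
    if len(roots) == 1:
        return float(roots[0]), flags
    if prev_lat is not None and np.isfinite(prev_lat):
        return float(min(roots, key=lambda r: abs(r - prev_lat))), flags
    if hemisphere == "south":
        south = [r for r in roots if r < 0]
        return float(south[0] if south else min(roots)), flags
    north = [r for r in roots if r > 0]
    return float(north[0] if north else max(roots)), flags


def derive_positions(
    pairs: list[TwilightPair],
    sun_angle: float = DEFAULT_SUN_ANGLE,
    individual_id: str = "",
    hemisphere: str = "south",
) -> list[GeoFix]:
    """Noon and midnight fixes from consecutive twilight pairs.

    Each clean dawn–dusk pair yields a noon fix (longitude from the midpoint,
    latitude from day length); each dusk–next-dawn interval shorter than ~30 h
    yields a midnight fix from night length, dated by the earlier day.
    """
    clean = [p for p in pairs if p.quality == "clean"]
    fixes: list[GeoFix] = []
    prev_lat: float | None = None
    for i, p in enumerate(clean):
        noon = p.dawn + (p.dusk - p.dawn) // 2
        lon = estimate_longitude(p)
        day_h = (p.dusk - p.dawn) / np.timedelta64(3600, "s")
        lat, flags = estimate_latitude(day_h / 2.0 * 15.0, noon, sun_angle, prev_lat, hemisphere)
        if np.isfinite(lat):
            prev_lat = lat
        fixes.append(GeoFix(individual_id, noon, lat, lon, "noon", flags))
        if i + 1 < len(clean):
            nxt = clean[i + 1]
            night_h = (nxt.dawn - p.dusk) / np.timedelta64(3600, "s")
            if 0 < night_h <= 30.0:
                midnight = p.dusk + (nxt.dawn - p.dusk) // 2
                lon_m = _longitude_at(midnight, apparent_hour=24.0)
                lat_m, flags_m = estimate_latitude(
                    180.0 - night_h / 2.0 * 15.0, midnight, sun_angle, prev_lat, hemisphere
                )
                if np.isfinite(lat_m):
                    prev_lat = lat_m
                fixes.append(GeoFix(individual_id, midnight, lat_m, lon_m, "midnight", flags_m))
    fixes.sort(key=lambda g: g.time)
    return fixes


def default_equinox_dates(years) -> list[np.datetime64]:
    """20 March and 22 September for each year."""
    out = []
    for y in sorted(set(int(y) for y in years)):
        out.append(np.datetime64(f"{y}-03-20"))
        out.append(np.datetime64(f"{y}-09-22"))
    return out


def filter_positions(
    fixes: list[GeoFix],
    equinox_dates=None,
    window_days: int = EQUINOX_WINDOW_DAYS,
    max_speed_kmh: float = DEFAULT_MAX_SPEED_KMH,
) -> list[GeoFix]:
    """Flag equinox-window and speed-implausible fixes (annotation only, no deletion).

    A fix is speed-rejected when the great-circle speed to both the previous and
    the next currently-accepted neighbour exceeds ``max_speed_kmh``; the filter
    iterates until stable.
    """
    if not fixes:
        return fixes
    if equinox_dates is None:
        years = {t.astype("datetime64[Y]").astype(int) + 1970 for t in (f.time for f in fixes)}
        equinox_dates = default_equinox_dates(years)
    window = np.timedelta64(window_days, "D")
    for f in fixes:
        d = f.time.astype("datetime64[D]")
        if any(abs(d - e.astype("datetime64[D]")) <= window for e in equinox_dates):
            f.flags.add("equinox-excluded")

    def usable(f: GeoFix) -> bool:
        return np.isfinite(f.lat) and "speed-rejected" not in f.flags

    changed = True
    while changed:
        changed = False
        live = [f for f in fixes if usable(f)]
        for j in range(1, len(live) - 1):
            a, b, c = live[j - 1], live[j], live[j + 1]
            def speed(p, q):
                hours = (q.time - p.time) / np.timedelta64(3600, "s")
                if hours <= 0:
                    return np.inf
                return haversine_km(p.lat, p.lon, q.lat, q.lon) / hours
            if speed(a, b) > max_speed_kmh and speed(b, c) > max_speed_kmh:
                b.flags.add("speed-rejected")
                changed = True
                break
    return fixes


def fixes_to_frame(fixes: list[GeoFix]) -> pd.DataFrame:
    """Tabulate fixes: id, timestamp, lat, lon, type, semicolon-joined flags."""
    return pd.DataFrame(
        {
            "id": [f.individual_id for f in fixes],
            "timestamp": [pd.Timestamp(f.time) for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
            "type": [f.fix_type for f in fixes],
            "flags": [";".join(sorted(f.flags)) for f in fixes],
        }
    )
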