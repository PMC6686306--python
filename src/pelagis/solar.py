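"""Low-precision solar geometry shared by the light simulator and the geolocation solver.

The same declination / equation-of-time approximations are used when rendering
synthetic light curves and when inverting twilight times to positions, so that
round-trip tests isolate algorithmic error from ephemeris mismatch.  Accuracy is
a fraction of a degree in declination and well under a minute in the equation of
time — far below the ~2 min twilight interpolation error of 5–10 min light
sampling, and the ~186 km accuracy expected of threshold geolocation.

All angles are degrees, times UTC.
"""

from __future__ import annotations

import numpy as np

# mean tropical year and Earth's obliquity
_TROPICAL_YEAR = 365.25
_OBLIQUITY = 23.44


def _day_of_year(times: np.ndarray) -> np.ndarray:
    """Fractional day of year (1-based) for datetime64 input."""
    t = np.asarray(times, dtype="datetime64[s]")
    years = t.astype("datetime64[Y]")
    return (t - years) / np.timedelta64(86400, "s") + 1.0


def solar_declination(times) -> np.ndarray:
    """Solar declination in degrees, low-order Fourier series in day of year.

    Three harmonics (Spencer's coefficients) keep the error below ~0.3 deg and,
    unlike the single-cosine form, place the zero crossings on the actual
    equinox dates — which matters for flagging the latitude-degenerate window.
    """
    n = _day_of_year(np.asarray(times, dtype="datetime64[s]"))
    g = 2.0 * np.pi * (n - 1.0) / 365.0
    decl_rad = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.rad2deg(decl_rad)


def equation_of_time(times) -> np.ndarray:
    """Equation of time in minutes (apparent minus mean solar time).

    Low-order Fourier approximation; |error| < 1 min over the year.
    """
    n = _day_of_year(np.asarray(times, dtype="datetime64[s]"))
    b = 2.0 * np.pi * (n - 81.0) / 364.0
    return 9.87 * np.sin(2 * b) - 7.53 * np.cos(b) - 1.5 * np.sin(b)


def hour_angle(times, longitude) -> np.ndarray:
    """Solar hour angle in degrees (0 at local apparent noon, +15°/hr afterwards)."""
    t = np.asarray(times, dtype="datetime64[s]")
    days = t.astype("datetime64[D]")
    utc_hours = (t - days) / np.timedelta64(3600, "s")
    solar_hours = utc_hours + np.asarray(longitude) / 15.0 + equation_of_time(t) / 60.0
    return (solar_hours - 12.0) * 15.0


def solar_elevation(times, latitude, longitude) -> np.ndarray:
    """Solar elevation angle in degrees at the given instants and positions.

    sin e = sin(phi) sin(delta) + cos(phi) cos(delta) cos(H)
    """
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    delta = np.deg2rad(solar_declination(times))
    h = np.deg2rad(hour_angle(times, longitude))
    sin_e = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
    return np.rad2deg(np.arcsin(np.clip(sin_e, -1.0, 1.0)))


def solar_position(date, latitude: float, longitude: float, time=None):
    """Declination (deg), equation of time (min) and elevation (deg).

    Parameters
    ----------
    date : date-like
        Used for declination and equation of time.
    latitude, longitude : float
        Observer position, decimal degrees (longitude west-negative).
    time : datetime-like, optional
        Instant for the elevation; defaults to 12:00 UTC on ``date``.
    """
    d = np.datetime64(date, "s")
    if time is None:
        time = d.astype("datetime64[D]") + np.timedelta64(12 * 3600, "s")
    decl = float(solar_declination(d))
    eot = float(equation_of_time(d))
    elev = float(solar_elevation(np.datetime64(time, "s"), latitude, longitude))
    return decl, eot, elev
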