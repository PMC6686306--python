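"""Moon illuminated fraction by date.

A synodic cosine approximation: the fraction of the lunar disc illuminated at
00:00 UTC is (1 - cos(2*pi*age/P))/2 with P = 29.530588 d and age counted from
a reference new moon (2000-01-06 18:14 UTC).  Phase error against a full
ephemeris is below one day, which is irrelevant for a cyclic smooth with k = 3.
An externally supplied per-date table (e.g. from an almanac service) overrides
the formula.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SYNODIC_MONTH_DAYS = 29.530588
NEW_MOON_EPOCH = np.datetime64("2000-01-06T18:14:00", "s")


def moon_age(dates) -> np.ndarray:
    """Days since new moon, in [0, synodic month)."""
    t = pd.to_datetime(np.asarray(dates)).to_numpy(dtype="datetime64[s]")
    age = (t - NEW_MOON_EPOCH) / np.timedelta64(86400, "s")
    return np.mod(age, SYNODIC_MONTH_DAYS)


def moon_fraction(dates, table: pd.Series | None = None) -> pd.Series:
    """Illuminated fraction of the moon at midnight for each date.

    Parameters
    ----------
    dates : sequence of date-like
        Evaluated at 00:00 UTC of each date.
    table : pandas.Series, optional
        Per-date fractions indexed by date; overrides the formula where present.
        Values outside [0, 1] raise ``ValueError``.

    Returns
    -------
    pandas.Series indexed by normalized date, values in [0, 1].
    """
    idx = pd.to_datetime(pd.Index(dates))
    age = moon_age(idx)
    frac = 0.5 * (1.0 - np.cos(2.0 * np.pi * age / SYNODIC_MONTH_DAYS))
    out = pd.Series(frac, index=idx, name="moon_fraction")
    if table is not None:
        table = pd.Series(table)
        table.index = pd.to_datetime(table.index).normalize()
        if ((table < 0) | (table > 1)).any():
            raise ValueError("moon table contains fractions outside [0, 1]")
        norm = out.index.normalize()
        hit = np.asarray(norm.isin(table.index))
        out.iloc[np.nonzero(hit)[0]] = table.loc[norm[hit]].astype(float).to_numpy()
    return out
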