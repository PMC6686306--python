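"""Plain-text readers/writers for all pipeline artifacts, plus input validation.

Formats are deliberately simple: CSV for series and tables (ISO-8601 UTC
timestamps), GeoJSON for tracks, fix points and isopleth polygons, and JSON for
the run manifest.  Every reader validates what it loads; :func:`validate_io`
produces a line-numbered report without raising.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import ImmersionSeries
from .geolocation import LIGHT_MAX, LightSeries
from .simulate import BreedingRecord, TruePath


def write_light_csv(series: LightSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_light_csv(path, individual_id: str | None = None, interval_min: float | None = None) -> LightSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    times = df["timestamp"].to_numpy(dtype="datetime64[s]")
    if interval_min is None and len(times) > 1:
        interval_min = float(np.median(np.diff(times) / np.timedelta64(60, "s")))
    return LightSeries(individual_id or Path(path).stem, times, df["light"].to_numpy(), interval_min or 10.0)


def write_immersion_csv(series: ImmersionSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_immersion_csv(path, individual_id: str | None = None) -> ImmersionSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return ImmersionSeries(
        individual_id or Path(path).stem,
        df["state"].to_numpy(dtype=object),
        df["timestamp"].to_numpy(dtype="datetime64[s]"),
        df["duration_s"].to_numpy(dtype=float),
    )


def write_cohort_csv(records: list[BreedingRecord], path) -> None:
    from .simulate import cohort_to_frame

    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[BreedingRecord]:
    df = pd.read_csv(path, parse_dates=["laying_date", "hatching_date", "failure_date", "return_date"])
    out = []
    for _, r in df.iterrows():
        out.append(
            BreedingRecord(
                individual_id=str(r["individual_id"]),
                sex=str(r["sex"]),
                status=str(r["status"]),
                laying_date=np.datetime64(r["laying_date"], "D"),
                hatching_date=None if pd.isna(r["hatching_date"]) else np.datetime64(r["hatching_date"], "D"),
                failure_date=None if pd.isna(r["failure_date"]) else np.datetime64(r["failure_date"], "D"),
                return_date=None if pd.isna(r.get("return_date")) else np.datetime64(r["return_date"], "D"),
            )
        )
    return out


def write_path_geojson(path_obj: TruePath, path) -> None:
    coords = [[float(lo), float(la)] for lo, la in zip(path_obj.lon, path_obj.lat)]
    gj = {
        "type": "Feature",
        "properties": {"individual_id": path_obj.individual_id},
        "geometry": {"type": "LineString", "coordinates": coords},
    }
    Path(path).write_text(json.dumps(gj))


def write_path_csv(path_obj: TruePath, path) -> None:
    pd.DataFrame(
        {"timestamp": path_obj.times, "lat": path_obj.lat, "lon": path_obj.lon}
    ).to_csv(path, index=False)


def write_fixes_geojson(fixes_df: pd.DataFrame, path) -> None:
    feats = []
    for _, r in fixes_df.iterrows():
        if not np.isfinite(r["lat"]) or not np.isfinite(r["lon"]):
            continue
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "id": r["id"],
                    "timestamp": str(r["timestamp"]),
                    "type": r["type"],
                    "flags": r["flags"],
                },
                "geometry": {"type": "Point", "coordinates": [float(r["lon"]), float(r["lat"])]},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_moon_csv(moon: pd.Series, path) -> None:
    moon.rename_axis("date").to_frame().to_csv(path)


def read_moon_csv(path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    return df["moon_fraction"]


def write_ud_grid(ud, path) -> None:
    """Simple gridded text format: a JSON header line, then the density rows."""
    header = {"x0": ud.x0, "y0": ud.y0, "cell": ud.cell, "shape": list(ud.density.shape)}
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, ud.density, fmt="%.8e")


def read_ud_grid(path):
    from .spatial import UDGrid

    with open(path) as fh:
        header = json.loads(fh.readline())
        dens = np.loadtxt(fh)
    return UDGrid(header["x0"], header["y0"], header["cell"], dens.reshape(header["shape"]))


def write_isopleths_geojson(isopleths: dict, path) -> None:
    """{level or id: Isopleth} -> GeoJSON polygons in the planar frame (metres)."""
    feats = []
    for key, iso in isopleths.items():
        for poly in iso.polygons():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"key": str(key), "level": iso.level, "area_km2": iso.area_km2},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[float(x), float(y)] for x, y in poly.exterior.coords]],
                    },
                }
            )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


def validate_io(files: dict) -> list[str]:
    """Schema / monotonicity / range checks on input files; returns messages.

    ``files`` maps kind ("light" | "immersion" | "fixes" | "cohort") to paths.
    Report-only: problems are returned as strings, nothing raises.
    """
    report: list[str] = []
    for kind, paths in files.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        for p in paths:
            p = Path(p)
            if not p.exists():
                report.append(f"{p}: missing file")
                continue
            try:
                df = pd.read_csv(p)
            except Exception as e:  # noqa: BLE001 - report, don't raise
                report.append(f"{p}: unreadable CSV ({e})")
                continue
            report.extend(f"{p}:{m}" for m in _check_frame(kind, df))
    return report


def _check_frame(kind: str, df: pd.DataFrame) -> list[str]:
    msgs = []
    required = {
        "light": ["timestamp", "light"],
        "immersion": ["timestamp", "state", "duration_s"],
        "fixes": ["id", "timestamp", "lat", "lon"],
        "cohort": ["individual_id", "sex", "status", "laying_date"],
    }.get(kind, [])
    for col in required:
        if col not in df.columns:
            msgs.append(f" missing column '{col}'")
    if msgs:
        return msgs
    if "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = np.nonzero(ts.isna().to_numpy())[0]
        msgs.extend(f"{i + 2}: unparseable timestamp" for i in bad[:5])
        if kind in ("light", "immersion"):
            dec = np.nonzero(np.diff(ts.dropna().to_numpy()) <= np.timedelta64(0, "s"))[0]
            msgs.extend(f"{i + 3}: timestamp not increasing" for i in dec[:5])
    if kind == "light":
        bad = np.nonzero(((df["light"] < 0) | (df["light"] > LIGHT_MAX)).to_numpy())[0]
        msgs.extend(f"{i + 2}: light outside [0, {LIGHT_MAX}]" for i in bad[:5])
    if kind == "immersion":
        states = df["state"].to_numpy()
        bad = np.nonzero(~np.isin(states, ["wet", "dry"]))[0]
        msgs.extend(f"{i + 2}: state not wet/dry" for i in bad[:5])
        same = np.nonzero(states[1:] == states[:-1])[0]
        msgs.extend(f"{i + 3}: state does not alternate" for i in same[:5])
        neg = np.nonzero((df["duration_s"] <= 0).to_numpy())[0]
        msgs.extend(f"{i + 2}: non-positive duration" for i in neg[:5])
    if kind == "fixes":
        bad = np.nonzero((df["lat"].abs() > 90).fillna(False).to_numpy())[0]
        msgs.extend(f"{i + 2}: |lat| > 90" for i in bad[:5])
        bad = np.nonzero((df["lon"].abs() > 180).fillna(False).to_numpy())[0]
        msgs.extend(f"{i + 2}: |lon| > 180" for i in bad[:5])
    return msgs
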