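"""GPS fix ingest: parsing, plausibility filtering, day segmentation.

Timestamps are treated as local civil time (naive, no DST modelling)
so that fixes align with diary clock times. The day boundary is the
half-open interval [00:00, 24:00): a fix at exactly midnight belongs
to the starting date.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .geo import haversine_m

FIX_COLUMNS = ["participant_id", "timestamp", "lat", "lon"]


class ParseError(ValueError):
    """A malformed row or trackpoint in a GPS input file."""


def _validate_fixes(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    if df["timestamp"].isna().any():
        row = int(np.flatnonzero(df["timestamp"].isna().values)[0])
        raise ParseError(f"{origin}: unparseable timestamp at data row {row + 1}")
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise ParseError(
                f"{origin}: {col}={df[col].iloc[row]!r} out of [{lo}, {hi}] "
                f"at data row {row + 1}")
        df[col] = vals.astype(float)
    return df


def read_fixes(path, fmt: str | None = None, participant_id: str | None = None) -> pd.DataFrame:
    """Read GPS fixes from CSV or GPX into the canonical fix frame.

    CSV dialect: header ``participant_id,timestamp,lat,lon`` with
    ISO 8601 timestamps. GPX 1.1: one file per participant (id taken
    from ``participant_id`` or the file stem), ``<time>`` per
    trackpoint. Output is sorted per participant with exact-duplicate
    timestamps collapsed to the first occurrence.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"participant_id": str})
        missing = [c for c in FIX_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
        df = _validate_fixes(df, str(path))
    elif fmt == "gpx":
        df = _read_gpx(path, participant_id)
    else:
        raise ValueError(f"unknown GPS input format {fmt!r} (expected csv or gpx)")
    df = (df[FIX_COLUMNS]
          .sort_values(["participant_id", "timestamp"], kind="stable")
          .drop_duplicates(subset=["participant_id", "timestamp"], keep="first")
          .reset_index(drop=True))
    return df


def _read_gpx(path: Path, participant_id: str | None) -> pd.DataFrame:
    pid = participant_id or path.stem
    tree = etree.parse(str(path))
    ns = {"g": tree.getroot().nsmap.get(None) or "http://www.topografix.com/GPX/1/1"}
    rows = []
    for i, pt in enumerate(tree.findall(".//g:trkpt", ns)):
        t = pt.find("g:time", ns)
        if t is None or pt.get("lat") is None or pt.get("lon") is None:
            raise ParseError(f"{path}: trackpoint {i + 1} missing lat/lon/time")
        rows.append((pid, t.text, pt.get("lat"), pt.get("lon")))
    df = pd.DataFrame(rows, columns=FIX_COLUMNS)
    # GPX time is nominally UTC; interpret as local civil time, drop tz
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df["timestamp"] = df["timestamp"].dt.tz_localize(None)
    return _validate_fixes(df, str(path))


def remove_speed_outliers(fixes: pd.DataFrame, vmax_kmh: float = 330.0) -> pd.DataFrame:
    """Drop fixes implying implausible speeds (default > 330 km/h).

    Forward scan per participant: a fix is dropped when the
    great-circle speed from the *last retained* fix exceeds the
    ceiling, so a burst of consecutive jumps is removed entirely.
    The result is idempotent under re-application.
    """
    if len(fixes) == 0:
        return fixes.copy()
    vmax_ms = vmax_kmh / 3.6
    out_masks = []
    for _, grp in fixes.groupby("participant_id", sort=False):
        t = grp["timestamp"].values.astype("datetime64[ns]").astype(np.int64) / 1e9
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        keep = np.ones(len(grp), dtype=bool)
        # fast path: pairwise speeds all plausible
        if len(grp) > 1:
            d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
            dt = np.maximum(t[1:] - t[:-1], 1e-9)
            if (d / dt <= vmax_ms).all():
                out_masks.append(pd.Series(keep, index=grp.index))
                continue
        anchor = 0
        for i in range(1, len(grp)):
            d = haversine_m(lat[anchor], lon[anchor], lat[i], lon[i])
            dt = max(t[i] - t[anchor], 1e-9)
            if d / dt > vmax_ms:
                keep[i] = False
            else:
                anchor = i
        out_masks.append(pd.Series(keep, index=grp.index))
    mask = pd.concat(out_masks).reindex(fixes.index)
    return fixes.loc[mask.to_numpy(dtype=bool)].reset_index(drop=True)


def segment_days(fixes: pd.DataFrame) -> pd.DataFrame:
    """Assign each fix to its participant-day (local civil date).

    Returns a copy of the fix frame with a normalized ``date`` column;
    concatenating the per-day groups reproduces the input fix multiset.
    """
    out = fixes.copy()
    out["date"] = out["timestamp"].dt.normalize()
    return out


def flag_valid_days(day_fixes: pd.DataFrame,
                    min_registration_hours: float = 9.0,
                    min_valid_days: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """Per-day registration periods, validity flags and GPS eligibility.

    The registration period is the time between the first and last fix
    of a day; a day is valid iff it reaches ``min_registration_hours``.
    A participant is GPS-eligible iff they have at least
    ``min_valid_days`` valid days.
    """
    if len(day_fixes) == 0:
        days = pd.DataFrame(columns=["participant_id", "date", "n_fixes",
                                     "first_fix", "last_fix",
                                     "registration_min", "is_valid"])
        return days, pd.Series(dtype=bool, name="gps_eligible")
    g = day_fixes.groupby(["participant_id", "date"])["timestamp"]
    days = pd.DataFrame({"n_fixes": g.size(),
                         "first_fix": g.min(),
                         "last_fix": g.max()}).reset_index()
    days["registration_min"] = ((days["last_fix"] - days["first_fix"])
                                .dt.total_seconds() / 60.0)
    days["is_valid"] = days["registration_min"] >= min_registration_hours * 60.0
    eligible = (days.groupby("participant_id")["is_valid"].sum() >= min_valid_days)
    eligible.name = "gps_eligible"
    return days, eligible
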