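"""GPS mobility-event extraction.

Two event families are extracted per participant-day:

* **Time out of home (TOH)** — each fix is labelled home/out-of-home by
  a circular geofence of radius Dmax around the resolved home; maximal
  same-state runs become episodes, data gaps up to Tmax flanked by the
  same state are filled in at the event level, and out-of-home episodes
  of at least Tmin become TOH events.
* **Activity locations (AL)** — time-based sequential stop detection: a
  cluster grows from an anchor fix while subsequent fixes stay within
  Dmax of the anchor and inter-fix gaps stay within Tmax; clusters
  spanning at least Tmin are stops, short non-stop episodes (< 3 min)
  are noise, stops separated only by noise/gaps merge when close in
  space and time, and stops within Dmax of home are excluded.

Days are segmented at midnight before extraction, so events never span
midnight; no interpolation is performed into unobserved time at the
day edges. The geofence/stop boundary is inclusive: distance == Dmax
counts as inside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ThresholdSet
from .geo import _haversine_rad, haversine_m

EVENT_COLUMNS = ["participant_id", "date", "kind", "source", "start", "end",
                 "duration_min", "lat", "lon", "n_fixes"]

_SCAN_CHUNK = 512


def empty_events() -> pd.DataFrame:
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def label_fixes(lat, lon, home_lat: float, home_lon: float, dmax_m: float) -> np.ndarray:
    """Boolean home-state per fix: within the Dmax geofence (inclusive)."""
    d = haversine_m(np.asarray(lat, dtype=float), np.asarray(lon, dtype=float),
                    home_lat, home_lon)
    return d <= dmax_m


def build_episodes(t_s: np.ndarray, is_home: np.ndarray, tmax_min: float) -> list[dict]:
    """HOME/OH/GAP episodes from state-labelled, time-sorted fixes.

    Same-state gaps of at most Tmax are absorbed into their episode;
    longer gaps, and any inter-fix interval flanked by unequal states,
    become GAP episodes (``bridgeable`` marks gaps <= Tmax). Episode
    intervals run from first to last member fix; the episodes tile the
    registration period exactly.
    """
    n = len(t_s)
    if n == 0:
        return []
    tmax_s = tmax_min * 60.0
    episodes: list[dict] = []
    gaps = np.diff(t_s)
    block_bounds = np.concatenate([[0], np.flatnonzero(gaps > tmax_s) + 1, [n]])
    prev_last = None
    for bi in range(len(block_bounds) - 1):
        a, b = int(block_bounds[bi]), int(block_bounds[bi + 1])
        if prev_last is not None:
            episodes.append({"kind": "GAP", "t0": t_s[prev_last], "t1": t_s[a],
                             "bridgeable": False})
        s = is_home[a:b]
        run_starts = np.concatenate([[0], np.flatnonzero(s[1:] != s[:-1]) + 1])
        run_ends = np.concatenate([run_starts[1:], [b - a]])
        for r0, r1 in zip(run_starts, run_ends):
            i0, i1 = a + int(r0), a + int(r1)
            if episodes and episodes[-1]["kind"] in ("HOME", "OH"):
                episodes.append({"kind": "GAP", "t0": t_s[i0 - 1], "t1": t_s[i0],
                                 "bridgeable": True})
            episodes.append({"kind": "HOME" if s[r0] else "OH",
                             "t0": t_s[i0], "t1": t_s[i1 - 1], "bridgeable": False})
        prev_last = b - 1
    return episodes


def extract_toh_events(episodes: list[dict], tmin_min: float) -> list[dict]:
    """Promote OH episodes >= Tmin to TOH; relabel shorter ones HOME.

    Relabelled episodes are re-merged with surrounding HOME across the
    bridgeable transition gaps, so a sub-Tmin excursion disappears into
    the home period instead of becoming unobserved time. Returns the
    reworked episode list, with OH renamed to TOH.
    """
    tmin_s = tmin_min * 60.0
    work = []
    for e in episodes:
        e = dict(e)
        if e["kind"] == "OH" and (e["t1"] - e["t0"]) < tmin_s:
            e["kind"] = "HOME"
        work.append(e)
    out: list[dict] = []
    for e in work:
        if (e["kind"] == "HOME" and len(out) >= 2
                and out[-1]["kind"] == "GAP" and out[-1]["bridgeable"]
                and out[-2]["kind"] == "HOME"):
            out.pop()
            out[-1]["t1"] = e["t1"]
            continue
        if e["kind"] == "HOME" and out and out[-1]["kind"] == "HOME":
            out[-1]["t1"] = e["t1"]
            continue
        out.append(e)
    for e in out:
        if e["kind"] == "OH":
            e["kind"] = "TOH"
    return out


def _scan_break(t_s, lat_r, lon_r, i, dmax_m, tmax_s) -> int:
    """First index j > i violating the join-to-anchor rule, or n."""
    n = len(t_s)
    k = i + 1
    while k < n:
        j2 = min(n, k + _SCAN_CHUNK)
        d = _haversine_rad(lat_r[i], lon_r[i], lat_r[k:j2], lon_r[k:j2])
        g = t_s[k:j2] - t_s[k - 1:j2 - 1]
        bad = (d > dmax_m) | (g > tmax_s)
        hits = np.flatnonzero(bad)
        if len(hits):
            return k + int(hits[0])
        k = j2
    return n


def detect_stops(t_s: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                 thresholds: ThresholdSet) -> list[dict]:
    """Sequential time-based stop detection over one day of fixes.

    Returns chronologically ordered episodes: STOP (with coordinate-wise
    median position, member ranges and fix count), MOVE (released
    fixes), and GAP (inter-fix gaps exceeding Tmax). A fix joins the
    open cluster iff its distance to the cluster's anchor (first) fix is
    at most Dmax and the gap to the immediately preceding fix is at most
    Tmax; on violation the cluster closes and is a STOP iff its time
    span reaches Tmin.
    """
    n = len(t_s)
    if n == 0:
        return []
    lat_r = np.radians(np.asarray(lat, dtype=float))
    lon_r = np.radians(np.asarray(lon, dtype=float))
    tmin_s = thresholds.tmin_min * 60.0
    tmax_s = thresholds.tmax_min * 60.0

    clusters = []
    i = 0
    while i < n:
        j = _scan_break(t_s, lat_r, lon_r, i, thresholds.dmax_m, tmax_s)
        clusters.append((i, j))
        i = j

    episodes: list[dict] = []
    move_range = None

    def flush_move():
        nonlocal move_range
        if move_range is not None:
            a, b = move_range
            episodes.append({"kind": "MOVE", "t0": t_s[a], "t1": t_s[b - 1],
                             "i0": a, "i1": b})
            move_range = None

    for a, b in clusters:
        if a > 0 and (t_s[a] - t_s[a - 1]) > tmax_s:
            flush_move()
            episodes.append({"kind": "GAP", "t0": t_s[a - 1], "t1": t_s[a]})
        if (t_s[b - 1] - t_s[a]) >= tmin_s:
            flush_move()
            episodes.append(_make_stop(t_s, lat, lon, [(a, b)]))
        else:
            move_range = (move_range[0], b) if move_range is not None else (a, b)
    flush_move()
    return episodes


def _make_stop(t_s, lat, lon, ranges) -> dict:
    idx = np.concatenate([np.arange(a, b) for a, b in ranges])
    return {"kind": "STOP",
            "t0": t_s[ranges[0][0]], "t1": t_s[ranges[-1][1] - 1],
            "lat": float(np.median(lat[idx])), "lon": float(np.median(lon[idx])),
            "n_fixes": int(len(idx)), "ranges": list(ranges)}


def merge_noise(episodes: list[dict], thresholds: ThresholdSet,
                t_s: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                noise_move_min: float = 3.0) -> list[dict]:
    """Relabel short moves as noise and merge stops across them.

    MOVE episodes shorter than ``noise_move_min`` become NOISE. Two
    stops separated only by NOISE and/or GAP episodes merge into one
    when their median positions lie closer than Dmax and the time from
    the first stop's end to the second's start is below Tmax; the
    merged stop's position is the coordinate-wise median over the union
    of member fixes. Merging is applied left-to-right to a fixed point.
    """
    eps = []
    for e in episodes:
        e = dict(e)
        if e["kind"] == "MOVE" and (e["t1"] - e["t0"]) < noise_move_min * 60.0:
            e["kind"] = "NOISE"
        eps.append(e)
    tmax_s = thresholds.tmax_min * 60.0
    changed = True
    while changed:
        changed = False
        out: list[dict] = []
        i = 0
        while i < len(eps):
            e = eps[i]
            if e["kind"] != "STOP":
                out.append(e)
                i += 1
                continue
            j = i + 1
            while j < len(eps) and eps[j]["kind"] in ("NOISE", "GAP"):
                j += 1
            if j < len(eps) and eps[j]["kind"] == "STOP":
                nxt = eps[j]
                d = haversine_m(e["lat"], e["lon"], nxt["lat"], nxt["lon"])
                if d < thresholds.dmax_m and (nxt["t0"] - e["t1"]) < tmax_s:
                    eps[j] = _make_stop(t_s, lat, lon, e["ranges"] + nxt["ranges"])
                    i = j
                    changed = True
                    continue
            out.append(e)
            i += 1
        eps = out
    return eps


def exclude_home_stops(episodes: list[dict], home_lat: float, home_lon: float,
                       dmax_m: float) -> list[dict]:
    """Drop stops whose median position lies within Dmax of home."""
    out = []
    for e in episodes:
        if e["kind"] != "STOP":
            continue
        if haversine_m(e["lat"], e["lon"], home_lat, home_lon) <= dmax_m:
            continue
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# day-level orchestration on the canonical frames

def _day_arrays(grp: pd.DataFrame):
    t_s = grp["timestamp"].values.astype("datetime64[ns]").astype(np.int64) / 1e9
    return t_s, grp["lat"].to_numpy(dtype=float), grp["lon"].to_numpy(dtype=float)


def extract_day_events(day_fixes: pd.DataFrame, home_lat: float, home_lon: float,
                       thresholds: ThresholdSet, noise_move_min: float = 3.0):
    """TOH events, AL events and episode bookkeeping for one day.

    ``day_fixes`` is one participant-day of the fix frame, sorted by
    timestamp. Returns (toh_episodes, al_stops) as episode dict lists
    with t0/t1 in epoch seconds.
    """
    t_s, lat, lon = _day_arrays(day_fixes)
    is_home = label_fixes(lat, lon, home_lat, home_lon, thresholds.dmax_m)
    episodes = build_episodes(t_s, is_home, thresholds.tmax_min)
    toh_episodes = extract_toh_events(episodes, thresholds.tmin_min)
    stop_eps = detect_stops(t_s, lat, lon, thresholds)
    stop_eps = merge_noise(stop_eps, thresholds, t_s, lat, lon, noise_move_min)
    al_stops = exclude_home_stops(stop_eps, home_lat, home_lon, thresholds.dmax_m)
    return toh_episodes, al_stops


def _episodes_to_frame(episodes, pid, date, kinds, source="GPS") -> pd.DataFrame:
    rows = []
    for e in episodes:
        if e["kind"] not in kinds:
            continue
        rows.append({"participant_id": pid, "date": date, "kind": e["kind"],
                     "source": source,
                     "start": pd.Timestamp(int(round(e["t0"] * 1e9))),
                     "end": pd.Timestamp(int(round(e["t1"] * 1e9))),
                     "duration_min": (e["t1"] - e["t0"]) / 60.0,
                     "lat": e.get("lat", np.nan), "lon": e.get("lon", np.nan),
                     "n_fixes": e.get("n_fixes", np.nan)})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows else empty_events()


def extract_gps_events(day_fixes: pd.DataFrame, days: pd.DataFrame,
                       homes_resolved: pd.DataFrame, thresholds: ThresholdSet,
                       noise_move_min: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TOH and AL event frames over all valid days of home-valid participants."""
    homes = homes_resolved.loc[homes_resolved["is_valid"]]
    home_map = {r["participant_id"]: (r["lat"], r["lon"]) for _, r in homes.iterrows()}
    valid = days.loc[days["is_valid"], ["participant_id", "date"]]
    toh_frames, al_frames = [], []
    grouped = dict(tuple(day_fixes.groupby(["participant_id", "date"], sort=False)))
    for _, rec in valid.iterrows():
        pid, date = rec["participant_id"], rec["date"]
        if pid not in home_map or (pid, date) not in grouped:
            continue
        grp = grouped[(pid, date)].sort_values("timestamp", kind="stable")
        toh_eps, al_stops = extract_day_events(grp, home_map[pid][0], home_map[pid][1],
                                               thresholds, noise_move_min)
        toh_df = _episodes_to_frame(toh_eps, pid, date, kinds={"TOH"})
        if len(toh_df):
            toh_frames.append(toh_df)
        al_df = _episodes_to_frame(al_stops, pid, date, kinds={"STOP"})
        if len(al_df):
            al_df["kind"] = "AL"
            al_frames.append(al_df)
    toh = pd.concat(toh_frames, ignore_index=True) if toh_frames else empty_events()
    al = pd.concat(al_frames, ignore_index=True) if al_frames else empty_events()
    return toh, al


def aggregate_daily_gps(toh_events: pd.DataFrame, al_events: pd.DataFrame,
                        days: pd.DataFrame) -> pd.DataFrame:
    """Per valid participant-day: summed TOH minutes and AL counts.

    Valid days without any event are genuine zero-mobility days and
    appear with zeros.
    """
    valid = days.loc[days["is_valid"], ["participant_id", "date"]].copy()
    if len(toh_events):
        toh_sum = toh_events.groupby(["participant_id", "date"])["duration_min"] \
            .sum().rename("gps_toh_min")
        valid = valid.merge(toh_sum, on=["participant_id", "date"], how="left")
    else:
        valid["gps_toh_min"] = 0.0
    if len(al_events):
        al_n = al_events.groupby(["participant_id", "date"]).size().rename("gps_nals")
        valid = valid.merge(al_n, on=["participant_id", "date"], how="left")
    else:
        valid["gps_nals"] = 0
    valid["gps_toh_min"] = valid["gps_toh_min"].fillna(0.0)
    valid["gps_nals"] = valid["gps_nals"].fillna(0).astype(int)
    return valid.reset_index(drop=True)
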