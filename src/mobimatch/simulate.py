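"""Synthetic cohort generator.

Emulates the data-generating situation of a one-week mobility study in
community-dwelling older adults: each simulated participant carries a
phone logging GPS fixes at a fixed interval during waking hours, and
keeps two diaries — one for out-of-home episodes (TOH) and one for
stationary activity-location visits (ALs).

The generator produces, per participant-day, a ground-truth schedule of
home dwells, outings and nested stationary visits; a GPS fix stream
with isotropic Gaussian positional noise and bursty indoor signal
loss; and imperfect diaries (omissions, Gaussian start/end shifts,
clock-time rounding). Ground truth is returned unperturbed so every
downstream stage can be validated against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .geo import destination_point, haversine_m, interpolate_great_circle, offset_deg

ACTIVITY_TYPES = ("work", "commercial", "social", "personal_care",
                  "culture_religion_education", "recreation",
                  "transportation", "unassignable")
# rough frequency profile of reported visit types in an older-adult cohort
_ACTIVITY_WEIGHTS = (0.02, 0.44, 0.08, 0.07, 0.10, 0.14, 0.10, 0.05)
_P_INDOOR = 0.7

# Waking-hours scheduling window (seconds of day) within which outings
# are placed; the device-on window should cover it.
_SCHEDULE_START_S = 8 * 3600.0
_SCHEDULE_END_S = 21.5 * 3600.0
_MIN_PLACE_SEP_M = 400.0  # inter-place spacing floor (> any sensible Dmax)
_MEAN_LOSS_BURST_S = 600.0  # mean length of an indoor signal-loss burst


def _parse_clock(s: str) -> float:
    h, m = s.split(":")
    return int(h) * 3600.0 + int(m) * 60.0


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Rates are per-day / per-outing Poisson means; durations are
    log-normal in minutes. ``gps_interval_s`` defaults to 10 s to keep
    simulated streams compact; 1 s reproduces the original logging rate.
    """

    n_participants: int = 35
    n_days: int = 7
    home_coords: tuple | None = None  # ((lat, lon), ...) per participant
    outings_per_day_mean: float = 1.8
    outing_duration_lognorm: tuple = (np.log(45.0), 0.5)  # walk outings, min
    als_per_outing_mean: float = 1.5
    al_duration_lognorm: tuple = (np.log(30.0), 0.8)  # visit duration, min
    al_min_duration_min: float = 8.0
    travel_speed_ms: float = 1.4
    gps_interval_s: float = 10.0
    gps_noise_sd_m: float = 10.0
    indoor_loss_prob: float = 0.3
    device_off_windows: tuple = (("00:00", "07:30"), ("22:30", "24:00"))
    diary_omission_prob: float = 0.1
    diary_time_round_min: float = 5.0
    diary_shift_sd_min: float = 5.0
    seed: int = 0
    start_date: str = "2023-05-01"

    def __post_init__(self):
        def bad(name, msg):
            raise ConfigurationError(f"SimConfig.{name}: {msg}")

        for name in ("n_participants", "n_days"):
            if int(getattr(self, name)) < 0:
                bad(name, "must be a non-negative count")
        for name in ("outings_per_day_mean", "als_per_outing_mean"):
            if getattr(self, name) < 0:
                bad(name, "rate must be >= 0")
        for name in ("diary_omission_prob", "indoor_loss_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                bad(name, f"probability must lie in [0, 1], got {p!r}")
        if not (self.gps_interval_s > 0):
            bad("gps_interval_s", "must be strictly positive")
        for name in ("gps_noise_sd_m", "diary_time_round_min",
                     "diary_shift_sd_min", "travel_speed_ms",
                     "al_min_duration_min"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if self.travel_speed_ms == 0:
            bad("travel_speed_ms", "must be strictly positive")
        if self.home_coords is not None and len(self.home_coords) != self.n_participants:
            bad("home_coords", "must provide one (lat, lon) per participant")


@dataclass
class GroundTruth:
    """Unperturbed schedules underlying a simulated cohort.

    ``toh``: one row per true out-of-home episode; ``als``: one row per
    true stationary visit (nested inside a TOH episode); ``homes``: the
    true residence coordinates.
    """

    toh: pd.DataFrame
    als: pd.DataFrame
    homes: pd.DataFrame

    def daily_indicators(self) -> pd.DataFrame:
        """True per participant-day TOH minutes and visit counts."""
        toh = self.toh.copy()
        if len(toh):
            toh["date"] = toh["start"].dt.normalize()
            toh["dur"] = (toh["end"] - toh["start"]).dt.total_seconds() / 60.0
            t = toh.groupby(["participant_id", "date"])["dur"].sum()
        else:
            t = pd.Series(dtype=float)
        als = self.als.copy()
        if len(als):
            als["date"] = als["start"].dt.normalize()
            a = als.groupby(["participant_id", "date"]).size()
        else:
            a = pd.Series(dtype=int)
        idx = sorted(set(t.index) | set(a.index))
        out = pd.DataFrame(index=pd.MultiIndex.from_tuples(idx, names=["participant_id", "date"])
                           if idx else None)
        out["true_toh_min"] = t
        out["true_nals"] = a
        return out.fillna(0).reset_index()


@dataclass
class Cohort:
    """A simulated cohort in the pipeline's input representations."""

    fixes: pd.DataFrame       # participant_id, timestamp, lat, lon
    toh_diary: pd.DataFrame   # participant_id, start, end, worn_flag
    al_diary: pd.DataFrame    # participant_id, start, end, place_name, ...
    homes: pd.DataFrame       # participant_id, lat, lon
    truth: GroundTruth
    config: SimConfig


def _default_homes(n: int) -> np.ndarray:
    """Scatter residences on a ~5 km grid around central Cologne."""
    base_lat, base_lon = 50.94, 6.96
    rows = np.arange(n) // 6
    cols = np.arange(n) % 6
    return np.stack([base_lat + 0.05 * rows, base_lon + 0.08 * cols], axis=1)


def _sample_places(rng, home, k):
    """k destinations 0.4–2.5 km from home, pairwise >= 400 m apart."""
    places = []
    for _ in range(k):
        for _attempt in range(40):
            dist = rng.uniform(_MIN_PLACE_SEP_M, 2500.0)
            bearing = rng.uniform(0.0, 360.0)
            lat, lon = destination_point(home[0], home[1], bearing, dist)
            if all(haversine_m(lat, lon, p[0], p[1]) >= _MIN_PLACE_SEP_M
                   for p in places):
                break
        places.append((float(lat), float(lon)))
    return places


def _simulate_day_schedule(rng, cfg: SimConfig, home, pid, day_start):
    """Ground-truth segments and events for one participant-day.

    Returns (segments, toh_records, al_records). Segments tile
    [0, 86400) s with ('home',), ('stay', lat, lon) and
    ('travel', lat1, lon1, lat2, lon2) pieces.
    """
    mu_o, sg_o = cfg.outing_duration_lognorm
    mu_a, sg_a = cfg.al_duration_lognorm
    outings = []  # (start_s, end_s, inner segments rel. to start, al records)
    cursor = _SCHEDULE_START_S
    n_out = rng.poisson(cfg.outings_per_day_mean)
    for i in range(n_out):
        gap_min = rng.uniform(10.0, 90.0) if i == 0 else rng.uniform(20.0, 120.0)
        start = cursor + gap_min * 60.0
        k = int(rng.poisson(cfg.als_per_outing_mean))
        segs = []
        als = []
        if k == 0:
            dur_min = float(np.clip(rng.lognormal(mu_o, sg_o), 10.0, 240.0))
            half = cfg.travel_speed_ms * dur_min * 60.0 / 2.0
            bearing = rng.uniform(0.0, 360.0)
            dlat, dlon = destination_point(home[0], home[1], bearing, half)
            t_half = dur_min * 60.0 / 2.0
            segs = [(0.0, t_half, ("travel", home[0], home[1], float(dlat), float(dlon))),
                    (t_half, 2 * t_half, ("travel", float(dlat), float(dlon), home[0], home[1]))]
            total = 2 * t_half
        else:
            places = _sample_places(rng, home, k)
            stays = cfg.al_min_duration_min + np.clip(
                rng.lognormal(mu_a, sg_a, size=k), 0.0, 360.0)
            route = [tuple(home)] + places + [tuple(home)]
            t = 0.0
            for j in range(k):
                p0, p1 = route[j], route[j + 1]
                leg = haversine_m(p0[0], p0[1], p1[0], p1[1]) / cfg.travel_speed_ms
                segs.append((t, t + leg, ("travel", *p0, *p1)))
                t += leg
                stay_s = float(stays[j]) * 60.0
                segs.append((t, t + stay_s, ("stay", *p1)))
                als.append({"rel_start": t, "rel_end": t + stay_s,
                            "lat": p1[0], "lon": p1[1],
                            "place_name": f"place_{pid}_{len(als)}",
                            "activity_type": str(rng.choice(ACTIVITY_TYPES,
                                                            p=_ACTIVITY_WEIGHTS)),
                            "indoor_outdoor": "indoor" if rng.random() < _P_INDOOR
                            else "outdoor"})
                t += stay_s
            p0, p1 = route[-2], route[-1]
            leg = haversine_m(p0[0], p0[1], p1[0], p1[1]) / cfg.travel_speed_ms
            segs.append((t, t + leg, ("travel", *p0, *p1)))
            total = t + leg
        end = start + total
        if end > _SCHEDULE_END_S:
            break
        outings.append((start, end, segs, als))
        cursor = end

    # tile the day with home segments around the outings
    segments = []
    toh_records = []
    al_records = []
    prev = 0.0
    for start, end, segs, als in outings:
        if start > prev:
            segments.append((prev, start, ("home",)))
        for s0, s1, payload in segs:
            segments.append((start + s0, start + s1, payload))
        toh_records.append({"participant_id": pid,
                            "start": day_start + pd.Timedelta(seconds=start),
                            "end": day_start + pd.Timedelta(seconds=end)})
        for al in als:
            al_records.append({"participant_id": pid,
                               "start": day_start + pd.Timedelta(seconds=start + al["rel_start"]),
                               "end": day_start + pd.Timedelta(seconds=start + al["rel_end"]),
                               "lat": al["lat"], "lon": al["lon"],
                               "place_name": al["place_name"],
                               "activity_type": al["activity_type"],
                               "indoor_outdoor": al["indoor_outdoor"]})
        prev = end
    if prev < 86400.0:
        segments.append((prev, 86400.0, ("home",)))
    return segments, toh_records, al_records


def _sample_fixes(rng, cfg: SimConfig, home, segments, day_start):
    """GPS fixes for one day: sampling grid, positions, loss, noise."""
    step = max(1, int(round(cfg.gps_interval_s)))
    times = np.arange(0, 86400, step, dtype=np.int64)
    on = np.ones(len(times), dtype=bool)
    for w0, w1 in cfg.device_off_windows:
        a, b = _parse_clock(w0), _parse_clock(w1)
        on &= ~((times >= a) & (times < b))
    times = times[on]
    if len(times) == 0:
        return times, np.empty(0), np.empty(0), np.empty(0, dtype=bool)

    lat = np.empty(len(times))
    lon = np.empty(len(times))
    indoor = np.zeros(len(times), dtype=bool)
    starts = np.array([s[0] for s in segments])
    seg_idx = np.searchsorted(starts, times, side="right") - 1
    seg_idx = np.clip(seg_idx, 0, len(segments) - 1)
    for si in np.unique(seg_idx):
        s0, s1, payload = segments[si]
        mask = seg_idx == si
        if payload[0] == "home":
            lat[mask], lon[mask] = home[0], home[1]
            indoor[mask] = True
        elif payload[0] == "stay":
            lat[mask], lon[mask] = payload[1], payload[2]
            indoor[mask] = True  # refined below from visit labels by caller
        else:  # travel
            frac = (times[mask] - s0) / max(s1 - s0, 1e-9)
            la, lo = interpolate_great_circle(payload[1], payload[2],
                                              payload[3], payload[4],
                                              np.clip(frac, 0.0, 1.0))
            lat[mask], lon[mask] = la, lo
    return times, lat, lon, indoor


def _burst_loss_mask(rng, indoor: np.ndarray, p: float, step_s: float) -> np.ndarray:
    """Dropped-fix mask: bursty loss over indoor runs.

    Loss is a two-state (kept/dropped) alternating-run process whose
    stationary dropped fraction is ``p`` and whose mean dropped-run
    length is ~10 min, so gaps are contiguous as with real indoor
    signal loss rather than i.i.d. single-fix dropouts.
    """
    n = len(indoor)
    drop = np.zeros(n, dtype=bool)
    if p <= 0.0 or n == 0:
        return drop
    if p >= 1.0:
        return indoor.copy()
    mean_drop = max(1.0, _MEAN_LOSS_BURST_S / step_s)
    mean_keep = mean_drop * (1.0 - p) / p
    # walk the contiguous indoor runs with alternating geometric run lengths
    idx = 0
    while idx < n:
        if not indoor[idx]:
            idx += 1
            continue
        run_end = idx
        while run_end < n and indoor[run_end]:
            run_end += 1
        pos = idx
        dropping = rng.random() < p
        while pos < run_end:
            mean = mean_drop if dropping else mean_keep
            length = int(rng.geometric(min(1.0, 1.0 / mean)))
            drop[pos:min(pos + length, run_end)] = dropping
            pos += length
            dropping = not dropping
        idx = run_end
    return drop


def _perturb_diary(rng, df: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Apply omission, start/end shift and clock rounding to true events."""
    if len(df) == 0:
        return df.copy()
    keep = rng.random(len(df)) >= cfg.diary_omission_prob
    out = df.loc[keep].copy()
    if len(out) == 0:
        return out
    for col in ("start", "end"):
        shift = rng.normal(0.0, cfg.diary_shift_sd_min, size=len(out))
        t = out[col] + pd.to_timedelta(shift, unit="m")
        if cfg.diary_time_round_min > 0:
            t = t.dt.round(f"{int(cfg.diary_time_round_min * 60)}s")
        out[col] = t
    bad = out["end"] <= out["start"]
    grain = max(cfg.diary_time_round_min, 1.0)
    out.loc[bad, "end"] = out.loc[bad, "start"] + pd.Timedelta(minutes=grain)
    return out.reset_index(drop=True)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort (fixes, diaries, ground truth).

    Two calls with an equal ``SimConfig`` (including seed) produce
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    homes = (np.asarray(config.home_coords, dtype=float)
             if config.home_coords is not None
             else _default_homes(config.n_participants))
    day0 = pd.Timestamp(config.start_date)
    step = max(1, int(round(config.gps_interval_s)))

    fix_frames = []
    toh_truth = []
    al_truth = []
    for p in range(config.n_participants):
        pid = f"P{p + 101}"
        home = homes[p]
        for d in range(config.n_days):
            day_start = day0 + pd.Timedelta(days=d)
            segments, tohs, als = _simulate_day_schedule(rng, config, home, pid, day_start)
            toh_truth.extend(tohs)
            times, lat, lon, indoor = _sample_fixes(rng, config, home, segments, day_start)
            if len(times) == 0:
                continue
            # outdoor-labelled visits do not suffer indoor signal loss
            for al in als:
                if al["indoor_outdoor"] == "outdoor":
                    rel = (times >= (al["start"] - day_start).total_seconds()) & \
                          (times < (al["end"] - day_start).total_seconds())
                    indoor[rel] = False
            al_truth.extend(als)
            drop = _burst_loss_mask(rng, indoor, config.indoor_loss_prob, step)
            keep = ~drop
            times, lat, lon = times[keep], lat[keep], lon[keep]
            if config.gps_noise_sd_m > 0 and len(times):
                north = rng.normal(0.0, config.gps_noise_sd_m, len(times))
                east = rng.normal(0.0, config.gps_noise_sd_m, len(times))
                dlat, dlon = offset_deg(home[0], north, east)
                lat = lat + dlat
                lon = lon + dlon
            fix_frames.append(pd.DataFrame({
                "participant_id": pid,
                "timestamp": day_start + pd.to_timedelta(times, unit="s"),
                "lat": lat, "lon": lon}))

    fixes = (pd.concat(fix_frames, ignore_index=True) if fix_frames
             else pd.DataFrame(columns=["participant_id", "timestamp", "lat", "lon"]))
    truth_toh = pd.DataFrame(toh_truth, columns=["participant_id", "start", "end"])
    truth_als = pd.DataFrame(al_truth, columns=["participant_id", "start", "end",
                                                "lat", "lon", "place_name",
                                                "activity_type", "indoor_outdoor"])
    for df in (truth_toh, truth_als):
        for col in ("start", "end"):
            df[col] = pd.to_datetime(df[col])
    homes_df = pd.DataFrame({
        "participant_id": [f"P{p + 101}" for p in range(config.n_participants)],
        "lat": homes[:, 0] if len(homes) else [],
        "lon": homes[:, 1] if len(homes) else []})

    toh_diary = _perturb_diary(rng, truth_toh, config)
    toh_diary["worn_flag"] = True
    if "worn_flag" not in toh_diary.columns or len(toh_diary) == 0:
        toh_diary = toh_diary.reindex(columns=["participant_id", "start", "end", "worn_flag"])
    al_diary = _perturb_diary(
        rng, truth_als[["participant_id", "start", "end", "place_name",
                        "activity_type", "indoor_outdoor"]], config)
    al_diary["stationary"] = True
    al_diary["at_home"] = False
    al_diary["false_report"] = False
    al_diary = al_diary.reindex(columns=["participant_id", "start", "end", "place_name",
                                         "activity_type", "indoor_outdoor",
                                         "stationary", "at_home", "false_report"])
    toh_diary = toh_diary.reindex(columns=["participant_id", "start", "end", "worn_flag"])

    truth = GroundTruth(toh=truth_toh, als=truth_als, homes=homes_df.copy())
    return Cohort(fixes=fixes, toh_diary=toh_diary, al_diary=al_diary,
                  homes=homes_df, truth=truth, config=config)


def study_period(config: SimConfig) -> tuple[pd.Timestamp, pd.Timestamp]:
    """[start, end) study window of a simulated cohort."""
    start = pd.Timestamp(config.start_date)
    return start, start + pd.Timedelta(days=config.n_days)


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(path, cohort: Cohort) -> dict:
    """Write a cohort to disk in the pipeline's input CSV formats.

    Produces ``gps.csv``, ``toh_diary.csv``, ``al_diary.csv``,
    ``homes.csv`` and ``ground_truth.json`` under ``path``; timestamps
    are ISO 8601 at 1-s (GPS) / 1-min-compatible (diary) resolution.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    gps = cohort.fixes.copy()
    gps["timestamp"] = pd.to_datetime(gps["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    files["gps"] = path / "gps.csv"
    gps.to_csv(files["gps"], index=False)
    for name, df in (("toh_diary", cohort.toh_diary), ("al_diary", cohort.al_diary)):
        out = df.copy()
        for col in ("start", "end"):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        files[name] = path / f"{name}.csv"
        out.to_csv(files[name], index=False)
    files["homes"] = path / "homes.csv"
    cohort.homes.to_csv(files["homes"], index=False)

    def frame_payload(df):
        # ground truth keeps full (sub-second) precision, unlike the
        # 1-s GPS / whole-minute diary input formats
        out = df.copy()
        for col in ("start", "end"):
            if col in out.columns:
                out[col] = pd.to_datetime(out[col]).map(pd.Timestamp.isoformat)
        return {"columns": list(out.columns), "values": out.to_dict(orient="list")}

    truth_payload = {"toh": frame_payload(cohort.truth.toh),
                     "als": frame_payload(cohort.truth.als),
                     "homes": cohort.truth.homes.to_dict(orient="list"),
                     "config": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in asdict(cohort.config).items()}}
    files["ground_truth"] = path / "ground_truth.json"
    files["ground_truth"].write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    return files


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def parse(d, time_cols=("start", "end")):
        df = pd.DataFrame(d["values"]).reindex(columns=d["columns"])
        for col in time_cols:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        return df

    return GroundTruth(toh=parse(payload["toh"]), als=parse(payload["als"]),
                       homes=pd.DataFrame(payload["homes"]))
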