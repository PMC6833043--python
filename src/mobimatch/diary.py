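"""Diary validation and self-reported daily indicators.

Two paper diaries are processed: the TOH diary (out-of-home episodes
with a device-worn flag) and the AL diary (stationary activity-location
visits with place/activity annotations). Entries are validated against
the study period and the 3-min duration floor; AL entries additionally
against the stationary / away-from-home / genuine-report flags. Every
exclusion is logged with *all* reasons that applied, so reason tallies
may exceed the excluded-entry count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DIARY_EVENT_COLUMNS = ["participant_id", "date", "kind", "source", "start", "end",
                       "duration_min"]


def _split_at_midnight(df: pd.DataFrame) -> pd.DataFrame:
    """Split events spanning midnight so daily sums are well defined."""
    rows = []
    for _, r in df.iterrows():
        start, end = r["start"], r["end"]
        cut = start.normalize() + pd.Timedelta(days=1)
        while end > cut:
            piece = r.copy()
            piece["start"], piece["end"] = start, cut
            rows.append(piece)
            start = cut
            cut = cut + pd.Timedelta(days=1)
        piece = r.copy()
        piece["start"], piece["end"] = start, end
        rows.append(piece)
    return pd.DataFrame(rows).reset_index(drop=True)


def _finalize_events(df: pd.DataFrame, kind: str, extra_cols=()) -> pd.DataFrame:
    if len(df) == 0:
        cols = DIARY_EVENT_COLUMNS + list(extra_cols)
        out = pd.DataFrame(columns=cols)
        for c in ("start", "end"):
            out[c] = pd.to_datetime(out[c])
        return out
    out = _split_at_midnight(df)
    out["date"] = out["start"].dt.normalize()
    out["kind"] = kind
    out["source"] = "REP"
    out["duration_min"] = (out["end"] - out["start"]).dt.total_seconds() / 60.0
    return out[DIARY_EVENT_COLUMNS + list(extra_cols)].reset_index(drop=True)


def _base_reasons(df, study_period, min_duration_min):
    start_p, end_p = study_period
    dur_min = (df["end"] - df["start"]).dt.total_seconds() / 60.0
    malformed = df["start"].isna() | df["end"].isna() | (df["end"] <= df["start"])
    out_of_period = (~malformed) & ((df["start"] < start_p) | (df["start"] >= end_p))
    short = (~malformed) & (dur_min <= min_duration_min)
    return malformed, out_of_period, short


def _log_from_flags(df, flag_map) -> pd.DataFrame:
    """One row per (entry, reason) for all flagged entries."""
    rows = []
    for reason, mask in flag_map.items():
        for idx in np.flatnonzero(mask.to_numpy(dtype=bool)):
            rows.append({"entry_index": int(df.index[idx]),
                         "participant_id": df["participant_id"].iloc[idx],
                         "start": df["start"].iloc[idx],
                         "reason": reason})
    return pd.DataFrame(rows, columns=["entry_index", "participant_id",
                                       "start", "reason"])


def validate_toh_entries(entries: pd.DataFrame, study_period,
                         min_duration_min: float = 3.0):
    """Validate TOH diary entries; return (events, exclusion_log).

    Drops entries outside the study period or with duration <= 3 min
    (strict survival requires > 3 min); malformed entries (missing or
    inverted times) are logged too. Retained entries become REP TOH
    events, split at midnight if spanning.
    """
    df = entries.reset_index(drop=True)
    malformed, out_of_period, short = _base_reasons(df, study_period, min_duration_min)
    flags = {"malformed": malformed,
             "outside study period": out_of_period,
             "duration <= 3 min": short}
    log = _log_from_flags(df, flags)
    excluded = malformed | out_of_period | short
    kept = df.loc[~excluded]
    extra = [c for c in ("worn_flag",) if c in df.columns]
    return _finalize_events(kept, "TOH", extra_cols=extra), log


AL_EXCLUSION_REASONS = ("outside study period", "missing start/end time",
                        "duration <= 3 min", "non-stationary/movement",
                        "at home", "false report")


def validate_al_entries(entries: pd.DataFrame, study_period,
                        min_duration_min: float = 3.0):
    """Validate AL diary entries; return (events, exclusion_log).

    An entry is excluded if *any* condition holds: outside the study
    period, missing start/end time, duration <= 3 min, flagged as
    non-stationary movement, taking place at home, or a false report.
    All applicable reasons are logged per entry.
    """
    df = entries.reset_index(drop=True)
    missing = df["start"].isna() | df["end"].isna()
    inverted = (~missing) & (df["end"] <= df["start"])
    _, out_of_period, short = _base_reasons(df, study_period, min_duration_min)

    def flag(col):
        if col not in df.columns:
            return pd.Series(False, index=df.index)
        return df[col].fillna(False).astype(bool)

    flags = {"outside study period": out_of_period,
             "missing start/end time": missing,
             "duration <= 3 min": short,
             "non-stationary/movement": ~flag("stationary")
             if "stationary" in df.columns else pd.Series(False, index=df.index),
             "at home": flag("at_home"),
             "false report": flag("false_report"),
             "malformed": inverted}
    log = _log_from_flags(df, flags)
    excluded = pd.Series(False, index=df.index)
    for mask in flags.values():
        excluded |= mask
    kept = df.loc[~excluded]
    extra = [c for c in ("place_name", "activity_type", "indoor_outdoor")
             if c in df.columns]
    return _finalize_events(kept, "AL", extra_cols=extra), log


def aggregate_daily_rep(toh_events: pd.DataFrame, al_events: pd.DataFrame,
                        participants, study_period) -> pd.DataFrame:
    """Per participant-day reported indicators over the study period.

    Days without entries score 0 (they may later be invalidated by the
    inclusion rules; a zero here is only a candidate zero-mobility day).
    """
    start_p, end_p = study_period
    dates = pd.date_range(start_p.normalize(), end_p.normalize(),
                          inclusive="left", freq="D")
    idx = pd.MultiIndex.from_product([sorted(set(participants)), dates],
                                     names=["participant_id", "date"])
    out = pd.DataFrame(index=idx)
    if len(toh_events):
        out["rep_toh_min"] = toh_events.groupby(["participant_id", "date"])[
            "duration_min"].sum()
    else:
        out["rep_toh_min"] = 0.0
    if len(al_events):
        out["rep_nals"] = al_events.groupby(["participant_id", "date"]).size()
    else:
        out["rep_nals"] = 0
    out = out.fillna(0)
    out["rep_nals"] = out["rep_nals"].astype(int)
    return out.reset_index()
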