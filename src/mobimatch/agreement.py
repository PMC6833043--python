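"""Agreement statistics between reported and GPS-derived mobility.

Covers the full comparison battery: inclusion criteria producing
matched participant-days, event-level temporal matching (precision /
recall / F1, match cardinalities, interval IoU, duration
decomposition), and day-level statistics (signed-difference summaries,
Bland-Altman limits of agreement for repeated observations per
individual, one-way intraclass correlation, pooled and within-person
Spearman correlations).

Aggregation scopes follow the reporting conventions: precision, recall
and F1 are pooled over all events of all participants, whereas IoU and
the duration decomposition are computed per participant and then
averaged. Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import InclusionConfig
from . import intervals as iv


def round_half_up_pct(x: float) -> int:
    """Integer percentage with .5 rounding away from zero (table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# inclusion criteria

def build_matched_days(daily_rep: pd.DataFrame, daily_gps: pd.DataFrame,
                       rep_toh_events: pd.DataFrame, rep_al_events: pd.DataFrame,
                       config: InclusionConfig | None = None) -> dict:
    """Apply the day/participant inclusion rules per indicator.

    A GPS day is invalid if its registration period was too short (such
    days are absent from ``daily_gps``) or the device was reported
    unworn for at least one reported out-of-home event of that day.
    A reported TOH day is invalid when no TOH was reported although at
    least one AL was; a reported AL day is invalid when no AL was
    reported although > 30 min of TOH were. Participants reporting
    events on fewer than 2 days (per diary), and participants with
    fewer than 2 matched valid days, are excluded.

    Returns ``{"toh": frame, "al": frame, "manifest": tallies}`` with
    one row per matched participant-day carrying both indicators.
    """
    config = config or InclusionConfig()
    manifest = {}

    worn_bad_days = set()
    if len(rep_toh_events) and "worn_flag" in rep_toh_events.columns:
        bad = rep_toh_events.loc[~rep_toh_events["worn_flag"].fillna(True).astype(bool)]
        worn_bad_days = set(zip(bad["participant_id"], bad["date"]))
    gps = daily_gps.copy()
    gps["gps_valid"] = [
        (pid, date) not in worn_bad_days
        for pid, date in zip(gps["participant_id"], gps["date"])]
    manifest["gps_days_registration_valid"] = int(len(gps))
    manifest["gps_days_unworn_excluded"] = int((~gps["gps_valid"]).sum())

    merged = daily_rep.merge(gps[["participant_id", "date", "gps_toh_min",
                                  "gps_nals", "gps_valid"]],
                             on=["participant_id", "date"], how="left")
    merged["gps_valid"] = merged["gps_valid"].eq(True)  # NaN (no GPS day) -> False

    def reporting_days(events):
        if len(events) == 0:
            return pd.Series(dtype=int)
        return events.groupby("participant_id")["date"].nunique()

    rep_days_toh = reporting_days(rep_toh_events)
    rep_days_al = reporting_days(rep_al_events)
    ok_reporter_toh = set(rep_days_toh[rep_days_toh >= config.min_reporting_days].index)
    ok_reporter_al = set(rep_days_al[rep_days_al >= config.min_reporting_days].index)

    merged["rep_toh_valid"] = (
        merged["participant_id"].isin(ok_reporter_toh)
        & ~((merged["rep_toh_min"] == 0) & (merged["rep_nals"] >= 1)))
    merged["rep_al_valid"] = (
        merged["participant_id"].isin(ok_reporter_al)
        & ~((merged["rep_nals"] == 0)
            & (merged["rep_toh_min"] > config.contradiction_toh_min)))
    manifest["rep_toh_days_invalid"] = int((~merged["rep_toh_valid"]).sum())
    manifest["rep_al_days_invalid"] = int((~merged["rep_al_valid"]).sum())

    out = {"manifest": manifest}
    for key, rep_flag in (("toh", "rep_toh_valid"), ("al", "rep_al_valid")):
        m = merged.loc[merged[rep_flag] & merged["gps_valid"]].copy()
        per_p = m.groupby("participant_id").size()
        keep = set(per_p[per_p >= config.min_matched_days].index)
        manifest[f"{key}_participants_included"] = len(keep)
        m = m.loc[m["participant_id"].isin(keep)]
        manifest[f"{key}_matched_days"] = int(len(m))
        out[key] = m[["participant_id", "date", "rep_toh_min", "rep_nals",
                      "gps_toh_min", "gps_nals"]].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# event-level matching

def match_events(rep_events: pd.DataFrame, gps_events: pd.DataFrame) -> pd.DataFrame:
    """Annotate events of both sources with temporal-match records.

    Two events match when their intersection has strictly positive
    duration. Each record carries the number of opposite-source
    matches, the cardinality class (1:0 / 1:1 / 1:n) and the fraction
    of the event's duration covered by opposite-source events.
    """
    frames = []
    pids = sorted(set(rep_events.get("participant_id", pd.Series(dtype=str)))
                  | set(gps_events.get("participant_id", pd.Series(dtype=str))))
    for pid in pids:
        r = rep_events.loc[rep_events["participant_id"] == pid] if len(rep_events) else rep_events
        g = gps_events.loc[gps_events["participant_id"] == pid] if len(gps_events) else gps_events
        a, b = iv.to_ns(r), iv.to_ns(g)
        m = iv.overlap_matrix(a, b)
        for side, df, axis in (("REP", r, 1), ("GPS", g, 0)):
            if len(df) == 0:
                continue
            n_matches = (m > 0).sum(axis=axis)
            overlap_ns = m.sum(axis=axis)
            dur_ns = (iv.to_ns(df)[:, 1] - iv.to_ns(df)[:, 0]).astype(float)
            rec = df.copy()
            rec["side"] = side
            rec["n_matches"] = n_matches
            rec["cardinality"] = np.select(
                [n_matches == 0, n_matches == 1], ["1:0", "1:1"], default="1:n")
            rec["overlap_fraction"] = np.where(dur_ns > 0, overlap_ns / dur_ns, 0.0)
            frames.append(rec)
    if not frames:
        return pd.DataFrame(columns=["participant_id", "date", "start", "end",
                                     "duration_min", "side", "n_matches",
                                     "cardinality", "overlap_fraction"])
    return pd.concat(frames, ignore_index=True)


def cardinality_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per side: counts and integer percentages of 1:1 / 1:n / 1:0."""
    rows = []
    for side, grp in records.groupby("side"):
        total = len(grp)
        counts = grp["cardinality"].value_counts()
        for card in ("1:1", "1:n", "1:0"):
            n = int(counts.get(card, 0))
            rows.append({"side": side, "cardinality": card, "n": n,
                         "pct": round_half_up_pct(100.0 * n / total) if total else np.nan})
        rows.append({"side": side, "cardinality": "total", "n": total, "pct": 100})
    return pd.DataFrame(rows)


def precision_recall_f1(records: pd.DataFrame) -> dict:
    """Pooled event-level precision, recall and F1.

    Recall: matched reported events / all reported events. Precision:
    matched GPS-detected events / all GPS-detected events. A zero
    denominator leaves the metric undefined (NaN, with a warning).
    """
    out = {}
    for side, name in (("REP", "recall"), ("GPS", "precision")):
        grp = records.loc[records["side"] == side]
        if len(grp) == 0:
            warnings.warn(f"{name} undefined: no {side} events")
            out[name] = float("nan")
        else:
            out[name] = float((grp["n_matches"] >= 1).mean())
    p, r = out["precision"], out["recall"]
    out["f1"] = (2 * p * r / (p + r)) if (p + r) > 0 and not (np.isnan(p) or np.isnan(r)) \
        else float("nan")
    return out


def interval_iou(rep_events: pd.DataFrame, gps_events: pd.DataFrame,
                 participants=None):
    """Per-participant intersection-over-union of event timelines.

    IoU is computed per participant over all events of all days, then
    averaged across participants; participants with zero total event
    time are excluded from the mean with a warning. The participant
    universe defaults to everyone appearing in either event frame; an
    explicit ``participants`` list catches included participants with
    no events at all.
    Returns (per-participant Series, cohort mean).
    """
    per = {}
    pids = (sorted(set(participants)) if participants is not None else
            sorted(set(rep_events.get("participant_id", pd.Series(dtype=str)))
                   | set(gps_events.get("participant_id", pd.Series(dtype=str)))))
    for pid in pids:
        a = iv.merge(iv.to_ns(rep_events.loc[rep_events["participant_id"] == pid]))
        b = iv.merge(iv.to_ns(gps_events.loc[gps_events["participant_id"] == pid]))
        union = iv.total(iv.merge(np.concatenate([a, b]) if len(a) or len(b)
                                  else np.empty((0, 2), dtype=np.int64)))
        if union == 0:
            warnings.warn(f"IoU undefined for participant {pid}: no event time")
            continue
        per[pid] = iv.total(iv.intersect(a, b)) / union
    series = pd.Series(per, dtype=float, name="iou")
    return series, (float(series.mean()) if len(series) else float("nan"))


def duration_decomposition(rep_events: pd.DataFrame, gps_events: pd.DataFrame,
                           participants=None):
    """Intersection / REP-only / GPS-only percentages of the union timeline.

    Computed per participant then averaged; each participant's three
    percentages sum to 100. Participants with zero event time are
    excluded with a warning (see ``interval_iou`` for the participant
    universe).
    Returns (per-participant frame, dict of averaged percentages).
    """
    rows = {}
    pids = (sorted(set(participants)) if participants is not None else
            sorted(set(rep_events.get("participant_id", pd.Series(dtype=str)))
                   | set(gps_events.get("participant_id", pd.Series(dtype=str)))))
    for pid in pids:
        a = iv.merge(iv.to_ns(rep_events.loc[rep_events["participant_id"] == pid]))
        b = iv.merge(iv.to_ns(gps_events.loc[gps_events["participant_id"] == pid]))
        union = iv.total(iv.merge(np.concatenate([a, b]) if len(a) or len(b)
                                  else np.empty((0, 2), dtype=np.int64)))
        if union == 0:
            warnings.warn(f"duration decomposition undefined for participant {pid}")
            continue
        inter = iv.total(iv.intersect(a, b))
        rows[pid] = {"pct_intersection": 100.0 * inter / union,
                     "pct_rep_only": 100.0 * (iv.total(a) - inter) / union,
                     "pct_gps_only": 100.0 * (iv.total(b) - inter) / union}
    per = pd.DataFrame.from_dict(rows, orient="index")
    mean = (per.mean().to_dict() if len(per)
            else {"pct_intersection": float("nan"), "pct_rep_only": float("nan"),
                  "pct_gps_only": float("nan")})
    return per, mean


# ---------------------------------------------------------------------------
# day-level statistics

def daily_difference_stats(matched: pd.DataFrame, rep_col: str, gps_col: str,
                           tolerances=()) -> dict:
    """Summaries of signed daily differences (REP minus GPS).

    Positive values indicate REP > GPS. ``sd_between`` is the sample SD
    of participants' mean daily differences; ``mean_sd_within`` the
    average of per-participant sample SDs (participants with a single
    day contribute no within-SD). Tolerance-band shares report, for
    each tolerance, the percentage of days in agreement, REP above, and
    REP below.
    """
    d = matched[rep_col] - matched[gps_col]
    by_p = d.groupby(matched["participant_id"])
    within = by_p.std(ddof=1).dropna()
    out = {"n_days": int(len(d)),
           "mean": float(d.mean()), "sd": float(d.std(ddof=1)),
           "median": float(d.median()),
           "min": float(d.min()), "max": float(d.max()),
           "sd_between": float(by_p.mean().std(ddof=1)),
           "mean_sd_within": float(within.mean()) if len(within) else float("nan"),
           "tolerance_bands": {}}
    for tol in tolerances:
        out["tolerance_bands"][tol] = {
            "pct_agree": float(100.0 * (d.abs() <= tol).mean()),
            "pct_rep_higher": float(100.0 * (d > tol).mean()),
            "pct_rep_lower": float(100.0 * (d < -tol).mean())}
    return out


def bland_altman_repeated(diffs: pd.DataFrame, diff_col: str = "diff",
                          group_col: str = "participant_id") -> dict:
    """Bland-Altman limits of agreement for repeated observations.

    The total variance of a single difference combines the
    between-participant variance of true mean differences with the
    within-participant variance, estimated from a one-way ANOVA of the
    differences by participant:

        m0     = (Σm_i − Σm_i²/Σm_i) / (n − 1)
        σ²_b   = max(0, (MSB − MSW) / m0)
        σ²_d   = σ²_b + MSW
        LOA    = d̄ ± 1.96·σ_d

    When every participant contributes a single difference the
    procedure reduces exactly to simple Bland-Altman (σ²_d = sample
    variance of the differences).
    """
    d = diffs[diff_col].to_numpy(dtype=float)
    groups = diffs[group_col]
    n_total = len(d)
    dbar = float(d.mean())
    sizes = groups.value_counts()
    n_groups = len(sizes)
    if n_total == 0:
        return {"mean_diff": float("nan"), "loa_low": float("nan"),
                "loa_high": float("nan"), "sd_total": float("nan")}
    if n_groups == n_total or n_groups == 1:
        # one observation per participant (or a single participant):
        # simple Bland-Altman
        var_d = float(np.var(d, ddof=1)) if n_total > 1 else 0.0
        var_b, var_w = float("nan"), float("nan")
    else:
        gm = diffs.groupby(group_col)[diff_col]
        means = gm.mean()
        m = sizes.reindex(means.index).to_numpy(dtype=float)
        msb = float((m * (means.to_numpy() - dbar) ** 2).sum() / (n_groups - 1))
        ssw = float(((diffs[diff_col] - means.reindex(groups).to_numpy()) ** 2).sum())
        msw = ssw / (n_total - n_groups)
        m0 = (m.sum() - (m ** 2).sum() / m.sum()) / (n_groups - 1)
        var_b = max(0.0, (msb - msw) / m0)
        var_w = msw
        var_d = var_b + var_w
    sd = math.sqrt(var_d)
    return {"mean_diff": dbar, "loa_low": dbar - 1.96 * sd,
            "loa_high": dbar + 1.96 * sd, "sd_total": sd,
            "var_between": var_b, "var_within": var_w}


def icc_oneway(x, y, alpha: float = 0.05) -> dict:
    """One-way random-effects intraclass correlation for paired values.

    Each participant-day is a unit with k = 2 measurements (REP, GPS):
    ICC(1) = (MSB − MSW) / (MSB + MSW), with the confidence interval
    from the F distribution. Identical columns give exactly 1.0; zero
    between-unit variance can give a negative estimate, reported as-is.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        return {"icc": float("nan"), "ci_low": float("nan"), "ci_high": float("nan")}
    k = 2
    data = np.stack([x, y], axis=1)
    unit_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * float(((unit_means - grand) ** 2).sum()) / (n - 1)
    msw = float(((data - unit_means[:, None]) ** 2).sum()) / (n * (k - 1))
    if msw == 0.0:
        if msb == 0.0:
            return {"icc": float("nan"), "ci_low": float("nan"),
                    "ci_high": float("nan")}
        return {"icc": 1.0, "ci_low": 1.0, "ci_high": 1.0}
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    return {"icc": float(icc),
            "ci_low": float((fl - 1) / (fl + k - 1)),
            "ci_high": float((fu - 1) / (fu + k - 1))}


def correlations(matched: pd.DataFrame, rep_col: str, gps_col: str,
                 min_days: int = 3) -> dict:
    """Pooled Spearman rho plus within-person (iCorr) mean and SD.

    iCorr is computed per participant across their own days (skipped
    below ``min_days`` days or when either column is constant, with a
    warning), then summarised across participants.
    """
    if len(matched) < 2:
        pooled = float("nan")
    else:
        pooled = float(stats.spearmanr(matched[rep_col], matched[gps_col]).statistic)
    icorrs = {}
    for pid, grp in matched.groupby("participant_id"):
        if len(grp) < min_days:
            continue
        if grp[rep_col].nunique() < 2 or grp[gps_col].nunique() < 2:
            warnings.warn(f"iCorr skipped for {pid}: constant indicator values")
            continue
        icorrs[pid] = float(stats.spearmanr(grp[rep_col], grp[gps_col]).statistic)
    s = pd.Series(icorrs, dtype=float)
    return {"spearman_pooled": pooled,
            "icorr_mean": float(s.mean()) if len(s) else float("nan"),
            "icorr_sd": float(s.std(ddof=1)) if len(s) > 1 else float("nan"),
            "n_icorr": int(len(s))}


def event_characteristics(rep_records: pd.DataFrame,
                          label_cols=("activity_type", "indoor_outdoor")) -> dict:
    """Detection summaries of reported AL events by reported labels.

    For each label value: event count, percentage with at least one
    matching GPS event, median reported duration, and mean overlap
    fraction — except for 'unassignable' entries, whose rates are not
    meaningful and are left blank. Also reports Spearman correlations
    of reported duration with detection (binary) and with overlap
    fraction.
    """
    rec = rep_records.loc[rep_records["side"] == "REP"].copy()
    rec["matched"] = (rec["n_matches"] >= 1).astype(int)
    tables = {}
    for col in label_cols:
        if col not in rec.columns:
            continue
        rows = []
        for value, grp in rec.groupby(col):
            if len(grp) == 0:
                continue
            blank = value == "unassignable"
            rows.append({
                col: value, "n_events": int(len(grp)),
                "pct_matched": float("nan") if blank
                else 100.0 * float(grp["matched"].mean()),
                "median_duration_min": float("nan") if blank
                else float(grp["duration_min"].median()),
                "mean_overlap_pct": float("nan") if blank
                else 100.0 * float(grp["overlap_fraction"].mean())})
        tables[col] = pd.DataFrame(rows).sort_values(
            "pct_matched", ascending=False, na_position="last").reset_index(drop=True)
    corr = {}
    usable = rec if len(rec) >= 3 else rec.iloc[0:0]
    for name, target in (("rho_duration_detected", "matched"),
                         ("rho_duration_overlap", "overlap_fraction")):
        if len(usable) and usable["duration_min"].nunique() > 1 \
                and usable[target].nunique() > 1:
            corr[name] = float(stats.spearmanr(usable["duration_min"],
                                               usable[target]).statistic)
        else:
            corr[name] = float("nan")
    return {"tables": tables, "correlations": corr}


# ---------------------------------------------------------------------------
# report assembly

def agreement_report(rep_events: pd.DataFrame, gps_events: pd.DataFrame,
                     matched_daily: pd.DataFrame, rep_col: str, gps_col: str,
                     tolerances=()) -> dict:
    """Full event- and day-level agreement report for one indicator."""
    records = match_events(rep_events, gps_events)
    prf = precision_recall_f1(records) if len(records) else \
        {"precision": float("nan"), "recall": float("nan"), "f1": float("nan")}
    _, iou_mean = interval_iou(rep_events, gps_events)
    _, split = duration_decomposition(rep_events, gps_events)
    diffs = matched_daily.assign(diff=matched_daily[rep_col] - matched_daily[gps_col])
    ba = bland_altman_repeated(diffs)
    icc = icc_oneway(matched_daily[rep_col], matched_daily[gps_col])
    corr = correlations(matched_daily, rep_col, gps_col)
    dstats = daily_difference_stats(matched_daily, rep_col, gps_col, tolerances)
    return {"precision": prf["precision"], "recall": prf["recall"], "f1": prf["f1"],
            "iou_mean": iou_mean, "duration_split": split,
            "bland_altman": ba, "icc": icc, "correlations": corr,
            "daily_differences": dstats,
            "cardinality": cardinality_table(records) if len(records) else None,
            "match_records": records}
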