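"""End-to-end orchestration of the comparison pipeline.

Stages: GPS ingest (outlier removal, day segmentation, day validity),
home resolution, diary validation, GPS event extraction, daily
aggregation, inclusion criteria, and agreement statistics. A run
manifest records counts at every exclusion step so that inputs equal
retained plus excluded records throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, diary, events, home, ingest
from .config import InclusionConfig, PipelineConfig, ThresholdSet


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PreparedCohort:
    """Threshold-independent intermediate state of a pipeline run.

    Everything up to (and excluding) GPS event extraction: filtered
    fixes with day assignments, day validity, resolved homes, validated
    diary events and daily reported indicators. Event extraction and
    agreement can then be re-evaluated cheaply for many threshold
    settings, as the sensitivity analysis requires.
    """

    day_fixes: pd.DataFrame
    days: pd.DataFrame
    homes_resolved: pd.DataFrame
    rep_toh_events: pd.DataFrame
    rep_al_events: pd.DataFrame
    daily_rep: pd.DataFrame
    study_period: tuple
    inclusion: InclusionConfig
    noise_move_min: float = 3.0
    manifest: dict = field(default_factory=dict)
    toh_log: pd.DataFrame | None = None
    al_log: pd.DataFrame | None = None


def prepare_cohort(fixes: pd.DataFrame, toh_diary: pd.DataFrame,
                   al_diary: pd.DataFrame, homes_df: pd.DataFrame,
                   study_period, config: PipelineConfig | None = None) -> PreparedCohort:
    """Run all threshold-independent stages on in-memory inputs."""
    config = config or PipelineConfig()
    manifest = {"n_fixes_raw": int(len(fixes))}
    try:
        filtered = ingest.remove_speed_outliers(fixes, config.vmax_kmh)
        manifest["n_fixes_after_outliers"] = int(len(filtered))
        manifest["n_fixes_outliers_removed"] = int(len(fixes) - len(filtered))
        day_fixes = ingest.segment_days(filtered)
        days, eligible = ingest.flag_valid_days(
            day_fixes, config.min_registration_hours, config.min_valid_days)
        manifest["n_days_total"] = int(len(days))
        manifest["n_days_valid_registration"] = int(days["is_valid"].sum())
        manifest["n_participants_gps_eligible"] = int(eligible.sum())
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"gps_ingest: {exc}") from exc

    try:
        if homes_df is None or len(homes_df) == 0:
            raise ValueError("no home addresses provided")
        eligible_ids = set(eligible[eligible].index)
        homes_resolved = home.resolve_homes(
            day_fixes, days, homes_df.loc[homes_df["participant_id"].isin(eligible_ids)],
            eps_m=config.home_eps_m, min_pts=config.home_min_pts,
            max_home_distance_m=config.home_max_distance_m)
        manifest["n_homes_resolved_valid"] = int(homes_resolved["is_valid"].sum())
        manifest["n_homes_resolved_invalid"] = int((~homes_resolved["is_valid"]).sum())
    except Exception as exc:
        raise StageError(f"home_detection: {exc}") from exc

    try:
        rep_toh, toh_log = diary.validate_toh_entries(
            toh_diary, study_period, config.diary_min_duration_min)
        rep_al, al_log = diary.validate_al_entries(
            al_diary, study_period, config.diary_min_duration_min)
        manifest["toh_entries_in"] = int(len(toh_diary))
        manifest["toh_entries_retained"] = int(len(toh_diary) - toh_log["entry_index"].nunique())
        manifest["toh_exclusion_reasons"] = int(len(toh_log))
        manifest["al_entries_in"] = int(len(al_diary))
        manifest["al_entries_retained"] = int(len(al_diary) - al_log["entry_index"].nunique())
        manifest["al_exclusion_reasons"] = int(len(al_log))
        participants = sorted(set(fixes["participant_id"]) | set(toh_diary.get(
            "participant_id", pd.Series(dtype=str))) | set(al_diary.get(
                "participant_id", pd.Series(dtype=str))))
        daily_rep = diary.aggregate_daily_rep(rep_toh, rep_al, participants, study_period)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"diary_processing: {exc}") from exc

    return PreparedCohort(day_fixes=day_fixes, days=days,
                          homes_resolved=homes_resolved,
                          rep_toh_events=rep_toh, rep_al_events=rep_al,
                          daily_rep=daily_rep, study_period=study_period,
                          inclusion=config.inclusion,
                          noise_move_min=config.noise_move_min,
                          manifest=manifest, toh_log=toh_log, al_log=al_log)


def _restrict(events_df: pd.DataFrame, matched_days: pd.DataFrame) -> pd.DataFrame:
    if len(events_df) == 0 or len(matched_days) == 0:
        return events_df.iloc[0:0]
    keys = set(zip(matched_days["participant_id"], matched_days["date"]))
    mask = [(p, d) in keys for p, d in zip(events_df["participant_id"],
                                           events_df["date"])]
    return events_df.loc[mask]


def evaluate_thresholds(prep: PreparedCohort, thresholds: ThresholdSet,
                        full: bool = False) -> dict:
    """GPS extraction + inclusion + agreement for one threshold setting.

    With ``full=False`` returns only the four sensitivity series
    (pooled F1 and mean IoU for TOH and for ALs); with ``full=True``
    the complete per-indicator agreement reports and intermediate
    frames.
    """
    toh_gps, al_gps = events.extract_gps_events(
        prep.day_fixes, prep.days, prep.homes_resolved, thresholds,
        prep.noise_move_min)
    daily_gps = events.aggregate_daily_gps(toh_gps, al_gps, prep.days)
    matched = agreement.build_matched_days(
        prep.daily_rep, daily_gps, prep.rep_toh_events, prep.rep_al_events,
        prep.inclusion)
    out = {"thresholds": thresholds, "matched": matched, "daily_gps": daily_gps,
           "gps_toh_events": toh_gps, "gps_al_events": al_gps}
    for key, rep_ev, gps_ev, rep_col, gps_col, tols in (
            ("toh", prep.rep_toh_events, toh_gps, "rep_toh_min", "gps_toh_min",
             prep.inclusion.toh_tolerance_min),
            ("al", prep.rep_al_events, al_gps, "rep_nals", "gps_nals",
             prep.inclusion.al_tolerance)):
        m_days = matched[key]
        rep_m = _restrict(rep_ev, m_days)
        gps_m = _restrict(gps_ev, m_days)
        if full:
            out[key] = agreement.agreement_report(rep_m, gps_m, m_days,
                                                  rep_col, gps_col, tols)
        else:
            records = agreement.match_events(rep_m, gps_m)
            prf = (agreement.precision_recall_f1(records) if len(records)
                   else {"f1": float("nan")})
            _, iou_mean = agreement.interval_iou(rep_m, gps_m)
            out[key] = {"f1": prf["f1"], "iou_mean": iou_mean}
    out["series"] = {"f1_toh": out["toh"]["f1"], "iou_toh": out["toh"]["iou_mean"],
                     "f1_al": out["al"]["f1"], "iou_al": out["al"]["iou_mean"]}
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (pd.Timestamp, np.datetime64)):
        return pd.Timestamp(obj).isoformat()
    if isinstance(obj, ThresholdSet):
        return {"tmin_min": obj.tmin_min, "dmax_m": obj.dmax_m,
                "tmax_min": obj.tmax_min}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(fixes: pd.DataFrame, toh_diary: pd.DataFrame,
                 al_diary: pd.DataFrame, homes_df: pd.DataFrame,
                 study_period, config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Full deterministic pipeline run; optionally writes artifacts.

    Returns the result bundle (reports, frames, manifest); when
    ``out_dir`` is given, writes ``homes_resolved.csv``,
    ``events_gps.csv``, ``daily_indicators.csv``, ``match_table.csv``,
    ``exclusion_log.csv``, ``agreement_report.json`` and
    ``manifest.json``.
    """
    config = config or PipelineConfig()
    prep = prepare_cohort(fixes, toh_diary, al_diary, homes_df, study_period, config)
    toh_log, al_log = prep.toh_log, prep.al_log
    result = evaluate_thresholds(prep, config.thresholds, full=True)
    matched = result["matched"]
    manifest = dict(prep.manifest)
    manifest.update(matched["manifest"])
    manifest["thresholds"] = _jsonable(config.thresholds)

    daily = prep.daily_rep.merge(result["daily_gps"], on=["participant_id", "date"],
                                 how="outer")
    bundle = {"prep": prep, "result": result, "manifest": manifest,
              "daily_indicators": daily,
              "exclusion_log": pd.concat(
                  [toh_log.assign(diary="TOH"), al_log.assign(diary="AL")],
                  ignore_index=True)}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prep.homes_resolved.to_csv(out_dir / "homes_resolved.csv", index=False)
        gps_events = pd.concat([result["gps_toh_events"], result["gps_al_events"]],
                               ignore_index=True)
        gps_events.to_csv(out_dir / "events_gps.csv", index=False)
        daily.to_csv(out_dir / "daily_indicators.csv", index=False)
        match_frames = [result[k]["match_records"].assign(indicator=k.upper())
                        for k in ("toh", "al") if len(result[k]["match_records"])]
        (pd.concat(match_frames, ignore_index=True) if match_frames
         else pd.DataFrame()).to_csv(out_dir / "match_table.csv", index=False)
        bundle["exclusion_log"].to_csv(out_dir / "exclusion_log.csv", index=False)
        report = {k: {kk: vv for kk, vv in result[k].items()
                      if kk != "match_records"} for k in ("toh", "al")}
        report["inclusion"] = matched["manifest"]
        (out_dir / "agreement_report.json").write_text(
            json.dumps(_jsonable(report), indent=1))
        (out_dir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    return bundle
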