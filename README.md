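# mobimatch

**Agreement between self-reported and GPS-derived daily mobility
indicators in older adults.**

Daily mobility — how much time a person spends out of home and how many
places they visit — is a widely used marker of healthy aging. Two
instruments dominate its assessment: paper travel diaries
(self-reports, "REP") and wearable GPS logging. Both are imperfect:
diaries suffer omissions, rounding and recall errors; GPS suffers
signal loss, positional noise and threshold-dependent event detection.
`mobimatch` implements, as a tested and reusable pipeline, the full
comparison of the two instruments for two daily indicators:

* **TOH** — time out of home (minutes per day), via a circular
  geofence of radius *Dmax* around the residence, with event-level
  temporal interpolation of data gaps up to *Tmax* and a minimum event
  duration *Tmin*;
* **#ALs** — number of activity locations (stationary out-of-home
  visits per day), via sequential time-based stop detection (a cluster
  grows from its anchor fix while fixes stay within *Dmax* and
  inter-fix gaps within *Tmax*, and is a stop if it spans ≥ *Tmin*),
  with noise merging and home-stop exclusion.

The package covers every stage: GPS ingest (CSV/GPX, 330 km/h
plausibility filtering, midnight day segmentation, 9-h registration
validity), DBSCAN-based home validation, diary validation with full
exclusion bookkeeping, day/participant inclusion rules, event-level
agreement (precision/recall/F1, match cardinalities, interval IoU,
duration decomposition), day-level agreement (Bland-Altman for
repeated observations per individual, one-way ICC, pooled and
within-person Spearman correlations), and a stepwise sensitivity
analysis of (*Tmin*, *Dmax*, *Tmax*). Because raw study data of this
kind are rarely shareable, a synthetic-cohort generator with known
ground truth makes every stage testable.

## Worked example

Simulate a one-week cohort, run the full comparison, and optimize the
thresholds:

```bash
mobimatch simulate --out-dir cohort --participants 5 --days 7 --seed 3
mobimatch run-all --in-dir cohort --out-dir results \
    --study-start 2023-05-01 --study-days 7
```

The `run-all` command prints, for this seed:

```
TOH: F1=0.968 IoU=0.907 BA mean diff=-4.56 ICC=0.975
AL: F1=0.932 IoU=0.770 BA mean diff=-0.29 ICC=0.938
optimized thresholds: Tmin=4 min, Dmax=75 m, Tmax=60 min
```

Reading: event-level agreement between the two instruments is high —
96.8 % harmonic mean of precision and recall for TOH events and 90.7 %
temporal overlap (intersection over union of the two event timelines,
averaged over participants). At the day level, reported TOH is on
average 4.6 min *below* the GPS value (Bland-Altman mean difference,
REP − GPS), and the intraclass correlation of 0.975 indicates that
day-to-day variation is captured consistently by both instruments.
The stepwise sensitivity analysis, started from the literature setting
(*Tmin* = 3 min, *Tmax* = 1 h, *Dmax* = 100 m), lands on smaller
thresholds than the defaults here: this synthetic cohort has only
10 m of positional noise and little signal loss, so its agreement
curves plateau early and ties break toward the most conservative
(smallest) value. Noisier conditions push the selection toward the
default plateau (see the parameter-recovery battery in
`tests/test_acceptance.py`).

`results/` then contains `agreement_report.json` (all statistics),
`daily_indicators.csv`, `match_table.csv`, `events_gps.csv`,
`homes_resolved.csv`, `exclusion_log.csv`, `sensitivity_curves.csv`,
`optimal_thresholds.json` and a run `manifest.json` whose counts
conserve inputs = retained + excluded at every filtering step.

The same workflow is available as a library (`simulate_cohort`,
`prepare_cohort`, `evaluate_thresholds`, `stepwise_optimize`, …); see
`docs/methods.md` for the underlying models and conventions.

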