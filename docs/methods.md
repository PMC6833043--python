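# Methods

This note documents the models, conventions and design choices behind
`mobimatch`: what each pipeline stage computes, which parameters
matter, what the synthetic cohort does and does not emulate, and the
numerical decisions a user re-implementing or auditing the pipeline
would need.

## Indicators and event model

Two daily indicators are compared between self-reports (REP) and GPS:

* **Time out of home (TOH)**, minutes per day: the summed duration of
  out-of-home events.
* **Number of activity locations (#ALs)**: the count of stationary
  out-of-home visits per day.

All events are closed-open time intervals `[start, end)`. Days are
segmented at midnight with the half-open convention `[00:00, 24:00)`
(a fix at exactly midnight opens the new day), so events never span
midnight; overnight diary entries are split at the boundary.
Timestamps are local civil time without DST modelling, because diaries
are written in local clock time and the two sources must align.

## GPS processing

1. **Plausibility filter.** Fixes implying speeds above `vmax_kmh`
   (default 330 km/h, the regional high-speed-rail ceiling) are
   removed by a forward scan anchored on the *last retained* fix, so a
   burst of consecutive jumps is removed entirely. Anchoring on the
   raw predecessor would re-admit the second of two jumps; the chosen
   rule is idempotent and robust to bursts.
2. **Day validity.** The registration period is the time between the
   first and last fix of a day; days under 9 h are invalid, and
   participants need at least 2 valid days.
3. **Home validation.** DBSCAN (haversine metric, eps = 60 m,
   min_samples = 3) clusters the first-morning and last-evening fixes
   of all valid days ("anchor fixes" — interpreted as the first and
   last fix of each day). Cluster centres are coordinate-wise medians;
   the centre nearest the geocoded address wins (ties: larger
   membership, then lexicographically smaller centre — deterministic).
   A home is valid if that centre lies within 150 m of the address.
   The GPS-derived centre replaces the address only when *strictly*
   more of the participant's fixes fall within a 60-m buffer of it
   than of the address; ties conservatively keep the address.
4. **TOH extraction.** Each fix is labelled home/out-of-home (OH) by a
   geofence of radius *Dmax* around the resolved home; the boundary is
   inclusive (distance = *Dmax* counts as home), and the same
   inclusive rule is reused for home-stop exclusion. Maximal
   same-state runs become episodes. A data gap of at most *Tmax*
   flanked by the same state on both sides is absorbed into the
   episode (event-level temporal interpolation); a longer gap, or any
   inter-fix interval flanked by unequal states, is unobserved (GAP)
   time. No interpolation is performed into unobserved time at the day
   edges. OH episodes of at least *Tmin* become TOH events; shorter OH
   excursions are relabelled home and re-merged with their
   surroundings (they are observed time, not gaps). Short home
   episodes inside OH are *not* suppressed — *Tmin* is defined for OH
   events and stops only. Consequently, per day, HOME + TOH + GAP
   durations tile the registration period exactly (a tested
   invariant).
5. **AL extraction.** Sequential time-based stop detection: a cluster
   opens at an anchor fix; a subsequent fix joins iff its distance to
   the anchor is ≤ *Dmax* and its gap to the immediately preceding fix
   is ≤ *Tmax*. On violation the cluster closes: it is a stop if its
   time span is ≥ *Tmin*, else its fixes are released as movement.
   A stop is represented by the coordinate-wise median of its member
   fixes (even counts: mean of the two middle order statistics, per
   coordinate) and the interval from its first to its last member fix.
   Movement episodes under 3 min are treated as noise (3 min is the
   conventional minimum move duration); two stops separated only by
   noise and/or gaps merge when their medians are closer than *Dmax*
   and the inter-stop time is below *Tmax*, recomputing the median
   over the union of member fixes, applied left-to-right to a fixed
   point (deterministic and order-insensitive for chains). After
   merging, member fixes may exceed *Dmax* from the original anchor;
   the constraint binds only at clustering time. Stops whose median
   lies within *Dmax* of home are excluded; the rest are ALs.

## Diary processing

TOH entries are dropped when outside the study period or lasting
≤ 3 min (survival strictly requires > 3 min, as instructed to
participants). AL entries are additionally dropped when start/end
times are missing, the entry is flagged non-stationary, took place at
home, or is a false report. Every exclusion is logged with *all*
reasons that applied, so reason tallies can exceed excluded-entry
counts. Activity categories (work, commercial, social, personal care,
culture/religion/education, recreation, transportation, unassignable)
are taken as given input labels; free-text classification is out of
scope.

## Inclusion rules

A GPS day is invalid if registration was under 9 h or the device was
reported unworn for any reported out-of-home event that day. A
reported TOH day is contradictory (invalid) when no TOH was reported
but at least one AL was; a reported AL day when no AL was reported but
more than 30 min of TOH were. Participants reporting events on fewer
than 2 days (per diary) and participants with fewer than 2 matched
valid days are excluded. Comparisons use only matched participant-days
(both sides valid).

## Agreement statistics

* **Event matching.** Two events match when their intersection is
  strictly positive; abutting intervals do not match (exact under the
  half-open convention). Each event gets a match cardinality
  (1:0 / 1:1 / 1:n).
* **Precision / recall / F1** are pooled over all events of all
  participants (recall = matched reported events over all reported;
  precision = matched GPS events over all GPS events), whereas **IoU**
  (intersection over union of the merged REP and GPS timelines) and
  the **duration decomposition** (intersection %, REP-only %,
  GPS-only %) are computed per participant and then averaged — two
  deliberately different aggregation scopes, kept as conventionally
  reported. Undefined cases (zero denominators, zero event time) are
  reported missing with warnings, never silently zero.
* **Daily differences** are signed REP − GPS. Sample (n−1) SDs are
  used throughout; the between-participant SD is the SD of participant
  mean differences, the within-participant SD the mean of per-person
  SDs. Tolerance bands report the share of days agreeing within
  ±10/±20 min (TOH) or ±0/±1 locations (#ALs).
* **Bland-Altman for repeated observations.** With differences grouped
  by participant (sizes mᵢ, n participants, N days):
  `m₀ = (Σmᵢ − Σmᵢ²/Σmᵢ)/(n−1)`, `σ²_b = max(0, (MSB − MSW)/m₀)`,
  `σ²_d = σ²_b + MSW`, LOA = d̄ ± 1.96·σ_d. Negative between-variance
  estimates are truncated at zero. With one observation per
  participant the procedure reduces exactly to simple Bland-Altman —
  a tested identity.
* **ICC.** One-way random-effects ICC(1) with k = 2 measurements per
  participant-day: `(MSB − MSW)/(MSB + MSW)`, CI from the F
  distribution. The one-way form is used because neither source is
  treated as a fixed rater; identical columns return exactly 1.0, and
  negative estimates are reported as-is. Cross-checked against
  pingouin's ICC(1,1) in the tests.
* **Correlations.** Pooled Spearman over all matched days, plus iCorr:
  per-participant Spearman over that person's days (skipped below 3
  days or for constant columns, with a warning), then mean/SD across
  participants.
* Report-table percentages are rounded half-up to integers.

## Sensitivity analysis

Each threshold is varied over a grid while the other two are held
fixed; the stepwise order is *Tmax* → *Tmin* → *Dmax* → *Tmin*
(re-confirmation) → *Tmax* (re-confirmation), starting from the
literature setting *Tmin* = 3 min, *Tmax* = 60 min, *Dmax* = 100 m.
Where a human would select thresholds by visual inspection of the
agreement curves, the implementation uses an explicit scalar
objective — the unweighted mean of the four series (F1 and IoU for
both indicators), overridable by weights — with ties broken toward
the smallest (most conservative) threshold. Default grids span the
ranges in common use: *Tmax* ∈ {10…420} min, *Tmin* ∈ {2…15} min,
*Dmax* ∈ {25…500} m. Inclusion criteria are re-applied identically at
every grid point. The stepwise objective never deteriorates on the
evaluated grid (tested).

## Synthetic cohort

The generator emulates a one-week study in which older adults carry a
1-Hz-capable GPS logger during waking hours and keep two diaries. Per
participant-day it draws a Poisson number of outings (mean 1.8) within
an 08:00–21:30 scheduling window; each outing contains a Poisson
number (mean 1.5) of stationary visits at destinations 0.4–2.5 km from
home and at least 400 m apart, with visit durations 8 min + log-normal
(median ≈ 38 min) and constant-speed (1.4 m s⁻¹) great-circle travel
between places. Outings without visits are round-trip walks with
log-normal duration. These rates reproduce daily indicator levels
around 4 h out of home and 2–3 visits per day, the magnitudes typical
for community-dwelling older adults. The 8-min floor on visit
durations keeps every true visit clearly above both the 3-min diary
validity rule and the default *Tmin* — the separation the error-free
validation limit presupposes.

GPS error processes: isotropic Gaussian positional noise (default
10 m) applied in a local metric frame at the home latitude; bursty
indoor signal loss — a two-state alternating-run process over indoor
fixes whose stationary dropped fraction is `indoor_loss_prob` (default
0.3) and whose mean loss burst is ~10 min, producing the contiguous
multi-minute gaps that temporal interpolation exists for (i.i.d.
per-fix drops would create only single-sample gaps); and device-off
windows (default overnight, 22:30–07:30). Sampling defaults to one fix
per 10 s to keep runtimes small; 1 s reproduces the original logging
rate. Diary errors: per-entry omission (default 0.1), Gaussian
start/end shifts (SD 5 min), and rounding to 5-min clock times; with
all error parameters zero the diaries equal ground truth exactly, and
equal configurations (including seed) are byte-reproducible.

Not emulated: transport modes, multi-storey or urban-canyon GPS
artefacts, diary fabrication (non-stationary/at-home/false entries —
the validation rules for these are exercised with hand-built cases),
unworn-device episodes, and multi-residence or mid-study relocation.
Passing the synthetic batteries therefore demonstrates correctness of
the algorithms under the modelled error processes, not performance on
any particular real deployment.

## Validation batteries and problem sizes

* **Error-free limit:** 5 participants × 7 days at 5-s sampling with
  all error processes off, thresholds compatible with the generator
  (*Tmin* = 6 min, *Dmax* = 10 m, *Tmax* = 300 min). The only REP/GPS
  boundary discrepancy is then geofence-crossing time (*Dmax* / 1.4
  m s⁻¹) plus one sampling interval per event edge (~12 s), so
  event-level F1 is exactly 1.0 and per-participant IoU ≥ 0.99.
* **Oracle equivalence:** stop detection against an exhaustive greedy
  segmentation oracle and interval IoU against a minute-grid
  rasterization oracle, 100 random instances each.
* **Statistical reductions:** exact single-observation Bland-Altman
  reduction; exact ICC = 1 for identical columns; Bland-Altman total
  variance recovered within 10 % of the generating σ²_b + σ²_w on a
  balanced 3 × 4 simulation averaged over 1000 replicates.
* **Parameter recovery:** stepwise optimization on ten seeded cohorts
  (4 participants × 4 days, 30-s sampling, 30-m noise, visits
  ≥ 10 min) recovers *Dmax* within one grid step of the ~100–150 m
  spatial footprint implied by the noise scale, and *Tmin* at or below
  the true minimum visit duration, in at least 7 of 10 cohorts.

## Known limitations

* Anchor-based sequential stop detection inherits the usual
  sensitivity to the anchor fix under heavy noise; density-based
  alternatives are out of scope.
* The "first morning / last evening" anchor definition uses the first
  and last fix of each valid day, not fixed clock windows.
* Whether temporal interpolation should apply symmetrically to home
  and out-of-home states is ambiguous in common usage; it is applied
  symmetrically here (the binary-state formulation).
* The scalar sensitivity objective replaces human curve inspection;
  different weightings can shift plateau selections by one grid step.
* Diary validity flags (stationary, at-home, false report) are trusted
  as given; no spatial cross-checking of reported place names against
  GPS positions is performed.
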