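"""Stepwise threshold sensitivity analysis.

Agreement between reported and GPS-derived indicators is traced as a
function of each extraction threshold while the other two are held
fixed, then the thresholds are optimized stepwise in the order
Tmax → Tmin → Dmax → Tmin (re-confirmation) → Tmax (re-confirmation),
each step carrying the previous selections forward.

Selection replaces visual curve inspection with an explicit scalar
objective: the unweighted mean of the four agreement series (pooled F1
and mean IoU, for TOH and for ALs); ties break toward the smallest
threshold (the most conservative event definition). Custom series
weights may be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import INITIAL_THRESHOLDS, ConfigurationError, ThresholdSet
from .pipeline import PreparedCohort, evaluate_thresholds

SERIES = ("f1_toh", "iou_toh", "f1_al", "iou_al")

#: Default grids spanning the ranges in common use for stop/home
#: detection (minutes for Tmin/Tmax, metres for Dmax).
DEFAULT_GRIDS = {
    "Tmax": (10.0, 30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0, 420.0),
    "Tmin": tuple(float(v) for v in range(2, 16)),
    "Dmax": (25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 250.0, 300.0,
             400.0, 500.0),
}


@dataclass(frozen=True)
class SensitivityGrid:
    parameter: str               # "Tmax" | "Tmin" | "Dmax"
    values: tuple
    fixed: ThresholdSet

    def __post_init__(self):
        if self.parameter not in ("Tmax", "Tmin", "Dmax"):
            raise ConfigurationError(f"unknown parameter {self.parameter!r}")
        vals = tuple(self.values)
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ConfigurationError("grid values must be strictly increasing")


def agreement_curve(prep: PreparedCohort, grid: SensitivityGrid) -> pd.DataFrame:
    """F1 and IoU for both indicators at every grid value.

    Event extraction and the inclusion criteria are re-applied
    identically at each point. A grid value that makes extraction
    degenerate yields a missing point with a warning.
    """
    rows = []
    for value in grid.values:
        try:
            thresholds = grid.fixed.with_value(grid.parameter, value)
            res = evaluate_thresholds(prep, thresholds)
            series = res["series"]
        except ConfigurationError as exc:
            warnings.warn(f"{grid.parameter}={value}: {exc}; point skipped")
            series = {s: float("nan") for s in SERIES}
        rows.append({"parameter": grid.parameter, "value": float(value), **series})
    return pd.DataFrame(rows)


def _objective(row, weights=None) -> float:
    w = weights or {s: 1.0 for s in SERIES}
    vals = [(row[s], w.get(s, 1.0)) for s in SERIES if not np.isnan(row[s])]
    if not vals:
        return float("nan")
    return sum(v * wt for v, wt in vals) / sum(wt for _, wt in vals)


def stepwise_optimize(prep: PreparedCohort, grids: dict | None = None,
                      initial: ThresholdSet = INITIAL_THRESHOLDS,
                      weights: dict | None = None) -> dict:
    """Stepwise threshold optimization with re-confirmation.

    Returns ``{"thresholds": ThresholdSet, "curves": frame,
    "steps": [...], "reconfirmation_changed": bool}``. Deterministic:
    the same cohort and grids always select the same thresholds.
    """
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    current = initial
    step_order = ("Tmax", "Tmin", "Dmax", "Tmin", "Tmax")
    all_curves = []
    steps = []
    first_pick = {}
    changed = False
    for step_no, parameter in enumerate(step_order, start=1):
        grid = SensitivityGrid(parameter=parameter,
                               values=tuple(grids[parameter]), fixed=current)
        curve = agreement_curve(prep, grid)
        curve["objective"] = [_objective(r, weights) for _, r in curve.iterrows()]
        curve["step"] = step_no
        all_curves.append(curve)
        finite = curve.dropna(subset=["objective"])
        if len(finite) == 0:
            warnings.warn(f"step {step_no} ({parameter}): objective undefined "
                          "everywhere; keeping current value")
            best_value = {"Tmax": current.tmax_min, "Tmin": current.tmin_min,
                          "Dmax": current.dmax_m}[parameter]
        else:
            best = finite["objective"].max()
            # smallest maximizing value (tie-break toward conservative)
            best_value = float(finite.loc[finite["objective"] >= best - 1e-12,
                                          "value"].min())
        if parameter in first_pick and best_value != first_pick[parameter]:
            changed = True
        first_pick.setdefault(parameter, best_value)
        current = current.with_value(parameter, best_value)
        steps.append({"step": step_no, "parameter": parameter,
                      "selected": best_value})
    return {"thresholds": current,
            "curves": pd.concat(all_curves, ignore_index=True),
            "steps": steps, "reconfirmation_changed": changed}
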