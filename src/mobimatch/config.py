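"""Configuration types shared across the pipeline.

The defaults encode the study protocol this package operationalises:
a 330 km/h speed ceiling for plausibility filtering, 9 h minimum daily
registration, DBSCAN home validation at eps = 60 m / 3 points with a
150 m address-agreement limit, a 3-min floor for diary entries and for
the move/noise distinction, and event-extraction thresholds
Tmin = 6 min, Dmax = 125 m, Tmax = 300 min (the values a stepwise
sensitivity analysis selects as jointly optimal for both indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised when a configuration field is out of its valid domain."""


@dataclass(frozen=True)
class ThresholdSet:
    """The (Tmin, Dmax, Tmax) triple governing GPS event extraction.

    tmin_min
        Minimum duration (minutes) of an out-of-home episode or stop
        cluster to count as a valid event.
    dmax_m
        Spatial extent (metres): the home-buffer radius for
        time-out-of-home, and the maximum distance of a fix from a stop
        cluster's anchor fix.
    tmax_min
        Maximum data gap (minutes) bridged by event-level temporal
        interpolation.
    """

    tmin_min: float = 6.0
    dmax_m: float = 125.0
    tmax_min: float = 300.0

    def __post_init__(self):
        for name in ("tmin_min", "dmax_m", "tmax_min"):
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigurationError(f"{name} must be strictly positive, got {v!r}")
        if self.tmin_min >= 24 * 60:
            raise ConfigurationError(f"tmin_min must be below 24 h, got {self.tmin_min!r}")

    def with_value(self, parameter: str, value: float) -> "ThresholdSet":
        """Return a copy with one named threshold replaced.

        ``parameter`` is one of ``Tmin``, ``Dmax``, ``Tmax``.
        """
        key = {"Tmin": "tmin_min", "Dmax": "dmax_m", "Tmax": "tmax_min"}.get(parameter)
        if key is None:
            raise ConfigurationError(f"unknown threshold parameter {parameter!r}")
        return replace(self, **{key: value})


#: Initial setting used as the starting point of the stepwise
#: sensitivity analysis (literature-motivated, pre-optimisation).
INITIAL_THRESHOLDS = ThresholdSet(tmin_min=3.0, dmax_m=100.0, tmax_min=60.0)


@dataclass(frozen=True)
class InclusionConfig:
    """Day/participant inclusion rules for the REP-vs-GPS comparison."""

    min_registration_hours: float = 9.0
    min_reporting_days: int = 2
    min_matched_days: int = 2
    contradiction_toh_min: float = 30.0
    toh_tolerance_min: tuple = (10.0, 20.0)
    al_tolerance: tuple = (0, 1)

    def __post_init__(self):
        for name in ("min_registration_hours", "min_reporting_days",
                     "min_matched_days", "contradiction_toh_min"):
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    """All fixed constants of the end-to-end pipeline.

    Defaults reproduce the study protocol exactly; any override is the
    caller's responsibility and is recorded in the run manifest.
    """

    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    inclusion: InclusionConfig = field(default_factory=InclusionConfig)
    vmax_kmh: float = 330.0
    min_registration_hours: float = 9.0
    min_valid_days: int = 2
    home_eps_m: float = 60.0
    home_min_pts: int = 3
    home_max_distance_m: float = 150.0
    noise_move_min: float = 3.0
    diary_min_duration_min: float = 3.0
    seed: int = 0
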