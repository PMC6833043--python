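import numpy as np
import pandas as pd
import pytest

import mobimatch as mm


def make_cohort(**kwargs):
    """Simulate a cohort and bundle it with its study period."""
    cfg = mm.SimConfig(**kwargs)
    cohort = mm.simulate_cohort(cfg)
    start = pd.Timestamp(cfg.start_date)
    period = (start, start + pd.Timedelta(days=cfg.n_days))
    return cohort, period


ERROR_FREE = dict(gps_noise_sd_m=0.0, indoor_loss_prob=0.0,
                  diary_omission_prob=0.0, diary_shift_sd_min=0.0,
                  diary_time_round_min=0.0)

#: Thresholds compatible with the error-free generator geometry:
#: Tmin below the shortest true visit (8 min), Dmax above the (zero)
#: noise scale and far below the 400-m inter-place spacing, Tmax above
#: any within-day gap.
CLEAN_THRESHOLDS = mm.ThresholdSet(tmin_min=6.0, dmax_m=10.0, tmax_min=300.0)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small zero-noise, zero-omission cohort with 5-s sampling."""
    return make_cohort(n_participants=2, n_days=2, seed=7, gps_interval_s=5,
                       **ERROR_FREE)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort under the default (noisy) study conditions."""
    return make_cohort(n_participants=3, n_days=4, seed=5, gps_interval_s=15)


@pytest.fixture(scope="session")
def noisy_prep(noisy_cohort):
    cohort, period = noisy_cohort
    return mm.prepare_cohort(cohort.fixes, cohort.toh_diary, cohort.al_diary,
                             cohort.homes, period)


def day_fix_frame(times_s, lats, lons, pid="P1", date="2023-05-01"):
    """Build a single-day fix frame from second offsets and coordinates."""
    base = pd.Timestamp(date)
    return pd.DataFrame({
        "participant_id": pid,
        "timestamp": base + pd.to_timedelta(np.asarray(times_s, dtype=float), unit="s"),
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float)})
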