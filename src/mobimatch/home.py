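"""Home-location validation and replacement.

The geocoded residence address is checked against a GPS-derived home:
density clustering (DBSCAN, haversine metric) of the first-morning and
last-evening fixes of every valid day. The cluster nearest the address
is the GPS home candidate; if its centre lies within 150 m the home is
valid, and the candidate replaces the address when it captures
strictly more of the participant's fixes within a 60-m buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .geo import EARTH_RADIUS_M, haversine_m


@dataclass
class HomeLocation:
    participant_id: str
    lat: float
    lon: float
    source: str               # "address" or "gps"
    distance_to_address_m: float
    is_valid: bool
    diagnostic: str = ""


def anchor_fixes(day_fixes: pd.DataFrame, days: pd.DataFrame) -> pd.DataFrame:
    """First and last fix of every valid day (one fix if the day has one).

    ``day_fixes`` must carry a ``date`` column (see ``segment_days``);
    ``days`` is the validity table from ``flag_valid_days``.
    """
    valid = days.loc[days["is_valid"], ["participant_id", "date"]]
    if len(valid) == 0:
        return day_fixes.iloc[0:0].copy()
    merged = day_fixes.merge(valid, on=["participant_id", "date"])
    merged = merged.sort_values(["participant_id", "date", "timestamp"], kind="stable")
    g = merged.groupby(["participant_id", "date"], sort=False)
    first = g.head(1)
    last = g.tail(1)
    anchors = pd.concat([first, last]).drop_duplicates(
        subset=["participant_id", "date", "timestamp"])
    return anchors.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)


def detect_home(anchors: pd.DataFrame,
                address_home: tuple[float, float],
                all_fixes: pd.DataFrame,
                participant_id: str = "",
                eps_m: float = 60.0,
                min_pts: int = 3,
                max_home_distance_m: float = 150.0) -> HomeLocation:
    """Resolve one participant's home from anchor fixes and their address.

    DBSCAN clusters the anchors; each cluster is represented by the
    coordinate-wise median of its members. Among clusters, the one
    whose centre is nearest the address wins (ties: larger membership,
    then lexicographically smaller centre). The home is valid iff that
    centre lies within ``max_home_distance_m`` of the address. The
    final coordinates are the GPS centre if strictly more of
    ``all_fixes`` fall within ``eps_m`` of it than of the address,
    else the address.
    """
    addr_lat, addr_lon = float(address_home[0]), float(address_home[1])
    if len(anchors) == 0:
        return HomeLocation(participant_id, addr_lat, addr_lon, "address",
                            float("nan"), False, "no anchor fixes (no valid days)")
    coords = np.radians(anchors[["lat", "lon"]].to_numpy(dtype=float))
    labels = DBSCAN(eps=eps_m / EARTH_RADIUS_M, min_samples=min_pts,
                    metric="haversine").fit_predict(coords)
    cluster_ids = [c for c in np.unique(labels) if c != -1]
    if not cluster_ids:
        return HomeLocation(participant_id, addr_lat, addr_lon, "address",
                            float("nan"), False,
                            "all anchor fixes classified as noise by DBSCAN")
    centres = []
    for c in cluster_ids:
        members = anchors.loc[labels == c]
        centres.append((float(members["lat"].median()),
                        float(members["lon"].median()),
                        int(len(members))))
    dists = np.array([haversine_m(la, lo, addr_lat, addr_lon)
                      for la, lo, _n in centres])
    # nearest centre wins; deterministic tie-break: membership, then coords
    order = sorted(range(len(centres)),
                   key=lambda i: (dists[i], -centres[i][2],
                                  centres[i][0], centres[i][1]))
    best = order[0]
    gps_lat, gps_lon, _n = centres[best]
    dist = float(dists[best])
    is_valid = dist < max_home_distance_m

    fx = all_fixes.loc[all_fixes["participant_id"] == participant_id] \
        if "participant_id" in all_fixes.columns and participant_id else all_fixes
    n_gps = int((haversine_m(fx["lat"].to_numpy(), fx["lon"].to_numpy(),
                             gps_lat, gps_lon) <= eps_m).sum()) if len(fx) else 0
    n_addr = int((haversine_m(fx["lat"].to_numpy(), fx["lon"].to_numpy(),
                              addr_lat, addr_lon) <= eps_m).sum()) if len(fx) else 0
    if n_gps > n_addr:
        return HomeLocation(participant_id, gps_lat, gps_lon, "gps", dist, is_valid)
    return HomeLocation(participant_id, addr_lat, addr_lon, "address", dist, is_valid)


def resolve_homes(day_fixes: pd.DataFrame, days: pd.DataFrame,
                  address_homes: pd.DataFrame,
                  eps_m: float = 60.0, min_pts: int = 3,
                  max_home_distance_m: float = 150.0) -> pd.DataFrame:
    """Resolve homes for every participant in the address table.

    Returns the ``homes_resolved`` frame: participant_id, lat, lon,
    source, distance_to_address_m, is_valid.
    """
    anchors = anchor_fixes(day_fixes, days)
    rows = []
    for _, rec in address_homes.iterrows():
        pid = rec["participant_id"]
        hl = detect_home(anchors.loc[anchors["participant_id"] == pid],
                         (rec["lat"], rec["lon"]),
                         day_fixes, participant_id=pid, eps_m=eps_m,
                         min_pts=min_pts, max_home_distance_m=max_home_distance_m)
        rows.append({"participant_id": pid, "lat": hl.lat, "lon": hl.lon,
                     "source": hl.source,
                     "distance_to_address_m": hl.distance_to_address_m,
                     "is_valid": hl.is_valid, "diagnostic": hl.diagnostic})
    return pd.DataFrame(rows, columns=["participant_id", "lat", "lon", "source",
                                       "distance_to_address_m", "is_valid",
                                       "diagnostic"])
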