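"""Half-open time-interval arithmetic on int64 nanosecond endpoints.

Events throughout the package are closed-open intervals [start, end).
These helpers implement union, intersection and total-duration
operations used by the temporal-overlap agreement statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def to_ns(df: pd.DataFrame, start: str = "start", end: str = "end") -> np.ndarray:
    """Extract an (n, 2) int64-ns interval array from an event frame."""
    if len(df) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.stack([df[start].values.astype("datetime64[ns]").astype(np.int64),
                    df[end].values.astype("datetime64[ns]").astype(np.int64)], axis=1)
    return arr


def merge(intervals: np.ndarray) -> np.ndarray:
    """Union of intervals as a sorted, disjoint interval set."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total(intervals: np.ndarray) -> int:
    """Total covered duration (ns) of a disjoint interval set."""
    if len(intervals) == 0:
        return 0
    return int((intervals[:, 1] - intervals[:, 0]).sum())


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two disjoint sorted interval sets (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def overlap_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise overlap durations (ns) between raw interval arrays.

    Entry (i, j) is the length of a_i ∩ b_j; strictly positive entries
    mark temporally matching event pairs (abutting intervals do not
    match under the half-open convention).
    """
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)), dtype=np.int64)
    s = np.maximum(a[:, 0][:, None], b[:, 0][None, :])
    e = np.minimum(a[:, 1][:, None], b[:, 1][None, :])
    return np.maximum(e - s, 0)
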