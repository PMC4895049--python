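"""Half-open interval arithmetic on 0-based genomic coordinates.

Intervals are ``(n, 2)`` int64 arrays of ``[start, end)`` rows; tracks are
``{chromosome: intervals}`` dicts. All public helpers return *normalized*
arrays: sorted by start, non-overlapping, zero-length rows dropped.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "union",
    "subtract",
    "intersect",
    "total_length",
    "contains",
    "track_union",
    "track_subtract",
    "track_length",
]


def normalize(intervals) -> np.ndarray:
    """Sort and merge an interval array; overlapping/adjacent rows coalesce."""
    a = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if a.shape[0] == 0:
        return a
    if np.any(a[:, 1] < a[:, 0]):
        raise ValueError("interval end precedes start")
    a = a[a[:, 1] > a[:, 0]]
    if a.shape[0] == 0:
        return a
    a = a[np.argsort(a[:, 0], kind="stable")]
    merged = [a[0].copy()]
    for start, end in a[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append(np.array([start, end], dtype=np.int64))
    return np.array(merged, dtype=np.int64)


def union(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    return normalize(np.concatenate([a, b], axis=0))


def subtract(a, b) -> np.ndarray:
    """Set difference ``a \\ b`` of normalized interval sets."""
    a, b = normalize(a), normalize(b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return a
    out = []
    j = 0
    for start, end in a:
        cur = start
        while j < b.shape[0] and b[j, 1] <= cur:
            j += 1
        k = j
        while k < b.shape[0] and b[k, 0] < end:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < end:
            out.append((cur, end))
    return normalize(np.array(out, dtype=np.int64).reshape(-1, 2))


def intersect(a, b) -> np.ndarray:
    a, b = normalize(a), normalize(b)
    out = []
    i = j = 0
    while i < a.shape[0] and j < b.shape[0]:
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return normalize(np.array(out, dtype=np.int64).reshape(-1, 2))


def total_length(intervals) -> int:
    a = normalize(intervals)
    return int((a[:, 1] - a[:, 0]).sum()) if a.shape[0] else 0


def contains(intervals, positions) -> np.ndarray:
    """Boolean membership of each position in a normalized interval set."""
    a = normalize(intervals)
    pos = np.asarray(positions, dtype=np.int64)
    if a.shape[0] == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(a[:, 0], pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < a[idx[ok], 1]
    return out


def track_union(*tracks) -> dict:
    chroms = sorted({c for t in tracks for c in t})
    out = {}
    for c in chroms:
        acc = np.empty((0, 2), dtype=np.int64)
        for t in tracks:
            if c in t:
                acc = union(acc, t[c])
        out[c] = acc
    return out


def track_subtract(a: dict, b: dict) -> dict:
    return {c: subtract(iv, b.get(c, np.empty((0, 2), dtype=np.int64))) for c, iv in a.items()}


def track_length(track: dict) -> int:
    return sum(total_length(iv) for iv in track.values())
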