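"""Backward tracking of growing leaves from ligulation to emergence.

Growing leaves cannot be ordered topologically (they all emerge from the
whorl at the stem tip) and their geometry changes daily, but smoothly:
at a 24 h observation frequency the same leaf moves little between dates
compared to the separation between different leaves.  Each ranked leaf is
therefore chained backwards in time from its first ligulated observation,
at every earlier date greedily adopting the unassigned growing leaf whose
midrib is nearest in the resampled-polyline distance

    D(pl, pl') = sum_i d(pl_i, pl'_i)

over n equally arc-length-spaced points.
"""

from __future__ import annotations

import numpy as np

from .model import PlantSnapshot, Polyline3D, TrackedPlant, TrackingParams

__all__ = ["resample_polyline", "polyline_distance", "backtrack_growing"]


def resample_polyline(pl: Polyline3D, n_points: int = 20) -> np.ndarray:
    """Resample a polyline to n points equally spaced in arc length.

    Endpoints are preserved.  Raises on zero-length (degenerate) input.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pts = pl.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate polyline: zero arc length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for dim in range(3):
        out[:, dim] = np.interp(targets, s, pts[:, dim])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def polyline_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Index-wise sum of Euclidean distances between two resampled polylines."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("incompatible resampling: point counts differ")
    return float(np.linalg.norm(a - b, axis=1).sum())


def backtrack_growing(
    tracked: TrackedPlant,
    series: list[PlantSnapshot],
    params: TrackingParams,
) -> TrackedPlant:
    """Extend each rank's track backwards through the growing-leaf pool.

    Ranks are processed in ascending order.  For each, the chain starts at
    the rank's first ligulated observation and steps backwards date by
    date through the non-discarded snapshots; at each date the remaining
    unassigned growing leaf nearest to the last associated midrib (in the
    distance D) is adopted and removed from the pool.  A date with an
    empty pool is skipped; the chain stops when no earlier snapshot has
    any remaining growing leaf.  Lower ranks win contested observations.
    """
    snapshots = sorted(
        (s for s in series if not s.discarded), key=lambda s: s.time
    )
    resampled = {
        lf.uid: resample_polyline(lf.midrib, params.n_points)
        for s in snapshots
        for lf in s.growing
        if lf.rank is None
    }
    assigned: set[str] = set()
    for rank in sorted(tracked.tracks):
        track = tracked.tracks[rank]
        if not track:
            continue
        first = min(track, key=lambda lf: lf.time)
        query = resample_polyline(first.midrib, params.n_points)
        adopted = []
        earlier = [s for s in snapshots if s.time < first.time]
        remaining = {
            s.time: [
                lf
                for lf in s.growing
                if lf.rank is None and lf.uid not in assigned
            ]
            for s in earlier
        }
        for snap in reversed(earlier):
            if not any(remaining[s.time] for s in earlier if s.time <= snap.time):
                break
            pool = remaining[snap.time]
            if not pool:
                continue
            dists = [polyline_distance(query, resampled[lf.uid]) for lf in pool]
            k = int(np.argmin(dists))
            if (
                params.max_backtrack_distance is not None
                and dists[k] > params.max_backtrack_distance
            ):
                break
            chosen = pool[k]
            chosen.rank = rank
            assigned.add(chosen.uid)
            adopted.append(chosen)
            pool.remove(chosen)
            query = resampled[chosen.uid]
        if adopted:
            tracked.tracks[rank] = sorted(
                track + adopted, key=lambda lf: lf.time
            )
    return tracked
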