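"""Stem-series conditioning ahead of alignment.

Derives a per-date stem height from multi-view collar detections, removes
snapshots with abnormal stem shapes (directed Hausdorff distance to the
median stem), smooths the stem-height series to a non-decreasing curve, and
classifies leaves into ligulated / growing by comparing their insertion
point to the smoothed stem height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import cdist

from .model import (
    GROWING,
    LIGULATED,
    PlantSnapshot,
    Polyline3D,
    TrackingParams,
)

__all__ = [
    "MedianStem",
    "stem_height_from_collars",
    "median_stem",
    "directed_hausdorff",
    "flag_abnormal_snapshots",
    "smooth_stem_height",
    "classify_leaves",
]


@dataclass
class MedianStem:
    """Per-z-bin median (x, y) stem polyline over a time-series."""

    polyline: Polyline3D
    z_bin: float


def stem_height_from_collars(collars_per_view: list[list[float]]) -> float:
    """Stem height as the highest collar over all side views (mm)."""
    heights = [h for view in collars_per_view for h in view]
    if not heights:
        raise ValueError("no collar detections in any view")
    return float(max(heights))


def densify_polyline(pl: Polyline3D, max_spacing: float = 10.0) -> np.ndarray:
    """Insert intermediate vertices so no segment exceeds ``max_spacing`` mm."""
    pts = pl.points
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        # epsilon guards the subdivision count against float noise in seg,
        # keeping densification (hence Hausdorff) translation-invariant
        n_sub = max(1, int(np.ceil(seg / max_spacing - 1e-9)))
        for k in range(1, n_sub + 1):
            out.append(a + (b - a) * (k / n_sub))
    return np.asarray(out)


def median_stem(stems: list[Polyline3D], z_bin: float = 20.0) -> MedianStem:
    """Median stem: per-z-bin coordinate-wise median (x, y) position.

    All stem polyline points of the series are grouped into discrete z bins
    of width ``z_bin``; each occupied bin yields one polyline point at the
    bin centre with the median (x, y) of its members, ordered by z.
    """
    if not stems:
        raise ValueError("need at least one stem polyline")
    if z_bin <= 0:
        raise ValueError("z_bin must be positive")
    pts = np.vstack([densify_polyline(s) for s in stems])
    bins = np.floor(pts[:, 2] / z_bin).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = pts[bins == b]
        rows.append(
            [np.median(sel[:, 0]), np.median(sel[:, 1]), (b + 0.5) * z_bin]
        )
    if len(rows) < 2:
        # degenerate z extent: duplicate the single bin point slightly apart
        x, y, z = rows[0]
        rows = [[x, y, z - z_bin / 2], [x, y, z + z_bin / 2]]
    return MedianStem(Polyline3D(np.asarray(rows)), z_bin)


def directed_hausdorff(a: Polyline3D, b: Polyline3D) -> float:
    """Directed Hausdorff distance (mm) from polyline a to polyline b.

    max over vertices p of a of the distance from p to the nearest vertex
    of b; asymmetric by construction.  Both polylines are densified to
    <= 10 mm vertex spacing first, bounding the vertex-only error.
    """
    pa = densify_polyline(a)
    pb = densify_polyline(b)
    return float(cdist(pa, pb).min(axis=1).max())


def flag_abnormal_snapshots(
    series: list[PlantSnapshot], params: TrackingParams
) -> list[PlantSnapshot]:
    """Flag snapshots whose stem strays from the series median stem.

    Builds the median stem from all snapshots (single pass) and sets
    ``discarded`` on each snapshot whose directed Hausdorff distance from
    stem to median exceeds ``params.hausdorff_threshold``.
    """
    if len(series) < 2:
        return series
    med = median_stem([s.stem for s in series], params.z_bin)
    for snap in series:
        d = directed_hausdorff(snap.stem, med.polyline)
        snap.discarded = d > params.hausdorff_threshold
    return series


def smooth_stem_height(
    series: list[tuple[float, float]], median_window: int = 3
) -> list[tuple[float, float]]:
    """Smooth a stem-height series to a non-decreasing curve.

    A centred rolling median (default 3 points) removes isolated spikes,
    then isotonic (non-decreasing, least-squares) regression enforces
    monotone growth.  An already non-decreasing outlier-free series is
    returned unchanged.
    """
    if not series:
        return []
    times = np.asarray([t for t, _ in series], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    h = np.asarray([v for _, v in series], dtype=float)
    if h.size >= median_window and median_window > 1:
        half = median_window // 2
        padded = np.concatenate([h[:1].repeat(half), h, h[-1:].repeat(half)])
        despiked = np.array(
            [np.median(padded[i : i + median_window]) for i in range(h.size)]
        )
    else:
        despiked = h
    fitted = isotonic_regression(despiked, increasing=True).x
    # keep original values where they already satisfy monotonicity exactly
    if np.all(np.diff(h) >= 0):
        fitted = h
    return list(zip(times.tolist(), fitted.tolist()))


def classify_leaves(snapshot: PlantSnapshot, smoothed_height: float) -> PlantSnapshot:
    """Classify leaves as ligulated (insertion <= stem height) or growing.

    A collar exactly at the stem tip counts as ligulated.  The ligulated
    sequence is re-sorted by increasing insertion height; ties keep input
    order.  Every input leaf appears exactly once in the output.
    """
    leaves = snapshot.leaves
    lig = [lf for lf in leaves if lf.insertion_height <= smoothed_height]
    grow = [lf for lf in leaves if lf.insertion_height > smoothed_height]
    for lf in lig:
        lf.status = LIGULATED
    for lf in grow:
        lf.status = GROWING
    snapshot.ligulated = sorted(lig, key=lambda lf: lf.insertion_height)
    snapshot.growing = grow
    snapshot.stem_height = smoothed_height
    return snapshot
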