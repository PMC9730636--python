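"""Phenotypic trait extraction from a tracked plant.

Rank-based profiles (the median of a morphological variable per leaf rank
at ligulation), plant-development stages (visible and ligulated leaf
stage) and individual leaf growth curves.  These are the organ-level
traits that feed architectural (FSPM) model calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import LIGULATED, PlantSnapshot, TrackedPlant, TrackingParams

__all__ = [
    "RankProfile",
    "StageSeries",
    "ligulation_time",
    "rank_profile",
    "emergence_timing",
    "visible_leaf_stage",
    "ligulated_leaf_stage",
    "leaf_growth_curve",
]

_VARIABLES = {
    "length": lambda lf: lf.length,
    "insertion_height": lambda lf: lf.insertion_height,
    "azimuth": lambda lf: lf.azimuth,
}


@dataclass
class RankProfile:
    """Median value of one morphological variable per leaf rank."""

    variable: str
    values: dict[int, float] = field(default_factory=dict)

    def __getitem__(self, rank: int) -> float:
        return self.values[rank]

    def __contains__(self, rank: int) -> bool:
        return rank in self.values


@dataclass
class StageSeries:
    """Time-indexed development stage: (time, stage) pairs, non-decreasing."""

    times: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)


def ligulation_time(track, axis: str = "thermal_time"):
    """Time of a rank's first ligulated observation, or None."""
    lig = [lf for lf in track if lf.status == LIGULATED]
    if not lig:
        return None
    first = min(lig, key=lambda lf: lf.time)
    return getattr(first, axis)


def rank_profile(
    tracked: TrackedPlant, variable: str, params: TrackingParams
) -> RankProfile:
    """Per-rank median of a variable over ligulated observations.

    Only observations within ``params.ligulation_window`` day_20degC after
    the rank's ligulation (its first ligulated observation) enter the
    median; leaves observed longer after ligulation may already be
    degrading and are excluded.
    """
    if variable not in _VARIABLES:
        raise ValueError(f"unsupported variable: {variable!r}")
    get = _VARIABLES[variable]
    out = RankProfile(variable)
    for rank, track in sorted(tracked.tracks.items()):
        t_lig = ligulation_time(track, "thermal_time")
        if t_lig is None:
            continue
        vals = [
            get(lf)
            for lf in track
            if lf.status == LIGULATED
            and lf.thermal_time - t_lig <= params.ligulation_window
        ]
        if vals:
            out.values[rank] = float(np.median(vals))
    return out


def emergence_timing(
    series: list[PlantSnapshot], tracked: TrackedPlant
) -> dict[int, float]:
    """Emergence timing t_vis(r) of each leaf rank.

    r_vis(t) is the maximum rank observed at date t (growing leaves
    included, once ranked); t_med(r) the median of dates where r_vis = r;
    the emergence of leaf r is placed midway between consecutive plateaus:
    t_vis(r) = (t_med(r-1) + t_med(r)) / 2.  Ranks that are never the
    maximum (e.g. skipped by a double emergence) are omitted.
    """
    plateaus: dict[int, list[float]] = {}
    for snap in series:
        if snap.discarded:
            continue
        ranks = [lf.rank for lf in snap.leaves if lf.rank is not None]
        if not ranks:
            continue
        plateaus.setdefault(max(ranks), []).append(snap.time)
    t_med = {r: float(np.median(ts)) for r, ts in plateaus.items()}
    timings = {}
    for r in sorted(t_med):
        if r - 1 in t_med:
            timings[r] = (t_med[r - 1] + t_med[r]) / 2.0
    return timings


def visible_leaf_stage(
    timings: dict[int, float], query_times
) -> StageSeries:
    """Visible leaf stage n_vis(t): linear interpolation of (t_vis(r), r).

    Outside the support of the timings the stage is clamped to the first /
    last rank value (no extrapolation to negative stages).
    """
    if len(timings) < 2:
        raise ValueError("need at least two emergence timings")
    ranks = sorted(timings)
    knots_t = np.array([timings[r] for r in ranks], dtype=float)
    knots_r = np.array(ranks, dtype=float)
    order = np.argsort(knots_t)
    times = np.asarray(list(query_times), dtype=float)
    vals = np.interp(times, knots_t[order], knots_r[order])
    return StageSeries(times.tolist(), vals.tolist())


def ligulated_leaf_stage(
    tracked: TrackedPlant,
    h_profile: RankProfile,
    query_times,
    rank_offset: int = 1,
) -> StageSeries:
    """Ligulated leaf stage n_lig(t), integer-valued, piecewise constant.

    The ligulation timing of rank r is the earliest time the smoothed stem
    height reaches the insertion-height profile at rank r - rank_offset
    (linear interpolation between stem-height samples); n_lig(t) is the
    largest rank whose ligulation timing has passed.  Ranks whose keyed
    profile height exceeds the final stem height are excluded.
    """
    if not tracked.stem_height_series:
        raise ValueError("stem height series required")
    times_h = np.array([t for t, _ in tracked.stem_height_series])
    heights = np.array([h for _, h in tracked.stem_height_series])
    t_lig: dict[int, float] = {}
    for rank in sorted(h_profile.values):
        r = rank + rank_offset
        target = h_profile[rank]
        if target > heights[-1]:
            continue
        idx = int(np.searchsorted(heights, target, side="left"))
        if idx == 0:
            t_lig[r] = float(times_h[0])
        else:
            h0, h1 = heights[idx - 1], heights[idx]
            t0, t1 = times_h[idx - 1], times_h[idx]
            frac = 0.0 if h1 == h0 else (target - h0) / (h1 - h0)
            t_lig[r] = float(t0 + frac * (t1 - t0))
    times = sorted(float(t) for t in query_times)
    values = [
        float(max((r for r, tl in t_lig.items() if tl <= t), default=0))
        for t in times
    ]
    return StageSeries(times, values)


def leaf_growth_curve(
    tracked: TrackedPlant, rank: int
) -> list[tuple[float, float]]:
    """Pre-ligulation (time, length mm) curve of the rank's leaf."""
    if rank not in tracked.tracks:
        raise ValueError(f"rank {rank} not tracked")
    track = tracked.tracks[rank]
    t_lig = ligulation_time(track, "time")
    if t_lig is None:
        obs = sorted(track, key=lambda lf: lf.time)
    else:
        obs = sorted(
            (lf for lf in track if lf.time < t_lig), key=lambda lf: lf.time
        )
    return [(lf.time, lf.length) for lf in obs]
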