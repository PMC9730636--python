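"""Shared domain types for the leaf-tracking pipeline.

Coordinates are millimetres in a right-handed frame with z vertical.
Azimuth is measured in the horizontal plane, in radians, wrapped to
[-pi, pi].  Leaf ranks are 1-based, counting from the botanically first
(bottom) leaf.  Time is carried on two parallel axes -- calendar days and
thermal time in equivalent days at 20 degC (day_20degC); thermal time is an
input, never computed internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Polyline3D",
    "LeafObservation",
    "PlantSnapshot",
    "TrackedPlant",
    "TrackingParams",
    "LIGULATED",
    "GROWING",
    "wrap_angle",
    "validate_snapshot",
]

LIGULATED = "ligulated"
GROWING = "growing"


def wrap_angle(alpha: float) -> float:
    """Wrap an angle to [-pi, pi] (pi maps to pi, -pi stays -pi)."""
    wrapped = math.remainder(alpha, 2.0 * math.pi)
    # math.remainder returns in [-pi, pi]; normalise -0.0
    return wrapped + 0.0


@dataclass
class Polyline3D:
    """An ordered 3D polyline (mm), at least two points, positive arc length."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("polyline points must be an (n, 3) array")
        if pts.shape[0] < 2:
            raise ValueError("polyline needs at least two points")
        self.points = pts

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())

    def is_degenerate(self) -> bool:
        """True when every point coincides (zero total arc length)."""
        return self.arc_length <= 0.0

    def translated(self, offset) -> "Polyline3D":
        return Polyline3D(self.points + np.asarray(offset, dtype=float))

    def __eq__(self, other) -> bool:  # value semantics for tests/round-trips
        return isinstance(other, Polyline3D) and np.array_equal(
            self.points, other.points
        )


@dataclass
class LeafObservation:
    """One segmented leaf at one observation date.

    ``uid`` identifies the physical observation across serialisation and
    ground-truth sidecars.  ``rank`` stays ``None`` until assignment.
    """

    uid: str
    time: float
    thermal_time: float
    azimuth: float
    insertion_height: float
    length: float
    midrib: Polyline3D
    status: str = GROWING
    rank: Optional[int] = None
    is_artefact: bool = False

    def __hash__(self) -> int:
        return hash(self.uid)


@dataclass
class PlantSnapshot:
    """One date's segmentation: stem polyline plus classified leaves.

    ``ligulated`` is the bottom-to-top sequence S_t (sorted by insertion
    height); ``growing`` is the unordered whorl set.
    """

    time: float
    thermal_time: float
    stem: Polyline3D
    ligulated: list[LeafObservation] = field(default_factory=list)
    growing: list[LeafObservation] = field(default_factory=list)
    collars_per_view: Optional[list[list[float]]] = None
    stem_height: Optional[float] = None
    discarded: bool = False

    @property
    def leaves(self) -> list[LeafObservation]:
        return list(self.ligulated) + list(self.growing)


@dataclass
class TrackedPlant:
    """The 3D+t output: per-rank leaf tracks plus the stem-height series."""

    snapshots: list[PlantSnapshot]
    tracks: dict[int, list[LeafObservation]] = field(default_factory=dict)
    stem_height_series: list[tuple[float, float]] = field(default_factory=list)
    plant_id: str = "plant"


@dataclass
class TrackingParams:
    """Tunable parameters of the tracking pipeline.

    ``w_h`` (1/mm) and ``w_l`` (1/mm) scale insertion height and length into
    the leaf feature vector; ``w_gap`` multiplies the mean adjacent-leaf cost
    into the gap penalty; ``w_tml`` down-weights terminal gaps; ``n_points``
    is the midrib resampling count for backtracking; ``hausdorff_threshold``
    (mm) flags abnormal stem shapes; ``ligulation_window`` (day_20degC) bounds
    the observations entering rank-based profiles.
    """

    w_h: float = 0.03
    w_l: float = 0.004
    w_gap: float = 3.0
    w_tml: float = 0.2
    c_adj_override: Optional[float] = None
    n_points: int = 20
    hausdorff_threshold: float = 100.0
    ligulation_window: float = 20.0
    z_bin: float = 20.0
    median_window: int = 3
    lig_stage_rank_offset: int = 1
    max_backtrack_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.w_h <= 0 or self.w_l <= 0 or self.w_gap <= 0:
            raise ValueError("feature and gap weights must be strictly positive")
        if not (0.0 < self.w_tml <= 1.0):
            raise ValueError("w_tml must lie in (0, 1]")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.hausdorff_threshold <= 0:
            raise ValueError("hausdorff_threshold must be positive")
        if self.z_bin <= 0:
            raise ValueError("z_bin must be positive")
        if self.lig_stage_rank_offset not in (0, 1):
            raise ValueError("lig_stage_rank_offset must be 0 or 1")


def validate_snapshot(snapshot: PlantSnapshot) -> list[str]:
    """Check a snapshot against the domain invariants.

    Returns a list of human-readable violation descriptions; empty iff the
    snapshot is well-formed.  Never mutates its input.
    """
    violations: list[str] = []
    if snapshot.stem.points.shape[0] < 2:
        violations.append("stem polyline has fewer than two points")

    heights = [leaf.insertion_height for leaf in snapshot.ligulated]
    for i in range(1, len(heights)):
        if heights[i] < heights[i - 1]:
            violations.append(
                "ligulated sequence not ordered by insertion height at "
                f"positions {i - 1}-{i} ({heights[i - 1]:g} > {heights[i]:g} mm)"
            )

    stem_height = snapshot.stem_height
    for leaf in snapshot.leaves:
        if not (-math.pi <= leaf.azimuth <= math.pi):
            violations.append(
                f"leaf {leaf.uid}: azimuth {leaf.azimuth:g} outside [-pi, pi]"
            )
        if leaf.insertion_height < 0:
            violations.append(
                f"leaf {leaf.uid}: negative insertion height "
                f"{leaf.insertion_height:g} mm"
            )
        if leaf.length <= 0:
            violations.append(f"leaf {leaf.uid}: non-positive length")
        if (
            leaf.status == LIGULATED
            and stem_height is not None
            and leaf.insertion_height > stem_height
        ):
            violations.append(
                f"leaf {leaf.uid}: ligulated but inserted above stem height"
            )

    seen = {leaf.uid for leaf in snapshot.ligulated}
    for leaf in snapshot.growing:
        if leaf.uid in seen:
            violations.append(f"leaf {leaf.uid}: present in both ligulated and growing")
    return violations
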