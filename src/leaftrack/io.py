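"""Pipeline orchestration, serialization and configuration.

One JSON document per plant holds the snapshot series; the tracked output
is the same document augmented with per-leaf ranks plus a top-level track
index, and flat CSV exports carry the trait tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .backtrack import backtrack_growing
from .model import (
    GROWING,
    LIGULATED,
    LeafObservation,
    PlantSnapshot,
    Polyline3D,
    TrackedPlant,
    TrackingParams,
)
from .multialign import assign_ranks, progressive_align, prune_rare_columns
from .traits import (
    emergence_timing,
    leaf_growth_curve,
    ligulated_leaf_stage,
    rank_profile,
    visible_leaf_stage,
)

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "read_series",
    "write_series",
    "write_tracked",
    "tracked_to_frame",
    "run_pipeline",
    "export_traits",
]

log = logging.getLogger("leaftrack")


class SchemaError(ValueError):
    """Input document violates the snapshot schema; carries a JSON pointer."""

    def __init__(self, pointer: str, message: str) -> None:
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


@dataclass
class PipelineConfig:
    """Strict pipeline configuration (unknown keys rejected)."""

    params: TrackingParams = field(default_factory=TrackingParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        own = {f.name for f in dc_fields(cls)} - {"params"}
        param_names = {f.name for f in dc_fields(TrackingParams)}
        unknown = set(raw) - own - param_names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = TrackingParams(**{k: v for k, v in raw.items() if k in param_names})
        extra = {k: v for k, v in raw.items() if k in own}
        return cls(params=params, **extra)


_SNAPSHOT_KEYS = {
    "time",
    "thermal_time",
    "stem",
    "collars_per_view",
    "stem_height",
    "leaves",
}
_LEAF_KEYS = {
    "uid",
    "status",
    "azimuth",
    "insertion_height",
    "length",
    "midrib",
    "rank",
}


def _polyline(obj, pointer: str) -> Polyline3D:
    if not isinstance(obj, list) or len(obj) < 2:
        raise SchemaError(pointer, "expected a list of >= 2 [x, y, z] points")
    try:
        return Polyline3D(np.asarray(obj, dtype=float))
    except (ValueError, TypeError) as exc:
        raise SchemaError(pointer, str(exc)) from exc


def read_series(path) -> tuple[str, list[PlantSnapshot]]:
    """Read one plant's snapshot series with strict schema validation."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError("", "document must be an object")
    unknown = set(doc) - {"plant_id", "snapshots", "tracks"}
    if unknown:
        raise SchemaError("", f"unknown keys: {sorted(unknown)}")
    if "snapshots" not in doc:
        raise SchemaError("/snapshots", "missing required field")
    plant_id = str(doc.get("plant_id", "plant"))
    series: list[PlantSnapshot] = []
    for si, snap in enumerate(doc["snapshots"]):
        ptr = f"/snapshots/{si}"
        if not isinstance(snap, dict):
            raise SchemaError(ptr, "snapshot must be an object")
        unknown = set(snap) - _SNAPSHOT_KEYS
        if unknown:
            raise SchemaError(ptr, f"unknown keys: {sorted(unknown)}")
        for key in ("time", "stem", "leaves"):
            if key not in snap:
                raise SchemaError(f"{ptr}/{key}", "missing required field")
        stem = _polyline(snap["stem"], f"{ptr}/stem")
        time = float(snap["time"])
        thermal = float(snap.get("thermal_time", time))
        ligulated: list[LeafObservation] = []
        growing: list[LeafObservation] = []
        for li, leaf in enumerate(snap["leaves"]):
            lptr = f"{ptr}/leaves/{li}"
            if not isinstance(leaf, dict):
                raise SchemaError(lptr, "leaf must be an object")
            unknown = set(leaf) - _LEAF_KEYS
            if unknown:
                raise SchemaError(lptr, f"unknown keys: {sorted(unknown)}")
            for key in ("status", "azimuth", "insertion_height", "length", "midrib"):
                if key not in leaf:
                    raise SchemaError(f"{lptr}/{key}", "missing required field")
            status = leaf["status"]
            if status not in (LIGULATED, GROWING):
                raise SchemaError(
                    f"{lptr}/status", f"expected ligulated|growing, got {status!r}"
                )
            obs = LeafObservation(
                uid=str(leaf.get("uid", f"t{si}_l{li}")),
                time=time,
                thermal_time=thermal,
                azimuth=float(leaf["azimuth"]),
                insertion_height=float(leaf["insertion_height"]),
                length=float(leaf["length"]),
                midrib=_polyline(leaf["midrib"], f"{lptr}/midrib"),
                status=status,
                rank=leaf.get("rank"),
            )
            (ligulated if status == LIGULATED else growing).append(obs)
        collars = snap.get("collars_per_view")
        series.append(
            PlantSnapshot(
                time=time,
                thermal_time=thermal,
                stem=stem,
                ligulated=sorted(ligulated, key=lambda lf: lf.insertion_height),
                growing=growing,
                collars_per_view=collars,
                stem_height=snap.get("stem_height"),
            )
        )
    return plant_id, series


def _leaf_to_json(leaf: LeafObservation) -> dict:
    return {
        "uid": leaf.uid,
        "status": leaf.status,
        "azimuth": leaf.azimuth,
        "insertion_height": leaf.insertion_height,
        "length": leaf.length,
        "midrib": leaf.midrib.points.tolist(),
        "rank": leaf.rank,
    }


def _snapshot_to_json(snap: PlantSnapshot) -> dict:
    out = {
        "time": snap.time,
        "thermal_time": snap.thermal_time,
        "stem": snap.stem.points.tolist(),
        "leaves": [_leaf_to_json(lf) for lf in snap.leaves],
    }
    if snap.collars_per_view is not None:
        out["collars_per_view"] = snap.collars_per_view
    if snap.stem_height is not None:
        out["stem_height"] = snap.stem_height
    return out


def write_series(path, plant_id: str, series: list[PlantSnapshot]) -> None:
    doc = {
        "plant_id": plant_id,
        "snapshots": [_snapshot_to_json(s) for s in series],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_tracked(path, tracked: TrackedPlant) -> None:
    """Write the augmented snapshot document plus the track index."""
    doc = {
        "plant_id": tracked.plant_id,
        "snapshots": [_snapshot_to_json(s) for s in tracked.snapshots],
        "tracks": {
            str(rank): [lf.uid for lf in track]
            for rank, track in sorted(tracked.tracks.items())
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def tracked_to_frame(tracked: TrackedPlant) -> pd.DataFrame:
    """Flat per-observation trait table."""
    rows = []
    for snap in tracked.snapshots:
        for lf in snap.leaves:
            rows.append(
                {
                    "plant_id": tracked.plant_id,
                    "time": snap.time,
                    "rank": lf.rank,
                    "status": lf.status,
                    "azimuth": lf.azimuth,
                    "insertion_height": lf.insertion_height,
                    "length": lf.length,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    series: list[PlantSnapshot],
    params: Optional[TrackingParams] = None,
    plant_id: str = "plant",
) -> TrackedPlant:
    """Full tracking pipeline on one plant's snapshot series.

    Stages: stem-height extraction and smoothing, abnormal-snapshot
    removal, leaf classification, progressive alignment, rare-column
    pruning, rank assignment, backward tracking of growing leaves.
    Deterministic for fixed input and parameters.
    """
    if not series:
        raise ValueError("empty snapshot series")
    params = params or TrackingParams()
    series = sorted(series, key=lambda s: s.time)

    if len(series) >= 2:
        preprocess.flag_abnormal_snapshots(series, params)
    active = [s for s in series if not s.discarded]
    if not active:
        raise ValueError("all snapshots discarded by stem-shape filtering")
    log.info("snapshots: %d total, %d discarded", len(series), len(series) - len(active))

    raw_heights = []
    for snap in active:
        if snap.collars_per_view is not None:
            # collar regime: no detection means no ligulated leaf yet
            if any(snap.collars_per_view):
                h = preprocess.stem_height_from_collars(snap.collars_per_view)
            else:
                h = 0.0
        elif snap.stem_height is not None:
            h = snap.stem_height
        else:
            h = float(snap.stem.points[:, 2].max())
        raw_heights.append((snap.time, h))
    smoothed = preprocess.smooth_stem_height(raw_heights, params.median_window)
    for snap, (_, h) in zip(active, smoothed):
        preprocess.classify_leaves(snap, h)

    profile = progressive_align(active, params)
    pruned = prune_rare_columns(profile)
    log.info(
        "alignment: %d columns, %d pruned",
        len(profile.columns),
        len(profile.columns) - len(pruned.columns),
    )
    tracked = assign_ranks(pruned, series)
    tracked.plant_id = plant_id
    tracked = backtrack_growing(tracked, series, params)
    n_unassigned = sum(
        1 for s in active for lf in s.leaves if lf.rank is None
    )
    log.info("leaves left unassigned: %d", n_unassigned)
    return tracked


def export_traits(
    tracked: TrackedPlant, out_dir, params: Optional[TrackingParams] = None
) -> dict[str, Path]:
    """Write the trait CSVs (stage series, rank profiles, growth curves)."""
    params = params or TrackingParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    profiles = []
    for variable in ("length", "insertion_height", "azimuth"):
        prof = rank_profile(tracked, variable, params)
        for rank, value in sorted(prof.values.items()):
            profiles.append({"rank": rank, "variable": variable, "value": value})
    p = out_dir / "rank_profiles.csv"
    pd.DataFrame(profiles).to_csv(p, index=False)
    written["rank_profiles"] = p

    times = [s.time for s in tracked.snapshots if not s.discarded]
    timings = emergence_timing(tracked.snapshots, tracked)
    stage_rows = []
    if len(timings) >= 2:
        n_vis = visible_leaf_stage(timings, times)
        h_pf = rank_profile(tracked, "insertion_height", params)
        n_lig = ligulated_leaf_stage(
            tracked, h_pf, times, params.lig_stage_rank_offset
        )
        heights = dict(tracked.stem_height_series)
        for t, v, l in zip(times, n_vis.values, n_lig.values):
            stage_rows.append(
                {
                    "time": t,
                    "n_vis": v,
                    "n_lig": l,
                    "stem_height_mm": heights.get(t),
                }
            )
    p = out_dir / "stage_series.csv"
    pd.DataFrame(stage_rows).to_csv(p, index=False)
    written["stage_series"] = p

    growth_rows = []
    for rank in sorted(tracked.tracks):
        for t, length in leaf_growth_curve(tracked, rank):
            growth_rows.append({"rank": rank, "time": t, "length_mm": length})
    p = out_dir / "growth_curves.csv"
    pd.DataFrame(growth_rows).to_csv(p, index=False)
    written["growth_curves"] = p
    return written
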