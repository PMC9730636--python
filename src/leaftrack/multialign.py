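"""Progressive multiple alignment of ligulated-leaf sequences.

The per-date sequences S_t are folded, in ascending temporal order, into a
profile: an alignment of all processed sequences treated as a single
sequence of columns.  Aligning a new sequence against the profile reuses
the pairwise Needleman-Wunsch machinery with a sequence-profile cost: the
cost of matching a leaf vector v' against a column is the mean of the
pairwise costs against the column's k non-gap members (gaps do not dilute
the mean).  Columns tracking segmentation artefacts are sparse and are
pruned afterwards; surviving columns, numbered bottom-to-top, define the
leaf ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    LeafObservation,
    PlantSnapshot,
    TrackedPlant,
    TrackingParams,
)
from .pairalign import (
    align_pair,
    feature_vector,
    gap_penalty,
    leaf_pair_cost,
    mean_adjacent_cost,
)

__all__ = [
    "ProfileColumn",
    "AlignmentProfile",
    "profile_column_cost",
    "align_sequence_to_profile",
    "progressive_align",
    "prune_rare_columns",
    "assign_ranks",
]


@dataclass
class ProfileColumn:
    """One column: per processed snapshot a leaf entry or a gap (None)."""

    entries: list[Optional[LeafObservation]]
    vectors: list[Optional[np.ndarray]]

    @property
    def occupancy(self) -> int:
        return sum(1 for e in self.entries if e is not None)


@dataclass
class AlignmentProfile:
    """The multiple-alignment state: ordered columns over processed snapshots."""

    n_rows: int = 0
    columns: list[ProfileColumn] = field(default_factory=list)

    def row(self, r: int) -> list[Optional[LeafObservation]]:
        """Entries of snapshot r across all columns (gaps included)."""
        return [col.entries[r] for col in self.columns]


def profile_column_cost(column: ProfileColumn, v: np.ndarray) -> float:
    """Mean pairwise cost between v and the column's non-gap members."""
    vecs = [w for w in column.vectors if w is not None]
    if not vecs:
        raise ValueError("empty column: no non-gap entry to compare against")
    return float(np.mean([leaf_pair_cost(w, v) for w in vecs]))


def align_sequence_to_profile(
    profile: AlignmentProfile,
    leaves: list[LeafObservation],
    vectors: list[np.ndarray],
    g: float,
    w_tml: float,
) -> AlignmentProfile:
    """Fold one snapshot's ligulated sequence into the profile.

    Runs the end-gap-weighted alignment with the sequence-profile cost;
    a gap inserted into the profile becomes an all-gap entry for every
    previously processed snapshot.
    """
    aln = align_pair(
        profile.columns,
        vectors,
        g,
        w_tml,
        cost_fn=lambda i, j: profile_column_cost(profile.columns[i], vectors[j]),
    )
    n_prev = profile.n_rows
    new_columns: list[ProfileColumn] = []
    for ci, sj in aln.columns:
        if ci is not None:
            col = profile.columns[ci]
            entries = list(col.entries)
            vecs = list(col.vectors)
        else:
            entries = [None] * n_prev
            vecs = [None] * n_prev
        if sj is not None:
            entries.append(leaves[sj])
            vecs.append(vectors[sj])
        else:
            entries.append(None)
            vecs.append(None)
        new_columns.append(ProfileColumn(entries, vecs))
    return AlignmentProfile(n_rows=n_prev + 1, columns=new_columns)


def progressive_align(
    series: list[PlantSnapshot], params: TrackingParams
) -> AlignmentProfile:
    """Align all non-discarded snapshots' ligulated sequences, oldest first."""
    active = [s for s in series if not s.discarded]
    if not active:
        raise ValueError("no non-discarded snapshot to align")
    active = sorted(active, key=lambda s: s.time)
    g: Optional[float] = None  # estimated once, on first real alignment

    profile = AlignmentProfile()
    for snap in active:
        leaves = list(snap.ligulated)
        vectors = [feature_vector(lf, params) for lf in leaves]
        if profile.n_rows == 0:
            profile = AlignmentProfile(
                n_rows=1,
                columns=[
                    ProfileColumn([lf], [v]) for lf, v in zip(leaves, vectors)
                ],
            )
        else:
            if g is None:
                g = gap_penalty(params, mean_adjacent_cost(active, params))
            profile = align_sequence_to_profile(
                profile, leaves, vectors, g, params.w_tml
            )
    return profile


def prune_rare_columns(profile: AlignmentProfile) -> AlignmentProfile:
    """Drop sparse interior columns (likely segmentation artefacts).

    Column k (neither first nor last) is deleted when its occupancy n_k
    satisfies n_k < (n_{k-1} + n_{k+1}) / 4, evaluated on the original
    counts of the immediate original neighbours, in a single pass.
    """
    cols = profile.columns
    if len(cols) <= 2:
        return AlignmentProfile(profile.n_rows, list(cols))
    counts = [c.occupancy for c in cols]
    kept = [
        col
        for k, col in enumerate(cols)
        if k == 0
        or k == len(cols) - 1
        or counts[k] >= (counts[k - 1] + counts[k + 1]) / 4.0
    ]
    return AlignmentProfile(profile.n_rows, kept)


def assign_ranks(
    profile: AlignmentProfile, series: list[PlantSnapshot]
) -> TrackedPlant:
    """Number surviving columns 1..K bottom-to-top and build per-rank tracks.

    Every ligulated leaf of a surviving column receives the column's rank;
    leaves of pruned columns stay unassigned.  Tracks are time-ordered.
    """
    surviving = {id(e) for col in profile.columns for e in col.entries if e is not None}
    for snap in series:
        for lf in snap.leaves:
            if id(lf) not in surviving:
                lf.rank = None
    tracks: dict[int, list[LeafObservation]] = {}
    for rank, col in enumerate(profile.columns, start=1):
        obs = [e for e in col.entries if e is not None]
        for lf in obs:
            lf.rank = rank
        tracks[rank] = sorted(obs, key=lambda lf: lf.time)
    snapshots = sorted(series, key=lambda s: s.time)
    heights = [
        (s.time, s.stem_height)
        for s in snapshots
        if not s.discarded and s.stem_height is not None
    ]
    return TrackedPlant(
        snapshots=snapshots, tracks=tracks, stem_height_series=heights
    )
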