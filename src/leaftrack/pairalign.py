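"""Pairwise alignment of two ligulated-leaf sequences.

Each ligulated leaf is summarised by the feature vector

    v = [cos(alpha), sin(alpha), w_h * h, w_l * l]

(azimuth alpha, insertion height h in mm, length l in mm).  The cost of
matching two leaves is the Euclidean distance between their vectors.  A
gap penalty g = w_gap * c_adj is charged per gap, where c_adj is the mean
matching cost over topologically adjacent leaves of the series; terminal
gaps (leading/trailing in either aligned sequence) are down-weighted by
w_tml, because leaves legitimately appear at the top and disappear at the
bottom of the sequence over time.

The optimal alignment minimises

    C = (n - n_tml) * g + n_tml * w_tml * g + sum over matches of c_vv

and is found by Needleman-Wunsch dynamic programming with end-gap-aware
penalties: gap moves taken in the first or last row/column of the DP
matrix cost w_tml * g, interior gaps cost g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .model import LeafObservation, PlantSnapshot, TrackingParams

__all__ = [
    "feature_vector",
    "leaf_pair_cost",
    "mean_adjacent_cost",
    "gap_penalty",
    "align_pair",
    "alignment_cost",
    "count_terminal_gaps",
    "PairwiseAlignment",
]

# traceback move codes, in tie-break preference order
_MATCH, _GAP_S2, _GAP_S1 = 0, 1, 2


def feature_vector(leaf: LeafObservation, params: TrackingParams) -> np.ndarray:
    """Four-component morphology vector [cos a, sin a, w_h*h, w_l*l]."""
    return np.array(
        [
            math.cos(leaf.azimuth),
            math.sin(leaf.azimuth),
            params.w_h * leaf.insertion_height,
            params.w_l * leaf.length,
        ]
    )


def leaf_pair_cost(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean distance between two leaf feature vectors."""
    return float(np.linalg.norm(np.asarray(v1) - np.asarray(v2)))


def mean_adjacent_cost(
    series: list[PlantSnapshot], params: TrackingParams
) -> float:
    """Mean matching cost over consecutive ligulated-leaf pairs (c_adj).

    Averaged over all couples of topologically adjacent leaves within each
    snapshot's ligulated sequence, across all non-discarded snapshots.  If
    ``params.c_adj_override`` is set, that value is returned instead.
    """
    if params.c_adj_override is not None:
        return float(params.c_adj_override)
    costs = []
    for snap in series:
        if snap.discarded:
            continue
        vecs = [feature_vector(lf, params) for lf in snap.ligulated]
        for a, b in zip(vecs[:-1], vecs[1:]):
            costs.append(leaf_pair_cost(a, b))
    if not costs:
        raise ValueError("cannot estimate c_adj: no adjacent ligulated pair")
    return float(np.mean(costs))


def gap_penalty(params: TrackingParams, c_adj: float) -> float:
    """Per-gap penalty g = w_gap * c_adj."""
    if c_adj < 0:
        raise ValueError("c_adj must be non-negative")
    return params.w_gap * c_adj


@dataclass
class PairwiseAlignment:
    """An order-preserving alignment of two sequences.

    ``columns`` lists (i, j) pairs where either index may be None (a gap);
    no column is (None, None).  ``cost`` is the global alignment cost C.
    """

    columns: list[tuple[Optional[int], Optional[int]]]
    cost: float
    n_gaps: int = 0
    n_terminal: int = 0
    matched: list[tuple[int, int]] = field(default_factory=list)


def count_terminal_gaps(
    columns: Sequence[tuple[Optional[int], Optional[int]]]
) -> int:
    """Count gap columns lying in the leading/trailing run of either sequence.

    A gap in sequence k is terminal iff every column before it (or every
    column after it) is also a gap in sequence k.
    """
    total = 0
    for side in (0, 1):
        isgap = [col[side] is None for col in columns]
        n = len(isgap)
        lead = 0
        while lead < n and isgap[lead]:
            lead += 1
        trail = 0
        while trail < n - lead and isgap[n - 1 - trail]:
            trail += 1
        total += lead + trail
    return total


def alignment_cost(
    columns: Sequence[tuple[Optional[int], Optional[int]]],
    cost_fn: Callable[[int, int], float],
    g: float,
    w_tml: float,
) -> float:
    """Evaluate the global cost C of an alignment from its columns."""
    n_gaps = sum(1 for c in columns if c[0] is None or c[1] is None)
    n_tml = count_terminal_gaps(columns)
    match_cost = sum(cost_fn(i, j) for i, j in columns if i is not None and j is not None)
    return (n_gaps - n_tml) * g + n_tml * w_tml * g + match_cost


def align_pair(
    s1: Sequence,
    s2: Sequence,
    g: float,
    w_tml: float,
    cost_fn: Optional[Callable[[int, int], float]] = None,
) -> PairwiseAlignment:
    """Optimal end-gap-weighted alignment of two sequences.

    ``s1`` and ``s2`` hold feature vectors (or arbitrary elements when a
    custom ``cost_fn(i, j)`` is supplied, as in sequence-profile alignment).
    On equal cost the traceback prefers match, then gap-in-s2 (consume s1),
    then gap-in-s1, making the output deterministic.
    """
    if cost_fn is None:
        cost_fn = lambda i, j: leaf_pair_cost(s1[i], s2[j])  # noqa: E731
    n1, n2 = len(s1), len(s2)
    tml = w_tml * g

    M = np.full((n1 + 1, n2 + 1), np.inf)
    move = np.full((n1 + 1, n2 + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        M[i, 0] = M[i - 1, 0] + tml
        move[i, 0] = _GAP_S2
    for j in range(1, n2 + 1):
        M[0, j] = M[0, j - 1] + tml
        move[0, j] = _GAP_S1
    for i in range(1, n1 + 1):
        gap_s1_cost = tml if (i == n1) else g  # consume s2, gap in s1
        for j in range(1, n2 + 1):
            gap_s2_cost = tml if (j == n2) else g  # consume s1, gap in s2
            best = M[i - 1, j - 1] + cost_fn(i - 1, j - 1)
            best_move = _MATCH
            cand = M[i - 1, j] + gap_s2_cost
            if cand < best:
                best, best_move = cand, _GAP_S2
            cand = M[i, j - 1] + gap_s1_cost
            if cand < best:
                best, best_move = cand, _GAP_S1
            M[i, j] = best
            move[i, j] = best_move

    columns: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n1, n2
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == _MATCH:
            i, j = i - 1, j - 1
            columns.append((i, j))
        elif mv == _GAP_S2:
            i -= 1
            columns.append((i, None))
        else:
            j -= 1
            columns.append((None, j))
    columns.reverse()

    matched = [(a, b) for a, b in columns if a is not None and b is not None]
    n_gaps = len(columns) - len(matched)
    n_tml = count_terminal_gaps(columns)
    cost = alignment_cost(columns, cost_fn, g, w_tml)
    return PairwiseAlignment(
        columns=columns,
        cost=cost,
        n_gaps=n_gaps,
        n_terminal=n_tml,
        matched=matched,
    )
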