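"""Shared fixtures and builders for the leaftrack test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from leaftrack.model import (  # noqa: E402
    GROWING,
    LIGULATED,
    LeafObservation,
    PlantSnapshot,
    Polyline3D,
    TrackingParams,
)

_UID = itertools.count()


@pytest.fixture
def params():
    return TrackingParams()


def make_leaf(
    azimuth=0.0,
    insertion_height=100.0,
    length=500.0,
    time=0.0,
    status=LIGULATED,
    uid=None,
    midrib=None,
):
    """A leaf observation with a plausible default midrib."""
    if midrib is None:
        ux, uy = math.cos(azimuth), math.sin(azimuth)
        s = np.linspace(0.0, 1.0, 8)
        midrib = Polyline3D(
            np.column_stack(
                [
                    ux * length * 0.8 * s,
                    uy * length * 0.8 * s,
                    insertion_height + length * 0.5 * s,
                ]
            )
        )
    return LeafObservation(
        uid=uid or f"leaf{next(_UID)}",
        time=time,
        thermal_time=time,
        azimuth=azimuth,
        insertion_height=insertion_height,
        length=length,
        midrib=midrib,
        status=status,
    )


def make_snapshot(time=0.0, ligulated=(), growing=(), stem_top=1000.0):
    stem = Polyline3D(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, stem_top]]))
    return PlantSnapshot(
        time=time,
        thermal_time=time,
        stem=stem,
        ligulated=sorted(ligulated, key=lambda lf: lf.insertion_height),
        growing=list(growing),
        stem_height=stem_top,
    )


def brute_force_align_cost(s1, s2, g, w_tml, cost_fn=None):
    """Exhaustive minimum of the global alignment cost over all alignments.

    Enumerates every lattice path (match / gap-in-s2 / gap-in-s1 moves) and
    evaluates the cost from the resulting column sequence: gaps lying in
    the leading or trailing gap run of either aligned sequence count as
    terminal.  Independent of the dynamic-programming implementation.
    """
    if cost_fn is None:
        cost_fn = lambda i, j: float(np.linalg.norm(np.asarray(s1[i]) - np.asarray(s2[j])))  # noqa: E731
    n1, n2 = len(s1), len(s2)
    best = math.inf

    def evaluate(columns):
        total_gaps = 0
        terminal = 0
        for side in (0, 1):
            flags = [col[side] is None for col in columns]
            total_gaps_side = sum(flags)
            lead = 0
            while lead < len(flags) and flags[lead]:
                lead += 1
            trail = 0
            while trail < len(flags) - lead and flags[len(flags) - 1 - trail]:
                trail += 1
            terminal += lead + trail
            total_gaps += total_gaps_side
        match_cost = sum(
            cost_fn(i, j) for i, j in columns if i is not None and j is not None
        )
        return (total_gaps - terminal) * g + terminal * w_tml * g + match_cost

    def recurse(i, j, columns):
        nonlocal best
        if i == n1 and j == n2:
            best = min(best, evaluate(columns))
            return
        if i < n1 and j < n2:
            recurse(i + 1, j + 1, columns + [(i, j)])
        if i < n1:
            recurse(i + 1, j, columns + [(i, None)])
        if j < n2:
            recurse(i, j + 1, columns + [(None, j)])

    recurse(0, 0, [])
    return best
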