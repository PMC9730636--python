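"""Progressive profile alignment, rare-column pruning and rank assignment."""

import math

import numpy as np
import pytest

from leaftrack.model import LIGULATED, TrackingParams
from leaftrack.multialign import (
    AlignmentProfile,
    ProfileColumn,
    align_sequence_to_profile,
    assign_ranks,
    profile_column_cost,
    progressive_align,
    prune_rare_columns,
)
from leaftrack.pairalign import feature_vector
from leaftrack.synthetic import SimulationConfig, corrupt, simulate_plant

from conftest import make_leaf, make_snapshot


def leaf_with_features(azimuth, h, l, time=0.0):
    return make_leaf(azimuth=azimuth, insertion_height=h, length=l, time=time)


def staircase_series(n_leaves=5, n_times=8, params=None):
    """Leaf r (1-based) ligulates at date r; features are exact and fixed."""
    params = params or TrackingParams()
    snaps = []
    for t in range(1, n_times + 1):
        leaves = []
        for r in range(1, min(t, n_leaves) + 1):
            leaves.append(
                leaf_with_features(
                    azimuth=(math.pi / 2) * (-1) ** r,
                    h=100.0 * r,
                    l=300.0 + 40.0 * r,
                    time=float(t),
                )
            )
        snaps.append(make_snapshot(time=float(t), ligulated=leaves))
    return snaps


class TestProfileColumnCost:
    def _column(self, vectors):
        entries = [make_leaf() if v is not None else None for v in vectors]
        return ProfileColumn(entries, [np.asarray(v) if v is not None else None for v in vectors])

    def test_identical_members_zero(self):
        v = [1.0, 0.0, 3.0, 2.0]
        col = self._column([v, v, v])
        assert profile_column_cost(col, np.asarray(v)) == 0.0

    def test_mean_over_non_gap_entries_only(self):
        v1 = np.array([0.0, 0, 2, 0])  # distance 2 to target
        v2 = np.array([0.0, 0, 0, 4])  # distance 4 to target
        col = self._column([v1, None, v2])
        target = np.zeros(4)
        assert profile_column_cost(col, target) == pytest.approx(3.0)

    def test_single_member_reduces_to_pair_cost(self):
        v = np.array([1.0, 0, 0, 0])
        col = self._column([v])
        assert profile_column_cost(col, np.zeros(4)) == pytest.approx(1.0)

    def test_all_gap_column_signalled(self):
        col = self._column([None, None])
        with pytest.raises(ValueError, match="empty column"):
            profile_column_cost(col, np.zeros(4))


class TestAlignSequenceToProfile:
    G, WT = 5.0, 0.2

    def _single_sequence_profile(self, leaves, params):
        vecs = [feature_vector(lf, params) for lf in leaves]
        return AlignmentProfile(
            1, [ProfileColumn([lf], [v]) for lf, v in zip(leaves, vecs)]
        )

    def test_identical_sequence_adds_no_columns(self, params):
        leaves = [leaf_with_features(0.0, 100, 400), leaf_with_features(1.0, 200, 500)]
        prof = self._single_sequence_profile(leaves, params)
        clones = [leaf_with_features(0.0, 100, 400), leaf_with_features(1.0, 200, 500)]
        vecs = [feature_vector(lf, params) for lf in clones]
        out = align_sequence_to_profile(prof, clones, vecs, self.G, self.WT)
        assert len(out.columns) == 2
        assert all(col.occupancy == 2 for col in out.columns)

    def test_unmatched_element_opens_interior_column(self, params):
        A = leaf_with_features(0.0, 100, 400)
        B = leaf_with_features(0.0, 500, 700)
        prof = self._single_sequence_profile([A, B], params)
        X = leaf_with_features(math.pi, 300, 100)  # far from both
        seq = [
            leaf_with_features(0.0, 100, 400),
            X,
            leaf_with_features(0.0, 500, 700),
        ]
        vecs = [feature_vector(lf, params) for lf in seq]
        out = align_sequence_to_profile(prof, seq, vecs, self.G, self.WT)
        assert len(out.columns) == 3
        assert [c.occupancy for c in out.columns] == [2, 1, 2]
        assert out.columns[1].entries == [None, X]

    def test_empty_sequence_adds_gap_row(self, params):
        leaves = [leaf_with_features(0.0, 100, 400)]
        prof = self._single_sequence_profile(leaves, params)
        out = align_sequence_to_profile(prof, [], [], self.G, self.WT)
        assert len(out.columns) == 1
        assert out.columns[0].entries == [leaves[0], None]
        assert out.n_rows == 2


class TestProgressiveAlign:
    def test_identical_snapshots_one_column_per_leaf(self, params):
        T = 6
        snaps = []
        for t in range(T):
            snaps.append(
                make_snapshot(
                    time=float(t),
                    ligulated=[
                        leaf_with_features(0.0, 100, 400, time=t),
                        leaf_with_features(math.pi / 2, 200, 500, time=t),
                    ],
                )
            )
        prof = progressive_align(snaps, params)
        assert len(prof.columns) == 2
        assert all(col.occupancy == T for col in prof.columns)

    def test_staircase_recovers_emergence_order(self, params):
        snaps = staircase_series(n_leaves=5, n_times=8)
        prof = progressive_align(snaps, params)
        assert len(prof.columns) == 5
        # column r (0-based) first appears at date r+1: occupancy T - r
        assert [c.occupancy for c in prof.columns] == [8, 7, 6, 5, 4]
        heights = [
            {e.insertion_height for e in c.entries if e is not None}
            for c in prof.columns
        ]
        assert heights == [{100.0 * (r + 1)} for r in range(5)]

    def test_artefact_isolated_in_sparse_column(self, params):
        # the artefact sits mid-sequence with several leaves below and
        # above, so absorbing it into a real column would displace a chain
        # of neighbours -- isolating it in an own column is optimal
        snaps = staircase_series(n_leaves=8, n_times=12)
        art = leaf_with_features(math.pi, 450.0, 90.0, time=10.0)
        snaps[9].ligulated = sorted(
            snaps[9].ligulated + [art], key=lambda lf: lf.insertion_height
        )
        prof = progressive_align(snaps, params)
        assert len(prof.columns) == 9
        art_cols = [
            c for c in prof.columns if art in [e for e in c.entries if e is not None]
        ]
        assert len(art_cols) == 1 and art_cols[0].occupancy == 1

    def test_rows_reproduce_original_sequences(self, params):
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed,
                n_leaves=8,
                n_timepoints=20,
                p_missing_leaf=0.05,
                p_artefact_leaf=0.1,
                feature_noise_sd=0.02,
            )
            sim = corrupt(simulate_plant(cfg), cfg)
            active = sorted(sim.series, key=lambda s: s.time)
            prof = progressive_align(active, params)
            for r, snap in enumerate(active):
                row = [e for e in prof.row(r) if e is not None]
                assert row == list(snap.ligulated)


class TestPruneRareColumns:
    def _profile_with_counts(self, counts):
        n_rows = max(counts)
        cols = []
        for c in counts:
            entries = [make_leaf() for _ in range(c)] + [None] * (n_rows - c)
            cols.append(ProfileColumn(entries, [np.zeros(4)] * c + [None] * (n_rows - c)))
        return AlignmentProfile(n_rows, cols)

    def test_sparse_interior_column_deleted(self):
        prof = self._profile_with_counts([40, 5, 38])
        out = prune_rare_columns(prof)
        assert [c.occupancy for c in out.columns] == [40, 38]

    def test_sufficient_interior_column_kept(self):
        prof = self._profile_with_counts([40, 20, 38])
        out = prune_rare_columns(prof)
        assert [c.occupancy for c in out.columns] == [40, 20, 38]

    def test_first_and_last_exempt(self):
        prof = self._profile_with_counts([3, 1])
        out = prune_rare_columns(prof)
        assert [c.occupancy for c in out.columns] == [3, 1]

    def test_single_pass_on_frozen_counts(self):
        # both interior columns evaluated on the original neighbour counts:
        # 12 >= (40+5)/4 keeps, 5 < (12+38)/4 deletes
        prof = self._profile_with_counts([40, 12, 5, 38])
        out = prune_rare_columns(prof)
        assert [c.occupancy for c in out.columns] == [40, 12, 38]


class TestAssignRanks:
    def test_staircase_ranks_match_emergence_order(self, params):
        snaps = staircase_series(n_leaves=5, n_times=8)
        prof = progressive_align(snaps, params)
        tracked = assign_ranks(prune_rare_columns(prof), snaps)
        for snap in tracked.snapshots:
            for lf in snap.ligulated:
                assert lf.rank == int(lf.insertion_height // 100)
        assert sorted(tracked.tracks) == [1, 2, 3, 4, 5]
        for rank, track in tracked.tracks.items():
            times = [lf.time for lf in track]
            assert times == sorted(times)
            assert len(set(times)) == len(times)

    def test_single_snapshot_topological_ranks(self, params):
        snap = make_snapshot(
            time=0.0,
            ligulated=[
                leaf_with_features(0.0, 100, 400),
                leaf_with_features(1.0, 200, 500),
                leaf_with_features(2.0, 300, 600),
            ],
        )
        prof = progressive_align([snap], params)
        tracked = assign_ranks(prune_rare_columns(prof), [snap])
        assert [lf.rank for lf in tracked.snapshots[0].ligulated] == [1, 2, 3]

    def test_pruned_leaves_left_unranked(self, params):
        snaps = staircase_series(n_leaves=8, n_times=12)
        art = leaf_with_features(math.pi, 450.0, 90.0, time=10.0)
        snaps[9].ligulated = sorted(
            snaps[9].ligulated + [art], key=lambda lf: lf.insertion_height
        )
        prof = progressive_align(snaps, params)
        tracked = assign_ranks(prune_rare_columns(prof), snaps)
        assert art.rank is None
        ranks = {lf.rank for s in tracked.snapshots for lf in s.ligulated if lf is not art}
        assert ranks == {1, 2, 3, 4, 5, 6, 7, 8}

    def test_ranks_increase_with_position_in_sequence(self, params):
        cfg = SimulationConfig(seed=3, n_leaves=8, n_timepoints=20)
        sim = corrupt(simulate_plant(cfg), cfg)
        prof = progressive_align(sim.series, params)
        tracked = assign_ranks(prune_rare_columns(prof), sim.series)
        for snap in tracked.snapshots:
            ranked = [lf.rank for lf in snap.ligulated if lf.rank is not None]
            assert ranked == sorted(ranked)
            assert len(set(ranked)) == len(ranked)
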