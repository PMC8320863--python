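import numpy as np
import pytest

from glogseed.exceptions import ParameterError
from glogseed.msclustering import (
    ClusterTable,
    MSConfig,
    iterate_kernel,
    mean_shift_cluster,
    merge_or_add,
)


class TestIterateKernel:
    def test_isolated_candidate_converges_to_itself(self):
        t = ClusterTable(np.array([[5, 5], [50, 50]]))
        center, members = iterate_kernel(0, t)
        assert np.allclose(center, [5, 5])
        assert members == frozenset({0})

    def test_symmetric_pair(self):
        t = ClusterTable(np.array([[0, 0], [5, 0]]))
        center, members = iterate_kernel(0, t)
        assert np.allclose(center, [2.5, 0.0])
        assert members == frozenset({0, 1})

    def test_chain_membership_is_center_distance_based(self):
        # from (0,0) the kernel recenters at (3.5, 0); (14, 0) is 10.5 px away,
        # outside the radius-8 kernel, so the ascent settles on the first pair
        t = ClusterTable(np.array([[0, 0], [7, 0], [14, 0]]))
        center, members = iterate_kernel(0, t)
        assert np.allclose(center, [3.5, 0.0])
        assert members == frozenset({0, 1})

    def test_votes_count_iterations_of_membership(self):
        t = ClusterTable(np.array([[0, 0], [5, 0]]))
        iterate_kernel(0, t)
        # two iterations (initial + stability check), both members inside each time
        assert (t.current_votes == 2).all()
        assert t.visited.all()


class TestMergeOrAdd:
    def test_first_center_appended(self):
        t = ClusterTable(np.array([[0, 0]]))
        cid = merge_or_add(np.array([3.0, 4.0]), t)
        assert cid == 0
        assert np.allclose(t.nuclei[0], [3.0, 4.0])

    def test_midpoint_merge_within_threshold(self):
        t = ClusterTable(np.array([[0, 0], [10, 0]]))
        t.nuclei.append(np.array([0.0, 0.0]))
        cid = merge_or_add(np.array([10.0, 0.0]), t)
        assert cid == 0
        assert np.allclose(t.nuclei[0], [5.0, 0.0])

    def test_beyond_threshold_adds_new_nucleus(self):
        t = ClusterTable(np.array([[0, 0], [20, 0]]))
        t.nuclei.append(np.array([0.0, 0.0]))
        cid = merge_or_add(np.array([20.0, 0.0]), t)
        assert cid == 1
        assert len(t.nuclei) == 2


class TestMeanShiftCluster:
    def test_empty_candidate_set(self):
        nuclei, table = mean_shift_cluster(np.empty((0, 2)))
        assert nuclei.shape == (0, 2)
        assert len(table.nuclei) == 0

    def test_single_tight_group(self, rng):
        S = np.array([[10, 10], [11, 10], [10, 12], [12, 11]])
        nuclei, _ = mean_shift_cluster(S)
        assert len(nuclei) == 1
        assert np.allclose(nuclei[0], S.mean(axis=0))

    def test_two_far_groups(self):
        S = np.array([[0, 1], [1, 0], [0, 0], [100, 100], [101, 99], [99, 100]])
        nuclei, _ = mean_shift_cluster(S)
        assert len(nuclei) == 2
        assert np.allclose(nuclei[0], S[:3].mean(axis=0))
        assert np.allclose(nuclei[1], S[3:].mean(axis=0))

    def test_chain_merges_through_vote_table(self):
        # the two ascents converge at (3.5,0) and (10.5,0); they merge
        # (distance 7 < 16) and the cluster mean over all three members is (7,0)
        nuclei, table = mean_shift_cluster(np.array([[0, 0], [7, 0], [14, 0]]))
        assert len(nuclei) == 1
        assert np.allclose(nuclei[0], [7.0, 0.0])
        assert table.visited.all()
        assert (table.cluster == 0).all()

    def test_all_candidates_visited_and_covered(self, rng):
        S = rng.integers(0, 60, (40, 2))
        nuclei, table = mean_shift_cluster(np.unique(S, axis=0))
        assert table.visited.all()
        assert (table.cluster >= 0).all()
        assert len(nuclei) >= 1

    def test_translation_and_rotation_invariance(self, rng):
        S = np.unique(rng.integers(0, 50, (30, 2)), axis=0)
        n0 = len(mean_shift_cluster(S)[0])
        assert len(mean_shift_cluster(S + [200, -70])[0]) == n0
        rot = np.column_stack([S[:, 1], -S[:, 0]])  # 90-degree rotation
        assert len(mean_shift_cluster(rot)[0]) == n0

    def test_deterministic_output(self, rng):
        S = np.unique(rng.integers(0, 80, (50, 2)), axis=0)
        a, _ = mean_shift_cluster(S)
        b, _ = mean_shift_cluster(S)
        assert np.array_equal(a, b)

    def test_seeded_random_pick_order_is_reproducible(self, rng):
        S = np.unique(rng.integers(0, 80, (50, 2)), axis=0)
        cfg = MSConfig(pick_order="random", rng_seed=42)
        a, _ = mean_shift_cluster(S, cfg)
        b, _ = mean_shift_cluster(S, cfg)
        assert np.array_equal(a, b)

    def test_group_recovery(self, rng):
        # tight groups separated by > 2x merge threshold are recovered exactly
        true_centers = np.array([[20, 20], [20, 90], [90, 20], [90, 90]], dtype=float)
        pts = []
        for c in true_centers:
            pts.append(np.rint(c + rng.normal(0, 1.0, (6, 2))).astype(int))
        S = np.unique(np.vstack(pts), axis=0)
        nuclei, _ = mean_shift_cluster(S)
        assert len(nuclei) == 4
        for c in true_centers:
            assert np.linalg.norm(nuclei - c, axis=1).min() <= 1.0

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            MSConfig(radius=0)
        with pytest.raises(ParameterError):
            MSConfig(merge_threshold=-1)

    def test_table_dataframe_columns(self):
        _, table = mean_shift_cluster(np.array([[0, 0], [5, 0]]))
        df = table.to_dataframe()
        assert list(df.columns) == [
            "seed_row", "seed_col", "visit_flag", "current_votes",
            "max_votes", "cluster", "nucleus_row", "nucleus_col",
        ]
        assert (df["visit_flag"] == 1).all()
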