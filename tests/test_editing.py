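"""Cluster-editing operations, merge/absorb semantics and log replay."""

import numpy as np
import pytest

import cnaseg as cs
from conftest import make_table


def chain_table():
    """Three clusters whose centroids form the chain c1-c2-c3 (m=1).

    Centroids: c1=(1.00, 0.50), c2=(1.02, 0.49), c3=(1.04, 0.48); with
    thresholds (0.03, 0.02) the pairs (1,2) and (2,3) are within reach but
    (1,3) is not (RDR gap 0.04 > 0.03).
    """
    rdr = [[1.00], [1.02], [1.02], [1.04]]
    baf = [[0.50], [0.49], [0.49], [0.48]]
    return make_table(rdr, baf, cluster=[1, 2, 2, 3])


class TestAssignAndNew:
    def test_assign_changes_only_selection(self):
        table = make_table(np.ones((3, 1)), np.full((3, 1), 0.4), cluster=[1, 1, 2])
        entry = cs.assign_cluster(table, {0, 1}, 5)
        assert table.cluster.tolist() == [5, 5, 2]
        assert entry.previous.tolist() == [1, 1]

    @pytest.mark.parametrize("reserved", [-1, -2])
    def test_reserved_ids_allowed(self, reserved):
        table = make_table(np.ones((2, 1)), np.full((2, 1), 0.4), cluster=[0, 0])
        cs.assign_cluster(table, {0}, reserved)
        assert table.cluster[0] == reserved

    def test_below_minus_two_rejected(self):
        table = make_table(np.ones((2, 1)), np.full((2, 1), 0.4))
        with pytest.raises(ValueError):
            cs.assign_cluster(table, {0}, -3)

    def test_empty_selection_warns_and_noops(self):
        table = make_table(np.ones((2, 1)), np.full((2, 1), 0.4), cluster=[3, 3])
        with pytest.warns(UserWarning):
            entry = cs.assign_cluster(table, set(), 0)
        assert entry is None and table.cluster.tolist() == [3, 3]

    @pytest.mark.parametrize(
        "cluster, expected",
        [([0, 1, 3, 3], 4), ([-1, -1, -1, -1], 0), ([-2, 7, -1, 7], 8)],
    )
    def test_new_cluster_is_max_in_use_plus_one(self, cluster, expected):
        table = make_table(np.ones((4, 1)), np.full((4, 1), 0.4), cluster=cluster)
        new_id, _ = cs.new_cluster(table, {0})
        assert new_id == expected

    def test_consecutive_new_clusters_distinct(self):
        table = make_table(np.ones((4, 1)), np.full((4, 1), 0.4))
        a, _ = cs.new_cluster(table, {0})
        b, _ = cs.new_cluster(table, {1})
        assert b == a + 1


class TestMerge:
    def test_chain_forms_one_component(self):
        plan = cs.plan_merge(chain_table(), cs.ThresholdSpec.uniform(0.03, 0.02, 1))
        assert plan == [{1, 2, 3}]

    def test_largest_cluster_wins(self):
        # component {1,2,3} with bin counts 10, 40, 20 -> everything becomes 2
        rdr = [[1.00]] * 10 + [[1.02]] * 40 + [[1.04]] * 20
        baf = [[0.50]] * 10 + [[0.49]] * 40 + [[0.48]] * 20
        table = make_table(rdr, baf, cluster=[1] * 10 + [2] * 40 + [3] * 20)
        plan, entry = cs.merge_by_centroids(table, cs.ThresholdSpec.uniform(0.03, 0.02, 1))
        assert plan == [{1, 2, 3}]
        assert np.all(table.cluster == 2)
        assert len(entry.indices) == 30  # only non-winners moved

    def test_zero_thresholds_distinct_centroids_noop(self):
        table = chain_table()
        before = table.cluster.copy()
        plan, entry = cs.merge_by_centroids(table, cs.ThresholdSpec.uniform(0.0, 0.0, 1))
        assert plan == [] and entry is None
        np.testing.assert_array_equal(table.cluster, before)

    def test_dry_run_leaves_table_untouched(self):
        table = chain_table()
        before = table.cluster.copy()
        plan, entry = cs.merge_by_centroids(
            table, cs.ThresholdSpec.uniform(0.03, 0.02, 1), dry_run=True
        )
        assert plan == [{1, 2, 3}] and entry is None
        np.testing.assert_array_equal(table.cluster, before)

    def test_per_sample_gating_requires_every_sample(self):
        # centroids close in sample 1 but far in sample 2 -> no merge
        rdr = [[1.0, 1.0], [1.01, 2.0]]
        baf = [[0.5, 0.5], [0.5, 0.2]]
        table = make_table(rdr, baf, cluster=[0, 1])
        plan = cs.plan_merge(table, cs.ThresholdSpec.uniform(0.05, 0.05, 2))
        assert plan == []

    def test_wrong_threshold_length_rejected(self):
        with pytest.raises(ValueError):
            cs.plan_merge(chain_table(), cs.ThresholdSpec.uniform(0.1, 0.1, 3))

    def test_merge_reduces_cluster_count_by_component_sizes(self):
        table = chain_table()
        k_before = len(np.unique(table.cluster[table.cluster >= 0]))
        plan, _ = cs.merge_by_centroids(table, cs.ThresholdSpec.uniform(0.03, 0.02, 1))
        k_after = len(np.unique(table.cluster[table.cluster >= 0]))
        assert k_before - k_after == sum(len(c) - 1 for c in plan)

    def test_plan_matches_union_find_oracle_on_random_centroids(self):
        """Pairwise-threshold components agree with a hand-rolled union-find."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            k = int(rng.integers(3, 9))
            rdr = rng.uniform(0.5, 2.5, (k, 1)).round(2)
            baf = rng.uniform(0.0, 0.5, (k, 1)).round(2)
            table = make_table(rdr, baf, cluster=np.arange(k))
            t_rdr, t_baf = 0.3, 0.1
            # oracle: explicit union-find over flagged pairs
            parent = list(range(k))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(k):
                for j in range(i + 1, k):
                    if abs(rdr[i, 0] - rdr[j, 0]) <= t_rdr and abs(baf[i, 0] - baf[j, 0]) <= t_baf:
                        parent[find(i)] = find(j)
            comps = {}
            for i in range(k):
                comps.setdefault(find(i), set()).add(i)
            expected = sorted((c for c in comps.values() if len(c) > 1), key=min)
            plan = cs.plan_merge(table, cs.ThresholdSpec(np.array([t_rdr]), np.array([t_baf])))
            assert plan == expected


class TestAbsorb:
    def absorb_fixture(self):
        """m=1: From cluster 1 centered at (2.0, 0.2), To cluster 2 at (1.0, 0.5),
        plus one From bin sitting near the To centroid."""
        rdr = [[2.0], [2.0], [1.01], [1.0], [1.0]]
        baf = [[0.2], [0.2], [0.49], [0.5], [0.5]]
        return make_table(rdr, baf, cluster=[1, 1, 1, 2, 2])

    def test_bin_near_to_centroid_reassigned(self):
        table = self.absorb_fixture()
        # From centroid is pulled toward the stray bin; thresholds gate on the
        # gap to the *To* centroid (1.0, 0.5)
        entry = cs.absorb_bins(table, {1}, {2}, cs.ThresholdSpec.uniform(0.05, 0.05, 1))
        assert table.cluster.tolist() == [1, 1, 2, 2, 2]
        assert entry.indices.tolist() == [2]

    def test_tight_threshold_blocks_reassignment(self):
        table = self.absorb_fixture()
        entry = cs.absorb_bins(table, {1}, {2}, cs.ThresholdSpec.uniform(0.001, 0.001, 1))
        assert entry is None
        assert table.cluster.tolist() == [1, 1, 1, 2, 2]

    def test_bin_nearest_to_own_centroid_stays(self):
        rdr = [[2.0], [2.0], [1.0]]
        baf = [[0.2], [0.2], [0.5]]
        table = make_table(rdr, baf, cluster=[1, 1, 2])
        cs.absorb_bins(table, {1}, {2}, cs.ThresholdSpec.uniform(10.0, 10.0, 1))
        # bins 0/1 sit on their own centroid, which beats the To centroid
        assert table.cluster.tolist() == [1, 1, 2]

    def test_bins_outside_from_never_move(self):
        table = self.absorb_fixture()
        cs.absorb_bins(table, {2}, {1}, cs.ThresholdSpec.uniform(10.0, 10.0, 1))
        assert set(np.flatnonzero(table.cluster != self.absorb_fixture().cluster)) <= {3, 4}

    def test_labels_stay_within_participants(self):
        rng = np.random.default_rng(3)
        table = make_table(
            rng.uniform(0.5, 2.0, (30, 1)), rng.uniform(0, 0.5, (30, 1)),
            cluster=rng.integers(0, 4, 30),
        )
        before = set(np.unique(table.cluster))
        cs.absorb_bins(table, {0, 1}, {2, 3}, cs.ThresholdSpec.uniform(1.0, 0.5, 1))
        assert set(np.unique(table.cluster)) <= before

    def test_empty_sets_rejected(self):
        table = self.absorb_fixture()
        with pytest.raises(ValueError):
            cs.absorb_bins(table, set(), {2}, cs.ThresholdSpec.uniform(0.1, 0.1, 1))
        with pytest.raises(ValueError):
            cs.absorb_bins(table, {1}, set(), cs.ThresholdSpec.uniform(0.1, 0.1, 1))


class TestUndoAndReplay:
    def test_assign_then_undo_restores(self):
        table = make_table(np.ones((3, 1)), np.full((3, 1), 0.4), cluster=[1, 1, 2])
        log = cs.EditLog()
        log.append(cs.assign_cluster(table, {0, 2}, 9))
        cs.undo(table, log)
        assert table.cluster.tolist() == [1, 1, 2] and len(log) == 0

    def test_merge_then_undo_restores(self):
        table = chain_table()
        before = table.cluster.copy()
        log = cs.EditLog()
        _, entry = cs.merge_by_centroids(table, cs.ThresholdSpec.uniform(0.03, 0.02, 1))
        log.append(entry)
        cs.undo(table, log)
        np.testing.assert_array_equal(table.cluster, before)

    def test_undo_on_empty_log_warns(self):
        table = chain_table()
        log = cs.EditLog()
        with pytest.warns(UserWarning):
            assert cs.undo(table, log) is None

    def test_fuzzed_operation_sequences_replay_exactly(self):
        """Replaying the log from the initial labels reproduces the final state."""
        rng = np.random.default_rng(1234)
        for trial in range(10):
            n = 40
            table = make_table(
                rng.uniform(0.5, 2.5, (n, 1)),
                rng.uniform(0.0, 0.5, (n, 1)),
                cluster=rng.integers(0, 5, n),
            )
            initial = table.cluster.copy()
            log = cs.EditLog()
            for _ in range(15):
                op = rng.integers(4)
                if op == 0:
                    sel = rng.choice(n, rng.integers(1, 6), replace=False)
                    entry = cs.assign_cluster(table, sel, int(rng.integers(-2, 7)))
                elif op == 1:
                    sel = rng.choice(n, rng.integers(1, 4), replace=False)
                    _, entry = cs.new_cluster(table, sel)
                elif op == 2:
                    _, entry = cs.merge_by_centroids(
                        table, cs.ThresholdSpec.uniform(0.4, 0.15, 1)
                    )
                else:
                    in_use = np.unique(table.cluster[table.cluster >= 0])
                    if len(in_use) < 2:
                        continue
                    entry = cs.absorb_bins(
                        table, {int(in_use[0])}, {int(in_use[-1])},
                        cs.ThresholdSpec.uniform(1.0, 0.5, 1),
                    )
                if entry is not None:
                    log.append(entry)
            np.testing.assert_array_equal(log.replay(initial), table.cluster)

    def test_operations_never_touch_signals(self):
        table = chain_table()
        rdr, baf = table.rdr.copy(), table.baf.copy()
        cs.merge_by_centroids(table, cs.ThresholdSpec.uniform(0.03, 0.02, 1))
        cs.assign_cluster(table, {0}, -2)
        np.testing.assert_array_equal(table.rdr, rdr)
        np.testing.assert_array_equal(table.baf, baf)
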