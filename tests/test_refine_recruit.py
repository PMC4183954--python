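"""Bin refinement (merge/split/journal/auto) and short-contig recruitment."""

import numpy as np
import pytest

from covbin import (
    auto_refine,
    make_core_bins,
    merge_bins,
    recruit_contigs,
    split_bin,
)
from covbin.core_binning import BinSet
from covbin.refine_recruit import delete_bin, replay_journal
from covbin.synthetic_data import simulate_marker_table


@pytest.fixture()
def binset(core_store):
    return make_core_bins(core_store)


class TestMergeSplit:
    def test_merge_unions_members_under_lowest_id(self, binset):
        ids = sorted(binset.bins)[:2]
        before = binset.bins[ids[0]].members | binset.bins[ids[1]].members
        merge_bins(binset, ids)
        assert binset.bins[ids[0]].members == before
        assert ids[1] not in binset.bins
        assert binset.journal[-1]["kind"] == "merge"

    def test_merge_all_bins_leaves_one(self, binset):
        all_members = set().union(*(b.members for b in binset.bins.values()))
        unbinned_before = set(binset.unbinned)
        merge_bins(binset, list(binset.bins))
        assert len(binset.bins) == 1
        [b] = binset.bins.values()
        assert b.members == all_members
        assert binset.unbinned == unbinned_before

    def test_merge_unknown_bin_raises(self, binset):
        with pytest.raises(KeyError):
            merge_bins(binset, [1, 999])

    def test_split_children_union_is_parent(self, binset):
        bid = sorted(binset.bins)[0]
        parent = set(binset.bins[bid].members)
        n_before = len(binset.bins)
        split_bin(binset, bid, axis="coverage", k=2)
        children = binset.journal[-1]["outputs"]
        assert len(children) == 2
        assert set().union(*(binset.bins[c].members for c in children)) == parent
        assert len(binset.bins) == n_before + 1

    def test_split_too_small_bin_raises(self, binset):
        bid = sorted(binset.bins)[0]
        with pytest.raises(ValueError, match="cannot split"):
            split_bin(binset, bid, k=10_000)

    def test_length_split_matches_exhaustive_1d_oracle(self, binset):
        bid = sorted(binset.bins)[0]
        members = sorted(binset.bins[bid].members)
        logs = np.log10(
            np.array(
                [binset.store.lengths[binset._index[c]] for c in members], dtype=float
            )
        )
        # exhaustive 1-D 2-means: best split point of the sorted values
        order = np.argsort(logs)
        vals = logs[order]
        best_cut, best_cost = None, np.inf
        for cut in range(1, len(vals)):
            left, right = vals[:cut], vals[cut:]
            cost = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            if cost < best_cost:
                best_cut, best_cost = cut, cost
        oracle_left = {members[i] for i in order[:best_cut]}
        split_bin(binset, bid, axis="length", k=2)
        children = [binset.bins[c].members for c in binset.journal[-1]["outputs"]]
        match = min(
            len(children[0] ^ oracle_left), len(children[1] ^ oracle_left)
        )
        assert match <= 1  # within one contig of the optimal threshold

    def test_journal_replay_reproduces_state(self, core_store):
        a = make_core_bins(core_store)
        ids = sorted(a.bins)
        merge_bins(a, ids[:2])
        split_bin(a, ids[0], axis="tf", k=2)
        delete_bin(a, sorted(a.bins)[-1])
        b = replay_journal(make_core_bins(core_store), a.journal)
        assert {k: v.members for k, v in a.bins.items()} == {
            k: v.members for k, v in b.bins.items()
        }
        assert a.unbinned == b.unbinned


class TestAutoRefine:
    def make_toy(self, core_store, n_markers=20):
        return make_core_bins(core_store)

    def test_chimeric_bin_is_split_to_clean_children(self, core_store, core_sim):
        binset = make_core_bins(core_store)
        truth = core_sim.truth
        rows, marker_set = simulate_marker_table(truth, n_markers=20, seed=1)
        ids = sorted(binset.bins)[:2]
        merge_bins(binset, ids)  # fabricate a chimera: two genomes, one bin
        n_before = len(binset.bins)
        auto_refine(binset, rows, marker_set)
        assert len(binset.bins) == n_before + 1
        # children are clean again: contamination back to ~0
        from covbin.refine_recruit import _quality_of

        for b in binset.bins.values():
            assert _quality_of(b.members, rows, marker_set).contamination <= 5.0

    def test_complementary_half_bins_are_merged(self, core_store, core_sim):
        binset = make_core_bins(core_store)
        rows, marker_set = simulate_marker_table(core_sim.truth, n_markers=20, seed=1)
        bid = sorted(binset.bins)[0]
        split_bin(binset, bid, axis="length", k=2)  # two halves of one genome
        n_before = len(binset.bins)
        auto_refine(binset, rows, marker_set)
        assert len(binset.bins) == n_before - 1

    def test_clean_bins_reach_fixpoint_without_actions(self, core_store, core_sim):
        binset = make_core_bins(core_store)
        rows, marker_set = simulate_marker_table(core_sim.truth, n_markers=20, seed=1)
        n_journal = len(binset.journal)
        auto_refine(binset, rows, marker_set)
        assert len(binset.journal) == n_journal

    def test_unknown_contigs_in_marker_table_are_ignored(self, core_store, core_sim):
        binset = make_core_bins(core_store)
        rows, marker_set = simulate_marker_table(core_sim.truth, n_markers=20, seed=1)
        rows.append(("not_a_contig", marker_set[0]))
        auto_refine(binset, rows, marker_set)  # warns, does not raise


class TestRecruit:
    def test_contig_at_centroid_is_recruited(self, core_store, binset):
        # plant an unbinned contig exactly on a bin centroid
        if not binset.unbinned:
            pytest.skip("no unbinned contig in fixture")
        bid = sorted(binset.bins)[0]
        cid = sorted(binset.unbinned)[0]
        i = core_store.index_of(cid)
        old_t, old_tf = core_store.transformed.copy(), core_store.tf_scores.copy()
        core_store.transformed[i] = binset.bins[bid].centroid_cov
        core_store.tf_scores[i] = binset.bins[bid].centroid_tf
        try:
            recruit_contigs(binset, core_store, recruit_min_len=0)
            assert cid in binset.bins[bid].members
        finally:
            core_store.transformed, core_store.tf_scores = old_t, old_tf

    def test_far_outlier_stays_unbinned(self, core_store, binset):
        # distance >> every bin's radius on every axis -> never recruited
        store = core_store
        far = store.transformed.copy()
        i = store.index_of(sorted(binset.unbinned)[0]) if binset.unbinned else None
        if i is None:
            pytest.skip("no unbinned contig in fixture")
        far[i] = far[i] + 1000.0
        old = store.transformed
        store.transformed = far
        try:
            before = {b: set(v.members) for b, v in binset.bins.items()}
            recruit_contigs(binset, store)
            cid = store.contig_ids[i]
            assert all(cid not in v.members for v in binset.bins.values())
        finally:
            store.transformed = old

    def test_recruit_is_idempotent_at_fixpoint(self, core_store, binset):
        recruit_contigs(binset, core_store)
        snapshot = {b: set(v.members) for b, v in binset.bins.items()}
        recruit_contigs(binset, core_store)
        assert snapshot == {b: set(v.members) for b, v in binset.bins.items()}

    def test_core_assignments_never_change(self, core_store, binset):
        core = {b: set(v.members) for b, v in binset.bins.items()}
        recruit_contigs(binset, core_store)
        for bid, members in core.items():
            assert members <= binset.bins[bid].members

    def test_partition_preserved(self, core_store, binset):
        recruit_contigs(binset, core_store)
        assert binset.check_partition()

    def test_empty_binset_raises(self, core_store):
        empty = BinSet(core_store)
        with pytest.raises(ValueError, match="no bins"):
            recruit_contigs(empty, core_store)
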