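"""Trajectory clustering, genotype nesting, introduction times, Muller export."""

import numpy as np
import pytest

from chemevolve import lineage as ln
from chemevolve import pipeline as pl
from chemevolve import synthdata as sd
from conftest import make_trajectory


GRID = (24, 61, 102, 137, 173, 213, 250)
SWEEP = [0.0, 0.05, 0.20, 0.45, 0.70, 0.85, 0.90]


class TestClustering:
    def test_identical_trajectories_merge(self):
        a = make_trajectory("a", SWEEP, final=0.90)
        b = make_trajectory("b", SWEEP, final=0.90)
        clusters = ln.cluster_trajectories([a, b])
        assert len(clusters) == 1
        assert {m.mutation_id for m in clusters[0].members} == {"a", "b"}

    def test_correlation_below_threshold_blocks_merge(self):
        a = make_trajectory("a", SWEEP, final=0.90)
        # search for a perturbation giving r just below 0.97
        base = np.array(SWEEP)
        for eps in np.linspace(0.01, 0.3, 200):
            v = base + eps * np.array([1, -1, 1, -1, 1, -1, 1]) * base.clip(0.02)
            v = np.clip(v, 0, 1)
            r = np.corrcoef(base, v)[0, 1]
            if 0.94 < r < 0.97:
                break
        assert 0.94 < r < 0.97  # direct Pearson oracle
        b = make_trajectory("b", v, final=0.90)
        assert len(ln.cluster_trajectories([a, b])) == 2

    def test_final_frequency_difference_blocks_merge(self):
        # r ~ 1 but terminal deep-seq frequencies 0.30 vs 0.36 (diff > 4%)
        a = make_trajectory("a", np.array(SWEEP) / 3, final=0.30)
        b = make_trajectory("b", np.array(SWEEP) / 3 + 0.002, final=0.36)
        assert len(ln.cluster_trajectories([a, b])) == 2
        # with the 5% variant threshold they merge
        assert len(ln.cluster_trajectories([a, b], max_final_diff=0.07)) == 1

    def test_all_pairs_criterion_prevents_chaining(self):
        # b is close to both a and c, but a and c differ in final freq;
        # average linkage with the all-pairs rule must not chain them
        a = make_trajectory("a", SWEEP, final=0.90)
        b = make_trajectory("b", SWEEP, final=0.93)
        c = make_trajectory("c", SWEEP, final=0.96)
        clusters = ln.cluster_trajectories([a, b, c])
        for cl in clusters:
            finals = [m.final_deepseq_freq for m in cl.members]
            assert max(finals) - min(finals) < 0.04

    def test_constant_trajectory_never_merges_and_warns(self):
        a = make_trajectory("a", [0.3] * 7, final=0.3)
        b = make_trajectory("b", [0.3] * 7, final=0.3)
        with pytest.warns(UserWarning, match="constant"):
            clusters = ln.cluster_trajectories([a, b])
        assert len(clusters) == 2

    def test_clustering_is_permutation_invariant(self, noiseless_trajectories):
        fwd = ln.cluster_trajectories(noiseless_trajectories)
        rev = ln.cluster_trajectories(noiseless_trajectories[::-1])
        as_sets = lambda cls: {
            frozenset(m.mutation_id for m in c.members) for c in cls
        }
        assert as_sets(fwd) == as_sets(rev)

    def test_same_clone_requirement_vetoes_merge(self):
        a = make_trajectory("a", SWEEP, final=0.90, clones=["c1"])
        b = make_trajectory("b", SWEEP, final=0.90, clones=["c2"])
        assert len(ln.cluster_trajectories([a, b], require_same_clone=True)) == 2
        b2 = make_trajectory("b", SWEEP, final=0.90, clones=["c1", "c3"])
        assert len(ln.cluster_trajectories([a, b2], require_same_clone=True)) == 1

    def test_mismatched_grids_rejected(self):
        a = make_trajectory("a", SWEEP)
        b = make_trajectory("b", SWEEP[:5], grid=GRID[:5])
        with pytest.raises(ValueError, match="grid"):
            ln.cluster_trajectories([a, b])


class TestOrdering:
    def test_descending_final_frequency_order(self):
        c = ln.TrajectoryCluster(
            members=[
                make_trajectory("a", SWEEP, final=0.50),
                make_trajectory("b", SWEEP, final=0.48),
            ],
            grid=list(GRID),
        )
        ordered, ties = ln.order_within_cluster(c)
        assert [m.mutation_id for m in ordered] == ["a", "b"]
        assert ties == []

    def test_three_member_strict_chain(self):
        c = ln.TrajectoryCluster(
            members=[
                make_trajectory("x", SWEEP, final=0.5),
                make_trajectory("y", SWEEP, final=0.9),
                make_trajectory("z", SWEEP, final=0.1),
            ],
            grid=list(GRID),
        )
        ordered, ties = ln.order_within_cluster(c)
        assert [m.mutation_id for m in ordered] == ["y", "x", "z"]
        assert not ties

    def test_equal_finals_flagged_unordered(self):
        c = ln.TrajectoryCluster(
            members=[
                make_trajectory("a", SWEEP, final=0.5),
                make_trajectory("b", SWEEP, final=0.5),
            ],
            grid=list(GRID),
        )
        _, ties = ln.order_within_cluster(c)
        assert ties == [("a", "b")]

    def test_missing_final_frequency_errors(self):
        t = make_trajectory("a", SWEEP)
        t.final_deepseq_freq = None
        c = ln.TrajectoryCluster(members=[t], grid=list(GRID))
        with pytest.raises(ValueError, match="deep-seq"):
            ln.order_within_cluster(c)


def _single_cluster(mid, freqs, final=None):
    return ln.TrajectoryCluster(
        members=[make_trajectory(mid, freqs, final=final)], grid=list(GRID)
    )


class TestNesting:
    def test_single_cluster_attaches_to_root(self):
        tree = ln.infer_genotype_nesting([_single_cluster("a", SWEEP)])
        assert tree.edges() == {("ancestor", "a")}

    def test_nested_sweep_recovered_from_truth(self, demo_truth,
                                               noiseless_trajectories):
        clusters = ln.cluster_trajectories(noiseless_trajectories)
        tree = ln.infer_genotype_nesting(clusters)
        assert tree.edges() == pl.true_lineage_tree(demo_truth)

    def test_mutually_exclusive_lineages_become_siblings(self):
        # each lineage exceeds the other at some timepoint (no containment
        # in either direction), so neither topology nests: both brute-force
        # candidate orientations violate the constraints and the clusters
        # must end up as independent lineages under the root
        va = [0.1, 0.3, 0.5, 0.6, 0.6, 0.55, 0.5]
        vb = [0.0, 0.05, 0.1, 0.2, 0.35, 0.45, 0.62]
        tol = 0.05
        assert any(b > a + tol for a, b in zip(va, vb))
        assert any(a > b + tol for a, b in zip(va, vb))
        tree = ln.infer_genotype_nesting(
            [_single_cluster("a", va), _single_cluster("b", vb)],
            containment_tol=tol,
        )
        assert tree.edges() == {("ancestor", "a"), ("ancestor", "b")}

    def test_cluster_above_one_errors(self):
        cluster = _single_cluster("a", [0.1, 0.5, 0.9, 0.9, 0.9, 0.9, 0.9])
        cluster.members[0].freq_by_generation[102] = 1.2  # corrupt input
        with pytest.raises(ValueError, match="exceeds frequency 1"):
            ln.infer_genotype_nesting([cluster])

    def test_clone_membership_vetoes_contradictory_parent(self):
        parent = ln.TrajectoryCluster(
            members=[make_trajectory("p", SWEEP, final=0.9, clones=["c1"])],
            grid=list(GRID),
        )
        child_freqs = list(np.array(SWEEP) * 0.5)
        child = ln.TrajectoryCluster(
            members=[make_trajectory("q", child_freqs, final=0.45, clones=["c2"])],
            grid=list(GRID),
        )
        tree = ln.infer_genotype_nesting([parent, child])
        # clone c2 never carries p, so q cannot nest inside p
        assert ("p", "q") not in tree.edges()
        assert ("ancestor", "q") in tree.edges()


class TestIntroductionTimes:
    def test_first_crossing_of_detection_floor(self):
        freqs = [0.0, 0.02, 0.30, 0.5, 0.6, 0.7, 0.8]
        tree = ln.infer_genotype_nesting([_single_cluster("a", freqs)])
        times = ln.estimate_introduction_times(tree, detection_floor=0.05)
        assert times["a"] == {"generation": 102, "left_censored": False}

    def test_detected_at_first_sample_is_left_censored(self):
        tree = ln.infer_genotype_nesting(
            [_single_cluster("a", [0.10, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])]
        )
        times = ln.estimate_introduction_times(tree)
        assert times["a"]["left_censored"]
        assert times["a"]["generation"] == 24

    def test_never_detected_is_absent(self):
        tree = ln.infer_genotype_nesting(
            [_single_cluster("a", [0.0, 0.01, 0.02, 0.03, 0.04, 0.04, 0.04])]
        )
        times = ln.estimate_introduction_times(tree, detection_floor=0.05)
        assert "a" not in times

    def test_interpolated_crossing_lies_between_samples(self):
        freqs = [0.0, 0.02, 0.30, 0.5, 0.6, 0.7, 0.8]
        tree = ln.infer_genotype_nesting([_single_cluster("a", freqs)])
        times = ln.estimate_introduction_times(tree, interpolate=True)
        assert 61 < times["a"]["generation"] < 102


class TestMullerExport:
    def test_root_only_tree_is_all_ancestor(self):
        tree = ln.GenotypeTree(list(GRID))
        table = ln.to_muller_table(tree)
        assert (table["genotype"] == "ancestor").all()
        assert (table["frequency"] == 1.0).all()

    def test_exclusive_frequency_is_parent_minus_child(self):
        parent = _single_cluster("p", [0.6] * 7)
        child = _single_cluster("q", [0.4] * 7)
        tree = ln.infer_genotype_nesting([parent, child])
        table = ln.to_muller_table(tree)
        at24 = table[table["generation"] == 24].set_index("genotype")["frequency"]
        assert at24["p"] == pytest.approx(0.2)
        assert at24["q"] == pytest.approx(0.4)
        assert at24["ancestor"] == pytest.approx(0.4)

    def test_truth_round_trip_conserves_frequencies(self, demo_truth,
                                                    noiseless_trajectories):
        clusters = ln.cluster_trajectories(noiseless_trajectories)
        tree = ln.infer_genotype_nesting(clusters)
        table = ln.to_muller_table(tree)
        sums = table.groupby("generation")["frequency"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-6)
        # exclusive ancestor fraction equals the truth founder frequency
        gens = list(demo_truth.config.sample_generations)
        founder_truth = demo_truth.frequency_matrix[0, gens]
        anc = table[table["genotype"] == "ancestor"].sort_values("generation")
        np.testing.assert_allclose(
            anc["frequency"].to_numpy(), founder_truth, atol=1e-6
        )

    def test_large_negative_exclusive_frequency_errors(self):
        tree = ln.GenotypeTree(list(GRID))
        tree.add(ln.TreeNode("p", _single_cluster("p", [0.3] * 7), "ancestor",
                             np.full(7, 0.3)))
        tree.add(ln.TreeNode("q", _single_cluster("q", [0.6] * 7), "p",
                             np.full(7, 0.6)))
        with pytest.raises(ValueError, match="negative exclusive frequency"):
            ln.to_muller_table(tree)
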