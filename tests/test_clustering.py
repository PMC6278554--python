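import io as stdio

import numpy as np
import pytest
from Bio import Phylo
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from supermhc.clustering import (
    cut_tree,
    label_supertypes,
    read_assignment,
    wpgma_tree,
    write_assignment,
)
from supermhc.rdi import DissimilarityMatrix


def make_matrix(names, values):
    return DissimilarityMatrix(molecules=list(names),
                               values=np.asarray(values, dtype=float))


def random_matrix(rng, n):
    """Symmetric dissimilarity matrix with distinct (tie-free) entries."""
    vals = rng.permutation(n * (n - 1) // 2) + rng.uniform(0.1, 0.9)
    return squareform(vals / vals.max())


THREE_LEAF = make_matrix(
    "ABC", [[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]]
)


class TestWPGMATree:
    def test_three_leaf_hand_agglomeration(self):
        tree = wpgma_tree(THREE_LEAF)
        heights = [h for _, _, h in tree.merges]
        assert heights == pytest.approx([0.2, 0.7])  # (0.6 + 0.8) / 2

    def test_two_leaves(self):
        tree = wpgma_tree(make_matrix("AB", [[0.0, 0.3], [0.3, 0.0]]))
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == 0.3

    def test_heights_nondecreasing(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            names = [f"M{i}" for i in range(6)]
            tree = wpgma_tree(make_matrix(names, random_matrix(rng, 6)))
            heights = [h for _, _, h in tree.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_merge_heights_match_scipy_weighted_linkage(self, n):
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            d = random_matrix(rng, n)
            tree = wpgma_tree(make_matrix([f"M{i}" for i in range(n)], d))
            ours = sorted(h for _, _, h in tree.merges)
            ref = sorted(linkage(squareform(d), method="weighted")[:, 2])
            assert np.allclose(ours, ref, atol=1e-12)

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(77)
        names = [f"M{i}" for i in range(7)]
        d = random_matrix(rng, 7)
        base = cut_tree(wpgma_tree(make_matrix(names, d)), 0.5)
        perm = rng.permutation(7)
        shuffled = make_matrix([names[i] for i in perm],
                               d[np.ix_(perm, perm)])
        assert cut_tree(wpgma_tree(shuffled), 0.5) == base

    def test_missing_entries_rejected(self):
        d = np.array([[0.0, np.nan, 0.3],
                      [np.nan, 0.0, 0.4],
                      [0.3, 0.4, 0.0]])
        with pytest.raises(ValueError, match="min_overlap"):
            wpgma_tree(make_matrix("ABC", d))

    def test_members_cover_all_leaves(self):
        tree = wpgma_tree(THREE_LEAF)
        root = tree.n_leaves() + len(tree.merges) - 1
        assert sorted(tree.members(root)) == ["A", "B", "C"]


class TestCutTree:
    def test_above_root_single_cluster(self):
        tree = wpgma_tree(THREE_LEAF)
        assert cut_tree(tree, 10.0) == [["A", "B", "C"]]

    def test_below_min_all_singletons(self):
        tree = wpgma_tree(THREE_LEAF)
        assert cut_tree(tree, 0.1) == [["A"], ["B"], ["C"]]

    def test_merge_exactly_at_threshold_does_not_join(self):
        # second merge happens at exactly 0.7: strict inequality keeps
        # {A,B} and {C} apart at a 0.7 cut
        tree = wpgma_tree(THREE_LEAF)
        assert cut_tree(tree, 0.7) == [["A", "B"], ["C"]]

    def test_cluster_count_nonincreasing_in_height(self):
        rng = np.random.default_rng(5)
        names = [f"M{i}" for i in range(8)]
        tree = wpgma_tree(make_matrix(names, random_matrix(rng, 8)))
        counts = [len(cut_tree(tree, h)) for h in np.linspace(0, 1.2, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_every_cut_is_a_partition(self):
        rng = np.random.default_rng(6)
        names = [f"M{i}" for i in range(8)]
        tree = wpgma_tree(make_matrix(names, random_matrix(rng, 8)))
        for h in (0.0, 0.3, 0.6, 2.0):
            part = cut_tree(tree, h)
            flat = [m for c in part for m in c]
            assert sorted(flat) == sorted(names)


class TestLabelSupertypes:
    def test_typical_hla_benchmark_shape(self):
        # 13 DR + 6 DP + two DQ clusters + 7 singletons
        dr = [f"DRB1_{i:04d}" for i in range(13)]
        dp = [f"DP{i}" for i in range(6)]
        dq1 = [f"DQa{i}" for i in range(4)]
        dq2 = [f"DQb{i}" for i in range(2)]
        singletons = [[f"S{i}"] for i in range(7)]
        isotype = {m: "DR" for m in dr}
        isotype |= {m: "DP" for m in dp}
        isotype |= {m: "DQ" for m in dq1 + dq2}
        isotype |= {s[0]: "DR" for s in singletons}
        assignment = label_supertypes([dr, dp, dq1, dq2] + singletons,
                                      isotype)
        assert sorted(assignment.main_clusters) == [
            "mainDP", "mainDQ1", "mainDQ2", "mainDR"]
        assert len(assignment.diverse) == 7
        assert assignment.labels[dq1[0]] == "mainDQ1"  # larger DQ cluster
        assert assignment.labels[dq2[0]] == "mainDQ2"
        assert assignment.labels["S0"] == "diverse"

    def test_all_singletons_all_diverse(self):
        partition = [["A"], ["B"], ["C"]]
        assignment = label_supertypes(partition, {m: "DR" for m in "ABC"})
        assert assignment.main_clusters == []
        assert sorted(assignment.diverse) == ["A", "B", "C"]

    def test_partition_property(self):
        partition = [["A", "B"], ["C"], ["D", "E", "F"]]
        isotype = dict.fromkeys("ABCDEF", "DQ")
        assignment = label_supertypes(partition, isotype)
        assert sorted(assignment.labels) == list("ABCDEF")
        labels = set(assignment.labels.values())
        assert labels == {"mainDQ1", "mainDQ2", "diverse"}

    def test_assignment_tsv_round_trip(self, tmp_path):
        partition = [["A", "B"], ["C"]]
        assignment = label_supertypes(partition,
                                      {"A": "DR", "B": "DR", "C": "DP"})
        path = tmp_path / "supertypes.tsv"
        write_assignment(assignment, path)
        loaded = read_assignment(path)
        assert loaded.labels == assignment.labels
        assert sorted(loaded.main_clusters) == \
            sorted(assignment.main_clusters)


class TestNewickExport:
    def test_parseable_and_ultrametric(self):
        rng = np.random.default_rng(21)
        names = [f"M{i}" for i in range(6)]
        tree = wpgma_tree(make_matrix(names, random_matrix(rng, 6)))
        phylo = Phylo.read(stdio.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in phylo.get_terminals()) == names
        root_height = tree.merges[-1][2]
        for leaf in phylo.get_terminals():
            assert phylo.distance(phylo.root, leaf) == pytest.approx(
                root_height / 2.0, abs=1e-6)

    def test_linkage_export_shape(self):
        tree = wpgma_tree(THREE_LEAF)
        z = tree.to_linkage()
        assert z.shape == (2, 4)
        assert z[-1, 3] == 3  # root covers all leaves
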