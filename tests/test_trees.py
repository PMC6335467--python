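import itertools

import numpy as np
import pytest
from _oracles import beta_sim_oracle, edge_bitmasks, random_newick, taxonomic_simpson

from phyloturn.trees import (Phylogeny, branch_partition, delta_transform,
                             faith_pd, phylo_simpson, read_newick_trees,
                             truncate_tree, write_newick_trees)


class TestFaithPD:
    def test_two_tip_clade(self, basic_tree):
        assert faith_pd(basic_tree, {"A", "B"}) == pytest.approx(3.0)

    def test_empty_community_is_zero(self, basic_tree):
        assert faith_pd(basic_tree, set()) == 0.0

    def test_all_tips_is_total_length(self, basic_tree):
        assert faith_pd(basic_tree, {"A", "B", "C", "D"}) == pytest.approx(6.0)

    def test_unknown_tip_named_in_error(self, basic_tree):
        with pytest.raises(KeyError, match="ZZZ"):
            faith_pd(basic_tree, {"A", "ZZZ"})

    def test_single_tip_is_root_path(self, basic_tree):
        assert faith_pd(basic_tree, {"A"}) == pytest.approx(2.0)


class TestBranchPartition:
    def test_disjoint_clades(self, basic_tree):
        p = branch_partition(basic_tree, {"A", "B"}, {"C", "D"})
        assert (p.a, p.b, p.c) == pytest.approx((0.0, 3.0, 3.0))

    def test_identical_communities(self, basic_tree):
        p = branch_partition(basic_tree, {"A", "C"}, {"A", "C"})
        assert p.a == pytest.approx(faith_pd(basic_tree, {"A", "C"}))
        assert p.b == pytest.approx(0.0)
        assert p.c == pytest.approx(0.0)

    def test_overlapping_communities(self, basic_tree):
        p = branch_partition(basic_tree, {"A", "B"}, {"A", "C"})
        assert (p.a, p.b, p.c) == pytest.approx((2.0, 1.0, 2.0))

    def test_sum_equals_union_pd(self, basic_tree):
        p = branch_partition(basic_tree, {"A", "B"}, {"A", "C"})
        assert p.a + p.b + p.c == pytest.approx(
            faith_pd(basic_tree, {"A", "B", "C"})
        )

    def test_empty_community_rejected(self, basic_tree):
        with pytest.raises(ValueError):
            branch_partition(basic_tree, set(), {"A"})


class TestPhyloSimpson:
    def test_disjoint_clades_full_turnover(self, basic_tree):
        assert phylo_simpson(basic_tree, {"A", "B"}, {"C", "D"}) == pytest.approx(1.0)

    def test_identical_communities_zero(self, basic_tree):
        assert phylo_simpson(basic_tree, {"A", "C"}, {"A", "C"}) == 0.0

    def test_overlap_one_third(self, basic_tree):
        assert phylo_simpson(basic_tree, {"A", "B"}, {"A", "C"}) == pytest.approx(1 / 3)

    def test_nested_community_zero(self, basic_tree):
        assert phylo_simpson(basic_tree, {"A"}, {"A", "B"}) == 0.0

    def test_symmetry_and_range_random_subsets(self, rng):
        tree = Phylogeny.from_newick(random_newick(rng, 8))
        tips = tree.tips
        for _ in range(100):
            c1 = set(rng.choice(tips, size=rng.integers(1, 8), replace=False))
            c2 = set(rng.choice(tips, size=rng.integers(1, 8), replace=False))
            b12 = phylo_simpson(tree, c1, c2)
            b21 = phylo_simpson(tree, c2, c1)
            assert b12 == pytest.approx(b21, abs=1e-12)
            assert 0.0 <= b12 <= 1.0
            assert phylo_simpson(tree, c1, c1) == 0.0

    def test_matches_edge_classification_oracle(self, rng):
        newick = random_newick(rng, 8)
        tree = Phylogeny.from_newick(newick)
        labels, edges = edge_bitmasks(newick)
        bit = {lbl: 1 << i for i, lbl in enumerate(labels)}
        for _ in range(200):
            c1 = set(rng.choice(labels, size=rng.integers(1, 8), replace=False))
            c2 = set(rng.choice(labels, size=rng.integers(1, 8), replace=False))
            m1 = sum(bit[t] for t in c1)
            m2 = sum(bit[t] for t in c2)
            assert phylo_simpson(tree, c1, c2) == pytest.approx(
                beta_sim_oracle(edges, m1, m2), abs=1e-12
            )

    def test_star_tree_reduces_to_taxonomic(self, rng):
        n = 10
        newick = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
        tree = Phylogeny.from_newick(newick)
        tips = tree.tips
        for _ in range(50):
            c1 = set(rng.choice(tips, size=rng.integers(1, n), replace=False))
            c2 = set(rng.choice(tips, size=rng.integers(1, n), replace=False))
            assert phylo_simpson(tree, c1, c2) == pytest.approx(
                taxonomic_simpson(c1, c2), abs=1e-12
            )


class TestDeltaTransform:
    def test_identity_preserves_distances(self, rng):
        tree = Phylogeny.from_newick(random_newick(rng, 12))
        out = delta_transform(tree, 1.0)
        np.testing.assert_allclose(
            out.tip_distance_matrix(), tree.tip_distance_matrix(), rtol=1e-9
        )

    def test_two_tip_tree_unchanged(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        out = delta_transform(tree, 10.0)
        np.testing.assert_allclose(out.lengths, tree.lengths, atol=1e-12)

    def test_cube_on_unit_height_tree(self):
        tree = Phylogeny.from_newick("((A:0.5,B:0.5):0.5);")
        out = delta_transform(tree, 3.0, preserve_height=True)
        # internal node depth 0.5 -> 0.125: stem 0.125, tips 0.875
        got = {out.labels[i]: out.lengths[i] for i in range(out.n_nodes)}
        assert got["A"] == pytest.approx(0.875)
        assert got["B"] == pytest.approx(0.875)
        internal = [out.lengths[i] for i in range(out.n_nodes)
                    if out.children(i) and i > 0]
        assert internal == [pytest.approx(0.125)]

    @pytest.mark.parametrize("delta", [0.1, 0.3, 3.0, 10.0])
    def test_height_preserved_and_depth_shift_sign(self, rng, delta):
        tree = Phylogeny.from_newick(random_newick(rng, 10))
        out = delta_transform(tree, delta, preserve_height=True)
        assert out.height == pytest.approx(tree.height, rel=1e-9)
        h = tree.height
        old = tree.node_depths / h
        new = out.node_depths / h
        internal = [i for i in range(1, tree.n_nodes) if tree.children(i)]
        if delta > 1:  # recent branches stretched: depths move rootward
            assert all(new[i] <= old[i] + 1e-12 for i in internal)
        else:
            assert all(new[i] >= old[i] - 1e-12 for i in internal)

    def test_invalid_delta(self, basic_tree):
        with pytest.raises(ValueError):
            delta_transform(basic_tree, 0.0)
        with pytest.raises(ValueError):
            delta_transform(basic_tree, -2.0)

    def test_topology_and_tips_unchanged(self, rng):
        tree = Phylogeny.from_newick(random_newick(rng, 9))
        out = delta_transform(tree, 3.0)
        assert out.tips == tree.tips
        np.testing.assert_array_equal(out.parent, tree.parent)


class TestTruncateTree:
    def test_cut_at_root_gives_basal_clades(self, basic_tree):
        out, mapping = truncate_tree(basic_tree, 0.0)
        assert out.n_tips == 2
        groups = {}
        for tip, grp in mapping.items():
            groups.setdefault(grp, set()).add(tip)
        assert sorted(map(sorted, groups.values())) == [["A", "B"], ["C", "D"]]

    def test_cut_below_tips_keeps_identity(self, basic_tree):
        out, mapping = truncate_tree(basic_tree, 1.5)
        assert out.n_tips == 4
        assert mapping == {t: t for t in "ABCD"}

    def test_cut_through_stems_collapses_cherries(self, basic_tree):
        out, mapping = truncate_tree(basic_tree, 0.5)
        assert out.n_tips == 2
        assert mapping["A"] == mapping["B"]
        assert mapping["C"] == mapping["D"]
        assert mapping["A"] != mapping["C"]
        # collapsed tips sit exactly at the cut
        assert out.height == pytest.approx(0.5)

    def test_tie_at_cut_is_half_open(self, basic_tree):
        # the internal nodes sit at depth 1: their child branches are cut
        out, mapping = truncate_tree(basic_tree, 1.0)
        assert out.n_tips == 4
        assert mapping == {t: t for t in "ABCD"}

    def test_mapping_partitions_tips_random(self, rng):
        for _ in range(20):
            tree = Phylogeny.from_newick(random_newick(rng, 10))
            depth = rng.uniform(0.0, tree.height * 0.999)
            out, mapping = truncate_tree(tree, depth)
            assert set(mapping) == set(tree.tips)  # total
            assert set(mapping.values()) == set(out.tips)  # onto
            assert out.height <= depth + 1e-12 or depth == 0.0

    def test_depth_near_height_bijective(self, rng):
        tree = Phylogeny.from_newick(random_newick(rng, 8))
        internal_max = max(
            tree.node_depths[i] for i in range(tree.n_nodes) if tree.children(i)
        )
        depth = 0.5 * (internal_max + tree.height)
        out, mapping = truncate_tree(tree, depth)
        assert sorted(out.tips) == sorted(tree.tips)

    def test_invalid_depth(self, basic_tree):
        with pytest.raises(ValueError):
            truncate_tree(basic_tree, 2.0)
        with pytest.raises(ValueError):
            truncate_tree(basic_tree, -0.1)


class TestNewickIO:
    def test_round_trip(self, rng, tmp_path):
        trees = [Phylogeny.from_newick(random_newick(rng, 7)) for _ in range(3)]
        path = tmp_path / "trees.nwk"
        write_newick_trees(trees, path)
        back = read_newick_trees(path)
        assert len(back) == 3
        for t1, t2 in zip(trees, back):
            assert t1.tips == t2.tips
            np.testing.assert_allclose(
                t1.tip_distance_matrix(), t2.tip_distance_matrix(), rtol=1e-9
            )

    def test_labels_with_spaces_are_quoted(self):
        tree = Phylogeny.from_newick("('Homo sapiens':1,B:1);")
        text = tree.to_newick()
        assert "'Homo sapiens'" in text
        assert Phylogeny.from_newick(text).tips == tree.tips

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError):
            Phylogeny.from_newick("((A:1,B:1),C:2);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValueError):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")
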