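import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from stenobarcode.distmat import DistanceMatrix
from stenobarcode.treetime import (
    ClockConfig,
    clock_dates,
    midpoint_root,
    nj_tree,
    node_heights,
    outgroup_root,
    tree_from_newick,
    ultrametricize,
)


def random_binary_tree(rng, n, lo=0.1, hi=1.0):
    """Random unrooted binary tree with uniform branch lengths."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        leaf.edge.length = float(rng.uniform(lo, hi))
        nodes.append(leaf)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes.pop(j), nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(lo, hi))
        nodes.append(parent)
    for node in nodes:
        tree.seed_node.add_child(node)
    return tree


def patristic_matrix(tree):
    """Tip-to-tip path-length matrix as a DistanceMatrix (by path summation)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                ta = tree.taxon_namespace.get_taxon(a)
                tb = tree.taxon_namespace.get_taxon(b)
                d[i, j] = d[j, i] = pdm.patristic_distance(ta, tb)
    return DistanceMatrix(labels=labels, d=d, model="p")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(labels=["A", "B", "C"], d=d, model="p")
        tree = nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        # pendant edges (d_AB + d_AC - d_BC)/2 etc.
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix by path summation
        true = tree_from_newick("((A:1,B:2):0.5,(C:3,D:4):0.5);")
        true.is_rooted = False
        dm = patristic_matrix(true)
        got = nj_tree(dm)
        got.migrate_taxon_namespace(true.taxon_namespace)
        got.encode_bipartitions()
        true.encode_bipartitions()
        assert treecompare.symmetric_difference(true, got) == 0
        back = patristic_matrix(got)
        assert np.allclose(back.d, dm.d, atol=1e-9)

    def test_additive_matrices_recovered_up_to_eight_taxa(self):
        rng = np.random.default_rng(21)
        for n in (4, 5, 6, 7, 8):
            for _ in range(5):
                true = random_binary_tree(rng, n)
                dm = patristic_matrix(true)
                got = nj_tree(dm)
                got.migrate_taxon_namespace(true.taxon_namespace)
                assert treecompare.symmetric_difference(
                    true, got, is_bipartitions_updated=False
                ) == 0
                assert np.allclose(patristic_matrix(got).d, dm.d, atol=1e-8)

    def test_ultrametric_nesting_recovered(self):
        # ((A,B) at h=1, +C at h=2, +D at h=3): NJ must join A,B first
        true = tree_from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        true.is_rooted = False
        dm = patristic_matrix(true)
        got = nj_tree(dm)
        got.migrate_taxon_namespace(true.taxon_namespace)
        assert treecompare.symmetric_difference(
            true, got, is_bipartitions_updated=False
        ) == 0

    def test_incomplete_matrix_rejected(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]], dtype=float)
        dm = DistanceMatrix(labels=["a", "b", "c"], d=d, model="p")
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    def test_negative_lengths_clamped_with_warning(self):
        # strongly non-additive matrix forces a negative NJ estimate
        d = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.05],
                [0.6, 0.6, 0.05, 0.0],
            ]
        )
        d[0, 2] = d[2, 0] = 0.9
        dm = DistanceMatrix(labels=list("abcd"), d=d, model="p")
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(dm)
        assert all(
            (e.length or 0.0) >= 0.0 for e in tree.preorder_edge_iter()
        )


class TestRooting:
    def test_two_branch_midpoint(self):
        tree = tree_from_newick("(A:1,B:3);")
        tree.is_rooted = False
        rooted = midpoint_root(tree)
        dists = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in rooted.leaf_node_iter()
        }
        assert dists["A"] == pytest.approx(2.0)
        assert dists["B"] == pytest.approx(2.0)

    def test_symmetric_four_tip_root_on_central_edge(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tree.is_rooted = False
        rooted = midpoint_root(tree)
        sides = [
            {l.taxon.label for l in ch.leaf_iter()}
            for ch in rooted.seed_node.child_nodes()
        ]
        assert {frozenset(s) for s in sides} == {
            frozenset({"A", "B"}), frozenset({"C", "D"}),
        }

    def test_midpoint_halves_the_diameter(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            tree = random_binary_tree(rng, 8)
            dm = patristic_matrix(tree)
            diameter = dm.d.max()
            rooted = midpoint_root(tree)
            far = max(
                leaf.distance_from_root()
                for leaf in rooted.leaf_node_iter()
            )
            assert far == pytest.approx(diameter / 2)

    def test_outgroup_root_on_pendant_edge(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,O:1):1);")
        tree.is_rooted = False
        rooted = outgroup_root(tree, ["O"])
        sides = [
            {l.taxon.label for l in ch.leaf_iter()}
            for ch in rooted.seed_node.child_nodes()
        ]
        assert {frozenset(s) for s in sides} == {
            frozenset({"O"}), frozenset({"A", "B", "C"}),
        }

    def test_outgroup_clade_stem(self):
        tree = tree_from_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,(O1:1,O2:1):1);"
        )
        tree.is_rooted = False
        rooted = outgroup_root(tree, ["O1", "O2"])
        sides = {
            frozenset(l.taxon.label for l in ch.leaf_iter())
            for ch in rooted.seed_node.child_nodes()
        }
        assert frozenset({"O1", "O2"}) in sides

    def test_polyphyletic_outgroup_warns_deterministically(self):
        tree = tree_from_newick("((A:1,O1:1):1,(B:1,O2:1):1);")
        tree.is_rooted = False
        with pytest.warns(UserWarning, match="not separable"):
            r1 = outgroup_root(tree, ["O1", "O2"])
        with pytest.warns(UserWarning):
            r2 = outgroup_root(tree, ["O1", "O2"])
        assert r1.as_string(schema="newick") == r2.as_string(schema="newick")

    def test_all_outgroup_rejected(self):
        tree = tree_from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            outgroup_root(tree, ["A", "B", "C"])


class TestUltrametricize:
    def test_fixed_point_on_ultrametric_tree(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);",
                                rooted=True)
        fitted = ultrametricize(tree)
        for before, after in zip(tree.preorder_node_iter(),
                                 fitted.preorder_node_iter()):
            if before.parent_node is not None:
                assert after.edge.length == pytest.approx(
                    before.edge.length, abs=1e-12
                )

    def test_two_tip_mean_height(self):
        tree = tree_from_newick("(A:0.1,B:0.3);", rooted=True)
        fitted = ultrametricize(tree)
        heights = node_heights(fitted)
        assert heights[fitted.seed_node] == pytest.approx(0.2)
        for leaf in fitted.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(0.2)

    def test_tips_equidistant_from_root(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = midpoint_root(random_binary_tree(rng, 7))
            fitted = ultrametricize(tree)
            dists = [
                leaf.distance_from_root()
                for leaf in fitted.leaf_node_iter()
            ]
            assert max(dists) - min(dists) < 1e-9

    def test_noisy_clock_heights_recovered_within_two_sigma(self):
        # perturb pendant edges of a clock tree by N(0, sigma); the fitted
        # node heights (means over subtended tips) stay within 2 sigma
        sigma = 0.01
        for seed in range(100):
            rng = np.random.default_rng(seed)
            from stenobarcode.synthetic_data import SimParams, simulate_yule_tree

            dated = simulate_yule_tree(
                SimParams(n_tips=8, birth_rate=0.04, seed=seed)
            )
            tree = dated.tree.clone(depth=1)
            rate = 0.0016
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= rate
            true_heights = {
                id(n): h for n, h in node_heights(tree).items()
            }
            noisy = tree.clone(depth=1)
            for leaf in noisy.leaf_node_iter():
                leaf.edge.length = max(
                    0.0, leaf.edge.length + rng.normal(0.0, sigma)
                )
            fitted = ultrametricize(noisy)
            for t_node, f_node in zip(tree.preorder_node_iter(),
                                      fitted.preorder_node_iter()):
                if t_node.is_leaf():
                    continue
                h_true = true_heights[id(t_node)]
                h_fit = node_heights(fitted)[f_node]
                assert abs(h_fit - h_true) <= 2 * sigma

    def test_unrooted_input_rejected(self):
        tree = tree_from_newick("(A:1,B:1,C:1);")
        tree.is_rooted = False
        with pytest.raises(ValueError):
            ultrametricize(tree)


class TestClockDates:
    def test_two_tip_split_age(self):
        # pairwise distance 0.0032 -> height 0.0016 -> age 1 Ma at the rate
        tree = tree_from_newick("(A:0.0016,B:0.0016);", rooted=True)
        clock = ClockConfig(rate=0.0016, rate_sd=0.0, n_draws=10)
        dated = clock_dates(tree, clock)
        assert dated.root_age == pytest.approx(1.0)

    def test_doubling_rate_halves_ages(self):
        tree = tree_from_newick("((A:0.01,B:0.01):0.01,C:0.02);",
                                rooted=True)
        slow = clock_dates(tree, ClockConfig(rate=0.001, rate_sd=0.0,
                                             root_age_prior_sd=1e9))
        fast = clock_dates(tree, ClockConfig(rate=0.002, rate_sd=0.0,
                                             root_age_prior_sd=1e9))
        for a, b in zip(slow.table, fast.table):
            assert a.age == pytest.approx(2 * b.age)

    def test_intervals_contain_point_estimate(self):
        tree = tree_from_newick("((A:0.01,B:0.01):0.01,C:0.02);",
                                rooted=True)
        dated = clock_dates(tree, ClockConfig(seed=0, root_age_prior_sd=1e9))
        for row in dated.table:
            assert row.lo <= row.age <= row.hi

    def test_parent_older_than_child_everywhere(self):
        rng = np.random.default_rng(8)
        tree = ultrametricize(midpoint_root(random_binary_tree(rng, 8)))
        dated = clock_dates(tree, ClockConfig(seed=1, root_age_prior_sd=1e9))
        ages = {row.node_id: row.age for row in dated.table}
        by_tips = {row.tip_labels: row.age for row in dated.table}
        for tips_child, age_child in by_tips.items():
            for tips_parent, age_parent in by_tips.items():
                if set(tips_child) < set(tips_parent):
                    assert age_child < age_parent
        assert dated.root_age == max(ages.values())

    def test_zero_height_tree_all_zero_ages(self):
        tree = tree_from_newick("(A:0,B:0);", rooted=True)
        dated = clock_dates(tree, ClockConfig(seed=0, root_age_prior_sd=1e9))
        assert dated.root_age == 0.0

    def test_rate_draws_seeded_and_truncated(self):
        clock = ClockConfig(seed=4)
        draws1, draws2 = clock.draw_rates(), clock.draw_rates()
        assert np.array_equal(draws1, draws2)
        assert (draws1 > 0).all()

    def test_implausible_root_age_warns(self):
        tree = tree_from_newick("(A:1.6,B:1.6);", rooted=True)  # 1000 Ma
        with pytest.warns(UserWarning, match="prior plausibility"):
            clock_dates(tree, ClockConfig(seed=0))


def test_relabeling_taxa_permutes_outputs_consistently():
    d = np.array(
        [
            [0.0, 0.2, 0.5, 0.6],
            [0.2, 0.0, 0.5, 0.6],
            [0.5, 0.5, 0.0, 0.3],
            [0.6, 0.6, 0.3, 0.0],
        ]
    )
    dm1 = DistanceMatrix(labels=list("abcd"), d=d, model="p")
    perm = [2, 3, 0, 1]
    dm2 = DistanceMatrix(
        labels=[dm1.labels[i] for i in perm],
        d=d[np.ix_(perm, perm)],
        model="p",
    )
    t1, t2 = nj_tree(dm1), nj_tree(dm2)
    t2.migrate_taxon_namespace(t1.taxon_namespace)
    assert treecompare.symmetric_difference(
        t1, t2, is_bipartitions_updated=False
    ) == 0
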