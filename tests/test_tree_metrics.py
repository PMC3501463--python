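import math

import dendropy
import numpy as np
import pytest

from indelphy.io_formats import SupportTree
from indelphy.tree_metrics import (
    bin_depth_support,
    build_tree_from_clades,
    congruent_clades,
    decay_regression,
    majority_consensus,
    node_depths,
    resolution,
    tree_support,
)

from conftest import all_rooted_binary_newicks, newick_clades


def tree_from(newick: str) -> SupportTree:
    t = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True, rooting="force-rooted",
    )
    for node in t.preorder_node_iter():
        if not node.is_leaf() and node.label not in (None, ""):
            node.support = float(node.label)
            node.label = None
    return SupportTree(t)


class TestResolution:
    def test_fully_resolved_five_tips(self):
        t = tree_from("((((A:1,B:1)1:1,C:1)1:1,D:1)1:1,E:1);")
        assert t.m == 3
        assert resolution(t) == 1.0

    def test_star(self):
        t = tree_from("(A:1,B:1,C:1,D:1,E:1);")
        assert resolution(t) == 0.0

    def test_basal_polytomy(self):
        t = tree_from("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert resolution(t) == pytest.approx(2 / 3)

    def test_too_few_tips(self):
        t = tree_from("(A:1,B:1);")
        with pytest.raises(ValueError):
            resolution(t)

    def test_matches_bracket_count_on_all_small_trees(self):
        # exhaustive: every rooted binary topology on 4 and 5 tips; for a
        # rooted binary newick, m = (number of '(') - 1
        for labels in (("A", "B", "C", "D"), ("A", "B", "C", "D", "E")):
            for nwk in all_rooted_binary_newicks(labels):
                t = tree_from(nwk)
                assert t.m == nwk.count("(") - 1
                assert resolution(t) == 1.0


class TestTreeSupport:
    def test_unanimous_fully_resolved_is_one(self):
        t = tree_from("(((A:1,B:1)1.0:1,C:1)1.0:1,D:1);")
        assert tree_support(t).tree_support == 1.0

    def test_mean_support_arithmetic(self):
        t = tree_from("((((A:1,B:1)1.0:1,C:1)1.0:1,D:1)0.5:1,E:1);")
        s = tree_support(t)
        assert s.resolution == 1.0
        assert s.mean_support == pytest.approx(2.5 / 3)
        assert s.tree_support == pytest.approx(0.83333, abs=1e-4)

    def test_star_is_zero(self):
        s = tree_support(tree_from("(A:1,B:1,C:1,D:1);"))
        assert s.tree_support == 0.0 and math.isnan(s.mean_support)

    def test_missing_support_raises(self):
        t = tree_from("((A:1,B:1):1,(C:1,D:1)0.9:1);")
        with pytest.raises(ValueError):
            tree_support(t)

    def test_product_bound(self):
        t = tree_from("(((A:1,B:1)0.7:1,C:1)0.9:1,(D:1,E:1)0.6:1);")
        s = tree_support(t)
        assert s.tree_support <= min(s.resolution, s.mean_support) + 1e-12


class TestNodeDepths:
    def test_cherry(self):
        t = tree_from("((A:0.1,B:0.3):1,C:1);")
        d = node_depths(t)
        assert d[frozenset("AB")] == pytest.approx(0.2)

    def test_ultrametric_equals_height(self):
        t = tree_from("(((A:1,B:1):1,C:2):1,D:3);")
        d = node_depths(t)
        assert d[frozenset("AB")] == pytest.approx(1.0)
        assert d[frozenset("ABC")] == pytest.approx(2.0)
        assert d[frozenset("ABCD")] == pytest.approx(3.0)

    def test_caterpillar_root_mean(self):
        t = tree_from("((A:1,B:1):1,C:3);")
        d = node_depths(t)
        assert d[frozenset("ABC")] == pytest.approx((2 + 2 + 3) / 3)

    def test_missing_branch_length_raises(self):
        t = tree_from("((A:1,B),C:1);")
        with pytest.raises(ValueError):
            node_depths(t)

    def test_invariant_under_child_reordering(self):
        d1 = node_depths(tree_from("((A:1,B:2):1,(C:3,D:4):2);"))
        d2 = node_depths(tree_from("((D:4,C:3):2,(B:2,A:1):1);"))
        assert set(d1) == set(d2)
        for k in d1:
            assert d1[k] == pytest.approx(d2[k])

    def test_exhaustive_path_sums_small_trees(self):
        # brute force: depth = mean over leaves of explicit path sums
        rng = np.random.default_rng(7)
        for nwk in all_rooted_binary_newicks(("A", "B", "C", "D", "E")):
            t = dendropy.Tree.get(data=nwk, schema="newick",
                                  rooting="force-rooted")
            for e in t.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.uniform(0.1, 2.0))
            st = SupportTree(t)
            got = node_depths(st)
            pdm = {}
            for node in st.tree.preorder_node_iter():
                if node.is_leaf():
                    continue
                paths = []
                for leaf in node.leaf_iter():
                    total, v = 0.0, leaf
                    while v is not node:
                        total += v.edge.length
                        v = v.parent_node
                    paths.append(total)
                key = frozenset(l.taxon.label for l in node.leaf_iter())
                pdm[key] = sum(paths) / len(paths)
            for k, v in pdm.items():
                assert got[k] == pytest.approx(v)


class TestBinning:
    def test_one_point_per_bin(self):
        p = bin_depth_support([(0.1, 0.8), (0.9, 0.4)], K=2)
        assert p.means == (0.8, 0.4)

    def test_single_bin_is_global_mean(self):
        p = bin_depth_support([(0.1, 0.8), (0.9, 0.4), (0.5, 0.6)], K=1)
        assert p.means[0] == pytest.approx(0.6)

    def test_conservation_identity(self, rng):
        pts = [(float(rng.uniform(0, 3)), float(rng.uniform(0, 1)))
               for _ in range(1000)]
        p = bin_depth_support(pts, K=800)
        global_mean = sum(s for _, s in pts) / len(pts)
        assert p.global_mean == pytest.approx(global_mean, abs=1e-12)

    def test_identical_depths_single_occupied_bin(self):
        p = bin_depth_support([(0.5, 0.2), (0.5, 0.8)], K=10)
        assert sum(c > 0 for c in p.counts) == 1
        assert p.global_mean == pytest.approx(0.5)


class TestCongruence:
    def test_identical_trees_pair_every_clade(self):
        a = tree_from("(((A:1,B:1)0.9:1,C:1)0.8:1,(D:1,E:1)0.7:1);")
        b = tree_from("(((A:1,B:1)0.95:1,C:1)0.85:1,(D:1,E:1)0.75:1);")
        pairs = congruent_clades(a, b)
        assert len(pairs) == 3

    def test_disjoint_resolutions_share_nothing(self):
        a = tree_from("((A:1,B:1)0.9:1,(C:1,D:1)0.9:1);")
        b = tree_from("((A:1,C:1)0.9:1,(B:1,D:1)0.9:1);")
        assert congruent_clades(a, b) == []

    def test_single_shared_clade(self):
        a = tree_from("((((A:1,B:1)0.9:1,C:1)0.9:1,D:1)0.9:1,(E:1,F:1)0.9:1);")
        b = tree_from("((((A:1,B:1)0.8:1,D:1)0.8:1,C:1)0.8:1,(E:1,F:1)0.4:1);")
        pairs = congruent_clades(a, b)
        assert {frozenset(p.clade) for p in pairs} == {
            frozenset("AB"), frozenset("EF"), frozenset("ABCD"),
        }

    def test_symmetry(self):
        a = tree_from("(((A:1,B:1)0.9:1,C:1)0.8:1,(D:1,E:1)0.7:1);")
        b = tree_from("(((A:1,B:1)0.5:1,(C:1,D:1)0.6:1)0.4:1,E:1);")
        ab = congruent_clades(a, b)
        ba = congruent_clades(b, a)
        assert {(p.clade, p.support_a, p.support_b) for p in ab} == {
            (p.clade, p.support_b, p.support_a) for p in ba
        }

    def test_tip_mismatch_raises(self):
        a = tree_from("((A:1,B:1)0.9:1,C:1);")
        b = tree_from("((A:1,B:1)0.9:1,D:1);")
        with pytest.raises(ValueError, match="C|D"):
            congruent_clades(a, b)

    def test_ratio_direction(self):
        a = tree_from("((A:1,B:1)0.5:1,(C:1,D:1)0.8:1);")
        b = tree_from("((A:1,B:1)1.0:1,(C:1,D:1)0.4:1);")
        ratios = {p.clade: p.ratio for p in congruent_clades(a, b)}
        assert ratios[frozenset("AB")] == pytest.approx(2.0)
        assert ratios[frozenset("CD")] == pytest.approx(0.5)


class TestDecayRegression:
    def test_exact_line(self):
        pts = [(d, 1 - 0.5 * d) for d in (0.0, 0.4, 1.0, 1.6)]
        fit = decay_regression(pts)
        assert fit.slope == pytest.approx(-0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_support(self):
        fit = decay_regression([(0.1, 0.7), (0.5, 0.7), (0.9, 0.7)])
        assert fit.slope == pytest.approx(0.0)

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 2, 20)
        y = 0.9 - 0.3 * x + rng.normal(0, 0.05, 20)
        fit = decay_regression(list(zip(x, y)))
        # independent closed-form OLS
        xb, yb = x.mean(), y.mean()
        slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
        intercept = yb - slope * xb
        resid = y - intercept - slope * x
        s2 = (resid ** 2).sum() / (len(x) - 2)
        slope_se = math.sqrt(s2 / ((x - xb) ** 2).sum())
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.slope_se == pytest.approx(slope_se, abs=1e-10)

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError):
            decay_regression([(0.5, 0.1), (0.5, 0.9), (0.5, 0.4)])


class TestMajorityConsensus:
    def test_identical_trees(self):
        trees = [tree_from("(((A:1,B:1):1,C:1):1,D:1);") for _ in range(3)]
        cons = majority_consensus(trees)
        sup = cons.clade_supports()
        assert set(sup) == {frozenset("AB"), frozenset("ABC")}
        assert all(v == 1.0 for v in sup.values())

    def test_two_thirds_clade(self):
        trees = [
            tree_from("((A:1,B:1):1,C:1,D:1);"),
            tree_from("((A:1,B:1):1,C:1,D:1);"),
            tree_from("((A:1,C:1):1,B:1,D:1);"),
        ]
        cons = majority_consensus(trees)
        sup = cons.clade_supports()
        assert sup == {frozenset("AB"): pytest.approx(2 / 3)}

    def test_maximal_conflict_gives_star(self):
        trees = [
            tree_from("(((A:1,B:1):1,C:1):1,D:1);"),
            tree_from("(((D:1,C:1):1,B:1):1,A:1);"),
        ]
        cons = majority_consensus(trees)
        assert cons.m == 0

    def test_mean_edge_lengths(self):
        trees = [
            tree_from("((A:1,B:1):1,C:1,D:1);"),
            tree_from("((A:2,B:1):3,C:1,D:1);"),
        ]
        cons = majority_consensus(trees)
        node = cons.clade_leafsets()[frozenset("AB")]
        assert node.edge.length == pytest.approx(2.0)

    def test_retained_clades_pairwise_compatible(self, rng):
        # random tree sets: the consensus builds without incompatibility
        labels = ("A", "B", "C", "D", "E", "F")
        pool = list(all_rooted_binary_newicks(labels))
        for _ in range(10):
            pick = rng.choice(len(pool), size=7, replace=True)
            trees = [tree_from(pool[i]) for i in pick]
            cons = majority_consensus(trees)   # raises if incompatible
            for clade in cons.clade_supports():
                count = sum(clade in t.clade_leafsets() for t in trees)
                assert count / len(trees) > 0.5

    def test_agrees_with_dendropy_consensus(self, rng):
        # independent library oracle on random 6-tip tree sets
        labels = ("A", "B", "C", "D", "E", "F")
        pool = list(all_rooted_binary_newicks(labels))
        for _ in range(5):
            pick = rng.choice(len(pool), size=9, replace=True)
            newicks = [pool[i] for i in pick]
            mine = majority_consensus([tree_from(n) for n in newicks])
            tns = dendropy.TaxonNamespace()
            tl = dendropy.TreeList(
                [dendropy.Tree.get(data=n, schema="newick",
                                   taxon_namespace=tns,
                                   rooting="force-rooted") for n in newicks]
            )
            dcons = tl.consensus(min_freq=0.5)
            dcons.is_rooted = True
            dclades = set()
            for node in dcons.preorder_node_iter():
                if node.is_leaf() or node is dcons.seed_node:
                    continue
                c = frozenset(l.taxon.label for l in node.leaf_iter())
                if len(c) < len(labels):
                    dclades.add(c)
            assert set(mine.clade_supports()) == dclades

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            majority_consensus([])

    def test_exhaustive_clade_frequencies_small_trees(self, rng):
        # brute-force oracle: clade frequencies counted from newick strings
        labels = ("A", "B", "C", "D", "E")
        pool = list(all_rooted_binary_newicks(labels))
        for _ in range(10):
            pick = rng.choice(len(pool), size=5, replace=True)
            newicks = [pool[i] for i in pick]
            counts = {}
            for n in newicks:
                for c in newick_clades(n):
                    counts[c] = counts.get(c, 0) + 1
            expected = {
                c: k / len(newicks)
                for c, k in counts.items() if k / len(newicks) > 0.5
            }
            mine = majority_consensus([tree_from(n) for n in newicks])
            got = {c: s for c, s in mine.clade_supports().items()}
            assert got == pytest.approx(expected)
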