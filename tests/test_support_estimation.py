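import dendropy
import numpy as np
import pytest

from indelphy.indel_coding import simple_indel_coding
from indelphy.io_formats import MultipleAlignment
from indelphy.support_estimation import (
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
)
from indelphy.tree_metrics import tree_support


def aln_of(*pairs):
    return MultipleAlignment.from_pairs(list(pairs))


class TestPairwiseDistance:
    def test_identical_rows(self):
        d = pairwise_distance(aln_of(("a", "ACGT"), ("b", "ACGT")))
        assert d.values[0, 1] == 0.0

    def test_single_mismatch(self):
        d = pairwise_distance(aln_of(("a", "AAAA"), ("b", "AAAC")))
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_gaps_and_missing_excluded(self):
        d = pairwise_distance(aln_of(("a", "AC-TN"), ("b", "ACGTA")))
        # comparable columns: 0,1,3 -> no mismatches
        assert d.values[0, 1] == 0.0

    def test_combined_weighting(self):
        # 4 comparable nt columns with 1 mismatch + 2 indel characters
        # with 1 mismatch: (1+1)/(4+2)
        aln = aln_of(
            ("a", "AAAA--G-T"),
            ("b", "AAAC--G-T"),
            ("c", "AAAAGGGAT"),
        )
        indels = simple_indel_coding(aln)
        assert indels.n_characters == 2
        d = pairwise_distance(MultipleAlignment(
            ("a", "b"), ("AAAA", "AAAC")), None)
        assert d.values[0, 1] == pytest.approx(0.25)
        full = pairwise_distance(
            MultipleAlignment(aln.taxa, ("AAAA", "AAAC", "AAAA")),
            indels,
        )
        # a vs c: 0 nt mismatches in 4, 2/2 indel mismatches -> 2/6
        assert full.values[0, 2] == pytest.approx(2 / 6)

    def test_no_comparable_positions_names_pair(self):
        aln = aln_of(("a", "AC--"), ("b", "--GT"))
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_distance(aln)


def _additive_distances(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return tuple(t.label for t in taxa), d


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        taxa = ("a", "b", "c")
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = neighbor_joining(DistanceMatrix(taxa, d))
        # pendant lengths solve the three-point formulas:
        # la = (dab+dac-dbc)/2 = 0.1, lb = 0.2, lc = 0.4
        lens = {}
        for leaf in t.tree.leaf_node_iter():
            lens[leaf.taxon.label] = leaf.edge.length
        # the smallest taxon's pendant edge is split by the root
        assert lens["a"] == pytest.approx(0.05)
        assert lens["b"] == pytest.approx(0.2)
        assert lens["c"] == pytest.approx(0.4)

    @pytest.mark.parametrize("newick", [
        "((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.2);",
        "(((A:0.1,B:0.2):0.1,C:0.3):0.25,(D:0.1,E:0.4):0.1);",
    ])
    def test_recovers_additive_topology(self, newick):
        taxa, d = _additive_distances(newick)
        t = neighbor_joining(DistanceMatrix(taxa, d))
        got = set(t.clade_leafsets())
        import re
        from conftest import newick_clades
        expected = newick_clades(newick)
        # the rooted-at-first-taxon convention adds the all-but-first clade
        full = frozenset(taxa)
        expected_rooted = set()
        for c in expected:
            side = c if taxa[0] not in c else full - c
            if 2 <= len(side) < len(taxa):
                expected_rooted.add(side)
        expected_rooted.add(full - {taxa[0]})
        assert got == expected_rooted

    def test_random_additive_trees_recovered(self, rng):
        # random 5-8 tip trees; distances are exactly additive
        for _ in range(15):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            tns = dendropy.TaxonNamespace(labels)
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                taxon_namespace=tns,
                rng=__import__("random").Random(int(rng.integers(1 << 30))),
            )
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.uniform(0.05, 1.0))
            nwk = tree.as_string(schema="newick").strip()
            taxa, d = _additive_distances(nwk)
            t = neighbor_joining(DistanceMatrix(tuple(taxa), d))
            # verify via unrooted splits against the generating tree
            from conftest import newick_clades
            gen = newick_clades(nwk.replace("[&R] ", ""))
            full = frozenset(taxa)
            gen_rooted = set()
            for c in gen:
                side = c if taxa[0] not in c else full - c
                if 2 <= len(side) < len(taxa):
                    gen_rooted.add(side)
            gen_rooted.add(full - {taxa[0]})
            assert set(t.clade_leafsets()) == gen_rooted

    def test_matches_skbio_on_random_matrices(self, rng):
        # independent implementation cross-check (unrooted splits)
        import skbio
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            n = int(rng.integers(4, 8))
            taxa = tuple(f"t{i}" for i in range(n))
            m = rng.uniform(0.1, 1.0, (n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = neighbor_joining(DistanceMatrix(taxa, d))
            sk = skbio_nj(skbio.DistanceMatrix(d, taxa))
            sk_splits = set()
            for node in sk.postorder():
                if node.is_tip() or node.is_root():
                    continue
                tips = frozenset(t.name for t in node.tips())
                side = tips if taxa[0] not in tips else frozenset(taxa) - tips
                if 2 <= len(side) < n:
                    sk_splits.add(side)
            sk_splits.add(frozenset(taxa) - {taxa[0]})
            assert set(mine.clade_leafsets()) == sk_splits

    def test_all_equal_distances_deterministic(self):
        taxa = tuple("abcde")
        d = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(DistanceMatrix(taxa, d))
        t2 = neighbor_joining(DistanceMatrix(taxa, d))
        assert t1.as_newick() == t2.as_newick()
        assert t1.m == 3  # fully resolved despite ties

    def test_non_finite_rejected(self):
        taxa = ("a", "b", "c")
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            DistanceMatrix(taxa, d)


def structured_alignment(n_cols_diag=20, n_cols_const=30):
    """Two 3-taxon groups separated at n_cols_diag diagnostic columns."""
    g1 = "A" * n_cols_diag
    g2 = "C" * n_cols_diag
    const = "G" * n_cols_const
    rng = np.random.default_rng(5)
    def noisy(base):
        return "".join(
            ch if rng.random() > 0.05 else "ACGT"[rng.integers(0, 4)]
            for ch in base
        )
    return MultipleAlignment.from_pairs([
        ("a1", noisy(g1) + const), ("a2", noisy(g1) + const),
        ("a3", noisy(g1) + const),
        ("b1", noisy(g2) + const), ("b2", noisy(g2) + const),
        ("b3", noisy(g2) + const),
    ])


class TestBootstrap:
    def test_seed_reproducibility(self):
        aln = structured_alignment()
        t1 = bootstrap_support(aln, None, B=50, seed=11)
        t2 = bootstrap_support(aln, None, B=50, seed=11)
        assert t1.as_newick() == t2.as_newick()
        assert t1.clade_supports() == t2.clade_supports()

    def test_strong_groups_highly_supported(self):
        aln = structured_alignment()
        t = bootstrap_support(aln, None, B=100, seed=3)
        sup = t.clade_supports()
        grp_b = frozenset(["b1", "b2", "b3"])
        assert sup.get(grp_b, 0) >= 0.95

    def test_supports_in_unit_interval_and_taxon_order_invariant(self, rng):
        aln = structured_alignment()
        perm = rng.permutation(aln.n_taxa)
        shuffled = MultipleAlignment(
            tuple(aln.taxa[i] for i in perm),
            tuple(aln.rows[i] for i in perm),
        )
        t1 = bootstrap_support(aln, None, B=50, seed=9)
        t2 = bootstrap_support(shuffled, None, B=50, seed=9)
        for v in t1.clade_supports().values():
            assert 0.0 <= v <= 1.0
        assert t1.clade_supports() == t2.clade_supports()

    def test_zero_variation_deterministic(self):
        aln = MultipleAlignment.from_pairs(
            [(f"t{i}", "ACGTACGTAC") for i in range(5)]
        )
        t1 = bootstrap_support(aln, None, B=10, seed=2)
        t2 = bootstrap_support(aln, None, B=10, seed=2)
        assert t1.as_newick() == t2.as_newick()
        # no internal signal: no clade beyond the rooting convention
        nontrivial = [c for c in t1.clade_supports() if len(c) < 4]
        assert nontrivial == []

    def test_more_diagnostic_columns_never_lower_support(self):
        # statistical monotonicity of signal
        sups = []
        for k in (2, 10, 30):
            aln = structured_alignment(n_cols_diag=k)
            t = bootstrap_support(aln, None, B=100, seed=21)
            sup = t.clade_supports().get(frozenset(["b1", "b2", "b3"]), 0.0)
            sups.append(sup)
        assert sups[0] <= sups[1] + 0.05 and sups[1] <= sups[2] + 0.05

    def test_partitioned_resampling_uses_indels(self):
        # groups distinguished ONLY by a shared indel
        rows = {
            "a1": "AAAA----CCCCGGGG", "a2": "AAAA----CCCCGGGG",
            "a3": "AAAA----CCCCGGGG",
            "b1": "AAAATTTTCCCCGGGG", "b2": "AAAATTTTCCCCGGGG",
            "b3": "AAAATTTTCCCCGGGG",
        }
        aln = MultipleAlignment.from_pairs(sorted(rows.items()))
        indels = simple_indel_coding(aln)
        assert indels.n_characters == 1
        t = bootstrap_support(aln, indels, B=100, seed=4)
        sup = t.clade_supports()
        assert sup.get(frozenset(["b1", "b2", "b3"]), 0) > 0.5
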