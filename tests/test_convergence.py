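"""AT-column filtering, NJ reconstruction, bootstrap, collapse, placement."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.optimize import nnls

from atbias import convergence as cv
from atbias.types import MultipleAlignment, TaxonGroups
from conftest import random_dna


def patristic(tree: dendropy.Tree, taxa):
    """Pairwise path-length matrix of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(taxa)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(tns.get_taxon(taxa[i]),
                                   tns.get_taxon(taxa[j]))
        D[i, j] = D[j, i] = d
    return D


def random_additive_matrix(rng, n):
    """Distance matrix realized by a random binary tree with positive edges."""
    taxa = [f"t{i}" for i in range(n)]
    # random topology by sequential joining, random positive branch lengths
    newick_nodes = list(taxa)
    while len(newick_nodes) > 1:
        i, j = sorted(rng.choice(len(newick_nodes), size=2, replace=False))
        b = newick_nodes.pop(j)
        a = newick_nodes.pop(i)
        la, lb = rng.uniform(0.1, 2.0, size=2)
        newick_nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    tree = dendropy.Tree.get(data=newick_nodes[0] + ";", schema="newick",
                             preserve_underscores=True)
    return patristic(tree, taxa), taxa, tree


class TestFilterATColumns:
    def test_definition_on_focal_row(self):
        aln = MultipleAlignment(["f", "x", "y"],
                                ["AG-C", "CCCC", "GGGG"])
        out = cv.filter_at_columns(aln, {"f"})
        assert out.row("f") == "G-C"
        assert out.row("x") == "CCC"
        assert out.n_columns == 3

    def test_gc_only_focal_row_is_identity(self):
        aln = MultipleAlignment(["f", "x"], ["GCGC", "ATAT"])
        assert cv.filter_at_columns(aln, {"f"}) == aln

    def test_gap_and_n_in_focal_retain_column(self):
        aln = MultipleAlignment(["f", "x"], ["-NAT", "ATAT"])
        out = cv.filter_at_columns(aln, {"f"})
        assert out.row("f") == "-N"

    def test_matches_per_column_scan(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        rows = [random_dna(rng, 120, p=(0.4, 0.1, 0.1, 0.4))
                for _ in taxa]
        aln = MultipleAlignment(taxa, rows)
        out = cv.filter_at_columns(aln, {"t0"})
        survivors = [c for c in range(120) if rows[0][c] not in "AT"]
        assert out.n_columns == len(survivors)
        assert out.row("t3") == "".join(rows[3][c] for c in survivors)

    def test_idempotent(self, rng):
        aln = MultipleAlignment(
            ["a", "b", "c"], [random_dna(rng, 60) for _ in range(3)])
        once = cv.filter_at_columns(aln, {"a"})
        assert cv.filter_at_columns(once, {"a"}) == once

    def test_commutes_with_taxon_reordering(self, rng):
        rows = [random_dna(rng, 60) for _ in range(3)]
        aln = MultipleAlignment(["a", "b", "c"], rows)
        flipped = MultipleAlignment(["c", "b", "a"], rows[::-1])
        out1 = cv.filter_at_columns(aln, {"b"})
        out2 = cv.filter_at_columns(flipped, {"b"})
        assert out1.row("a") == out2.row("a")
        assert out1.row("c") == out2.row("c")

    def test_unknown_focal_errors(self):
        aln = MultipleAlignment(["a", "b"], ["AC", "GT"])
        with pytest.raises(KeyError, match="nope"):
            cv.filter_at_columns(aln, {"nope"})

    def test_no_surviving_columns_errors(self):
        aln = MultipleAlignment(["a", "b"], ["AT", "GC"])
        with pytest.raises(ValueError, match="no columns survive"):
            cv.filter_at_columns(aln, {"a"})


class TestPairwiseDistance:
    def test_identical_rows_are_zero(self):
        aln = MultipleAlignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        for model in ("p-distance", "jc69", "k2p"):
            assert cv.pairwise_distance(aln, model)[0, 1] == 0.0

    def test_p_distance_hand_count(self):
        # 3 mismatches over 12 sites
        aln = MultipleAlignment(["a", "b"],
                                ["ACGTACGTACGT", "ACGTACGTTGCT"])
        assert cv.pairwise_distance(aln, "p-distance")[0, 1] == \
            pytest.approx(0.25)

    def test_jc69_closed_form(self):
        aln = MultipleAlignment(["a", "b"],
                                ["ACGTACGTACGT", "ACGTACGTTGCT"])
        d = cv.pairwise_distance(aln, "jc69")[0, 1]
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * 0.25 / 3),
                                  abs=1e-9)
        assert d == pytest.approx(0.304099, abs=5e-7)

    def test_saturated_pair_capped_with_warning(self):
        aln = MultipleAlignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.warns(UserWarning, match="saturated"):
            d = cv.pairwise_distance(aln, "jc69")[0, 1]
        assert d == cv.DISTANCE_CAP

    def test_pairwise_deletion_of_ambiguous_sites(self):
        aln = MultipleAlignment(["a", "b"], ["ACGTN-", "ACGAAC"])
        # comparable sites: first 4; one mismatch
        assert cv.pairwise_distance(aln, "p-distance")[0, 1] == \
            pytest.approx(0.25)

    def test_no_comparable_sites_errors(self):
        aln = MultipleAlignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="no comparable sites"):
            cv.pairwise_distance(aln, "p-distance")


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> distances below
        taxa = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        tree = cv.nj_tree(D, taxa)
        assert cv.tree_bipartitions(tree) == {frozenset({"A", "B"})}
        assert np.allclose(patristic(tree, taxa), D, atol=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = cv.nj_tree(D, ["a", "b", "c"])
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_exactness_on_random_additive_matrices(self, rng):
        for n in (5, 6, 8):
            D, taxa, true_tree = random_additive_matrix(rng, n)
            tree = cv.nj_tree(D, taxa)
            assert np.allclose(patristic(tree, taxa), D, atol=1e-9)
            assert cv.tree_bipartitions(tree) == \
                cv.tree_bipartitions(true_tree)

    def test_matches_exhaustive_least_squares_at_n5(self, rng):
        """Brute-force oracle: best of all 15 unrooted 5-taxon topologies."""
        D, taxa, _ = random_additive_matrix(rng, 5)
        pairs = list(itertools.combinations(range(5), 2))
        best_sse, best_cherries = None, None
        seen = set()
        for c1 in itertools.combinations(range(5), 2):
            for c2 in itertools.combinations(
                    [k for k in range(5) if k not in c1], 2):
                key = frozenset((frozenset(c1), frozenset(c2)))
                if key in seen:
                    continue
                seen.add(key)
                # edges: 5 pendant + 2 internal (one per cherry)
                A = np.zeros((len(pairs), 7))
                for row, (i, j) in enumerate(pairs):
                    A[row, i] = A[row, j] = 1
                    if (i in c1) != (j in c1):
                        A[row, 5] = 1
                    if (i in c2) != (j in c2):
                        A[row, 6] = 1
                y = np.array([D[i, j] for i, j in pairs])
                x, rnorm = nnls(A, y)
                if best_sse is None or rnorm < best_sse:
                    best_sse, best_cherries = rnorm, key
        tree = cv.nj_tree(D, taxa)
        nj_cherries = set()
        for split in cv.tree_bipartitions(tree):
            idx = frozenset(taxa.index(t) for t in split)
            if len(idx) > 2:  # normalized split may be the 3-taxon side
                idx = frozenset(range(5)) - idx
            nj_cherries.add(idx)
        assert nj_cherries == set(best_cherries)

    def test_agrees_with_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        D, taxa, _ = random_additive_matrix(rng, 7)
        mine = cv.nj_tree(D, taxa)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=taxa))
        theirs_dp = dendropy.Tree.get(data=str(theirs), schema="newick",
                                      preserve_underscores=True)
        assert cv.tree_bipartitions(mine) == cv.tree_bipartitions(theirs_dp)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            cv.nj_tree(np.array([[0, np.nan], [np.nan, 0]]), ["a", "b"])
        bad = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="negative"):
            cv.nj_tree(bad, ["a", "b", "c"])


def _supported_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        if node.label is not None:
            node.support = int(node.label)
    return tree


class TestBootstrapAndCollapse:
    @pytest.fixture()
    def alignment(self, rng):
        from atbias.synthetic_data import (default_convergence_scenario,
                                           simulate_alignment)
        scenario, _ = default_convergence_scenario(seed=11, length=600,
                                                   n_background=3)
        aln, _ = simulate_alignment(scenario)
        return aln

    def test_supports_are_percentages_and_reproducible(self, alignment):
        t1 = cv.bootstrap_tree(alignment, replicates=20, seed=5)
        t2 = cv.bootstrap_tree(alignment, replicates=20, seed=5)
        s1 = sorted(n.support for n in
                    t1.preorder_internal_node_iter(exclude_seed_node=True)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in
                    t2.preorder_internal_node_iter(exclude_seed_node=True)
                    if hasattr(n, "support"))
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_collapse_identity_when_all_strong(self):
        tree = _supported_tree("((a:1,b:1)100:1,(c:1,d:1)95:1,e:1);")
        collapsed = cv.collapse_low_support(tree, threshold=70)
        assert cv.tree_bipartitions(collapsed) == cv.tree_bipartitions(tree)

    def test_collapse_to_star_when_all_weak(self):
        tree = _supported_tree("((a:1,b:1)0:1,(c:1,d:1)10:1,e:1);")
        collapsed = cv.collapse_low_support(tree, threshold=70)
        assert cv.tree_bipartitions(collapsed) == set()
        assert cv.leaf_labels(collapsed) == cv.leaf_labels(tree)

    def test_collapse_matches_bipartition_filter(self, rng):
        """Oracle: surviving splits == input splits with support >= 70."""
        D, taxa, _ = random_additive_matrix(rng, 8)
        tree = cv.nj_tree(D, taxa)
        internal = [n for n in tree.preorder_internal_node_iter(
            exclude_seed_node=True)]
        supports = rng.integers(0, 101, size=len(internal))
        expected = set()
        leaves = cv.leaf_labels(tree)
        ref = min(leaves)
        for node, sup in zip(internal, supports):
            node.support = int(sup)
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if 2 <= len(below) <= len(leaves) - 2 and sup >= 70:
                expected.add(below if ref in below else leaves - below)
        collapsed = cv.collapse_low_support(tree, threshold=70)
        assert cv.tree_bipartitions(collapsed) == expected
        # original tree untouched
        assert len(list(tree.leaf_node_iter())) == 8


class TestPlacement:
    GROUPS = TaxonGroups({"f": "plants", "p1": "plants", "p2": "plants",
                          "s1": "protists", "s2": "protists",
                          "s3": "protists"})

    def test_focal_nested_in_other_group(self):
        tree = _supported_tree("((f:1,s1:1)100:1,(s2:1,s3:1)100:1,"
                               "(p1:1,p2:1)100:1);")
        report = cv.placement(tree, "f", self.GROUPS)
        assert report.clade_taxa == ("f", "s1")
        assert report.label == "protists"
        assert report.attachment_tally == {"plants": 2, "protists": 3}

    def test_focal_with_own_group(self):
        tree = _supported_tree("((f:1,p1:1)100:1,(s2:1,s3:1)100:1,"
                               "(s1:1,p2:1)100:1);")
        report = cv.placement(tree, "f", self.GROUPS)
        assert report.label == "plants"

    def test_tie_is_unresolved(self):
        tree = _supported_tree("(((f:1,p1:1)100:1,s1:1)100:1,s2:1,"
                               "(p2:1,s3:1)100:1);")
        # smallest clade is (f,p1); strict majority holds -> plants.
        # now collapse everything: the star tallies 2 plants vs 3 protists
        star = cv.collapse_low_support(
            _supported_tree("((f:1,p1:1)0:1,(s1:1,s2:1)0:1,"
                            "(p2:1,s3:1)0:1);"), 70)
        report = cv.placement(star, "f", self.GROUPS)
        assert report.clade_taxa == tuple(sorted(self.GROUPS.mapping))
        assert report.label == "protists"  # 3 of 5 non-focal: majority
        # a 2-2 split among non-focal members is a tie -> unresolved
        even_star = cv.collapse_low_support(
            _supported_tree("((f:1,p1:1)0:1,s1:1,(p2:1,s2:1)0:1);"), 70)
        assert cv.placement(even_star, "f", self.GROUPS).label == \
            "unresolved"

    def test_missing_focal_errors(self):
        tree = _supported_tree("((p1:1,p2:1)100:1,s1:1,s2:1);")
        with pytest.raises(ValueError, match="focal"):
            cv.placement(tree, "f", self.GROUPS)


class TestConvergenceTest:
    def test_paired_report_on_synthetic_scenario(self):
        from atbias.synthetic_data import (default_convergence_scenario,
                                           simulate_alignment)
        scenario, groups = default_convergence_scenario(seed=0, length=1200)
        aln, _ = simulate_alignment(scenario)
        result = cv.convergence_test(aln, "focal_plant", groups,
                                     replicates=25, seed=99)
        assert result.before.label == "protists"  # compositional attraction
        assert result.after.label != "protists"
        assert result.moved
        assert result.params["columns_after"] < result.params[
            "columns_before"]
        payload = result.to_dict()
        assert payload["before"]["placement_label"] == "protists"

    def test_short_filtered_alignment_warns_in_report(self):
        from atbias.synthetic_data import (default_convergence_scenario,
                                           simulate_alignment)
        scenario, groups = default_convergence_scenario(seed=2, length=300,
                                                        n_background=3)
        aln, _ = simulate_alignment(scenario)
        result = cv.convergence_test(aln, "focal_plant", groups,
                                     replicates=10, seed=1,
                                     min_columns=100)
        assert any("columns" in w for w in result.warnings)
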