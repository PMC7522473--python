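import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from oracles import entanglement_bruteforce
from riboscreen.phylo import (
    bootstrap_support,
    concatenate_alignments,
    entanglement,
    jc_distance,
    nj_tree,
    p_distance,
    tree_bipartitions,
)


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        d = p_distance([("a", "ACGT"), ("b", "ACGT")])
        assert d["a", "b"] == 0.0

    def test_one_difference_over_four_sites(self):
        d = p_distance([("a", "ACGT"), ("b", "ACGA")])
        assert d["a", "b"] == 0.25

    def test_pairwise_deletion_ignores_gapped_sites(self):
        d = p_distance([("a", "AC-T"), ("b", "ACGT")])
        assert d["a", "b"] == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            p_distance([("a", "ACGT"), ("b", "ACG")])

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance([("a", "--AA"), ("b", "GG--")])

    def test_jukes_cantor_exceeds_p_distance(self):
        aln = [("a", "ACGTACGTAC"), ("b", "ACGAACGTTC")]
        assert jc_distance(aln)["a", "b"] > p_distance(aln)["a", "b"]


def _random_additive_matrix(rng, n_taxa):
    """Distances from a randomly agglomerated tree with random branches."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    paths = {t: [] for t in taxa}  # edge ids with lengths from root
    groups = [[t] for t in taxa]
    edge = 0
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        for g, _ in ((groups[i], 0), (groups[j], 1)):
            length = float(rng.uniform(0.1, 1.0))
            for t in g:
                paths[t].append((edge, length))
            edge += 1
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [
            groups[i] + groups[j]
        ]
    d = np.zeros((n_taxa, n_taxa))
    for x, y in itertools.combinations(range(n_taxa), 2):
        ex = dict(paths[taxa[x]])
        ey = dict(paths[taxa[y]])
        shared = set(ex) & set(ey)
        dist = sum(v for k, v in ex.items() if k not in shared) + sum(
            v for k, v in ey.items() if k not in shared
        )
        d[x, y] = d[y, x] = dist
    return DistanceMatrix(d, taxa)


class TestNeighborJoining:
    def test_three_taxa_closed_form_branch_lengths(self):
        dm = DistanceMatrix(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], ["a", "b", "c"]
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_five_taxon_additive_matrix_recovered_exactly(self):
        # hand-built from ((a:2,b:3):1,(c:1,d:4):2,e:5)
        ids = ["a", "b", "c", "d", "e"]
        d = np.array(
            [
                [0, 5, 6, 9, 8],
                [5, 0, 7, 10, 9],
                [6, 7, 0, 5, 8],
                [9, 10, 5, 0, 11],
                [8, 9, 8, 11, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(d, ids))
        recovered = tree.tip_tip_distances(ids)
        np.testing.assert_allclose(recovered.data, d, atol=1e-9)
        assert frozenset({"a", "b"}) in tree_bipartitions(tree)
        assert frozenset({"c", "d"}) in tree_bipartitions(tree)

    def test_exact_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            dm = _random_additive_matrix(rng, int(rng.integers(4, 9)))
            tree = nj_tree(dm)
            recovered = tree.tip_tip_distances(list(dm.ids))
            np.testing.assert_allclose(recovered.data, dm.data, atol=1e-8)

    def test_topology_agrees_with_skbio_reference(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            dm = _random_additive_matrix(rng, 7)
            assert tree_bipartitions(nj_tree(dm)) == tree_bipartitions(skbio_nj(dm))

    def test_equal_distances_resolve_deterministically(self):
        dm = DistanceMatrix(1 - np.eye(4), ["a", "b", "c", "d"])
        t1 = str(nj_tree(dm))
        t2 = str(nj_tree(dm))
        assert t1 == t2

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_negative_branch_estimates_clamp_with_warning(self):
        d = np.array(
            [[0, 1, 1, 10], [1, 0, 1.9, 10], [1, 1.9, 0, 1], [10, 10, 1, 0]]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(DistanceMatrix(d, list("abcd")))
        assert all(t.length >= 0 for t in tree.traverse() if t.length is not None)


class TestBootstrap:
    ALN = [("a", "AAAAA"), ("b", "AAAAA"), ("c", "TTTTT"), ("d", "TTTTT"), ("e", "TTGTT")]

    def test_unanimous_split_gets_support_100(self):
        tree = bootstrap_support(self.ALN, n_replicates=50, seed=0)
        supports = {
            frozenset(t.name for t in node.tips()): node.support
            for node in tree.non_tips(include_self=False)
            if getattr(node, "support", None) is not None
        }
        assert supports[frozenset({"a", "b"})] == 100.0

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_support(self.ALN, n_replicates=30, seed=42)
        t2 = bootstrap_support(self.ALN, n_replicates=30, seed=42)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if n.support is not None)
        assert s1 == s2

    def test_supports_stay_within_range(self):
        rng = np.random.default_rng(4)
        aln = [
            (f"t{i}", "".join(rng.choice(list("ACGT"), size=40))) for i in range(6)
        ]
        tree = bootstrap_support(aln, n_replicates=25, seed=1)
        for node in tree.non_tips(include_self=False):
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0


def _random_binary_tree(rng, leaves):
    nodes = [TreeNode(name=leaf) for leaf in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


class TestEntanglement:
    def test_identical_trees_score_zero(self):
        t = TreeNode.read(["((a,b),(c,(d,e)));"])
        u = TreeNode.read(["((a,b),(c,(d,e)));"])
        assert entanglement(t, u).score == 0.0

    def test_matches_exhaustive_rotation_search_on_small_trees(self):
        rng = np.random.default_rng(13)
        leaves = list("abcde")
        for _ in range(10):
            t1 = _random_binary_tree(rng, leaves)
            t2 = _random_binary_tree(rng, leaves)
            expected = entanglement_bruteforce(t1, t2)
            assert entanglement(t1, t2).score == pytest.approx(expected)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(29)
        t1 = _random_binary_tree(rng, list("abcdef"))
        t2 = _random_binary_tree(rng, list("abcdef"))
        assert entanglement(t1, t2).score == pytest.approx(
            entanglement(t2, t1).score
        )

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(31)
        t1 = _random_binary_tree(rng, list("abcde"))
        t2 = _random_binary_tree(rng, list("abcde"))
        baseline = entanglement(t1, t2).score
        mapping = dict(zip("abcde", "vwxyz"))
        for tree in (t1, t2):
            for tip in tree.tips():
                tip.name = mapping[tip.name]
        assert entanglement(t1, t2).score == pytest.approx(baseline)

    def test_leaf_set_mismatch_rejected(self):
        t1 = TreeNode.read(["((a,b),c);"])
        t2 = TreeNode.read(["((a,b),d);"])
        with pytest.raises(ValueError, match="leaf sets"):
            entanglement(t1, t2)

    def test_planted_horizontal_transfer_raises_entanglement(self):
        """Rib genes copied into a distant subclade must entangle the rib
        tree against the housekeeping tree more than a housekeeping
        replicate does — the tanglegram logic at desk scale."""
        rng = np.random.default_rng(37)
        clades = {"ab": "AAAAAAAAAA", "cd": "CCCCCCCCCC", "ef": "GGGGGGGGGG"}

        def seq(clade_sig, private):
            return clade_sig + private

        def private(n=6):
            return "".join(rng.choice(list("ACGT"), size=n))

        hk = [
            ("a", seq(clades["ab"], private())),
            ("b", seq(clades["ab"], private())),
            ("c", seq(clades["cd"], private())),
            ("d", seq(clades["cd"], private())),
            ("e", seq(clades["ef"], private())),
            ("f", seq(clades["ef"], private())),
        ]
        # horizontal transfer: e and f carry the ab-clade rib signature
        rib = [
            ("a", seq(clades["ab"], private())),
            ("b", seq(clades["ab"], private())),
            ("c", seq(clades["cd"], private())),
            ("d", seq(clades["cd"], private())),
            ("e", seq(clades["ab"], private())),
            ("f", seq(clades["ab"], private())),
        ]
        hk_tree = nj_tree(p_distance(hk))
        rib_tree = nj_tree(p_distance(rib))
        hk_again = bootstrap_support(hk, n_replicates=1, seed=11)
        discordant = entanglement(hk_tree, rib_tree).score
        concordant = entanglement(hk_tree, hk_again).score
        assert discordant > concordant


class TestConcatenation:
    def test_missing_taxa_are_gap_filled(self):
        a1 = [("a", "ACGT"), ("b", "ACGT")]
        a2 = [("a", "GG"), ("c", "GG")]
        joined = dict(concatenate_alignments(a1, a2))
        assert joined["b"] == "ACGT--"
        assert joined["c"] == "----GG"
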