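"""Neighbor joining and nonparametric rate smoothing."""

import dendropy
import numpy as np
import pytest

from intetax import DistanceMatrix, is_ultrametric, neighbor_joining, nprs_smooth
from intetax.trees import collapse_haplotypes, patristic_matrix
from intetax import LabeledAlignment


def random_ultrametric_like_tree(rng, n_taxa):
    """Random rooted binary tree with positive branch lengths (not clock-like)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{l}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0, 2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return dendropy.Tree.get(data=nodes[0] + ";", schema="newick",
                             preserve_underscores=True), labels


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree_exactly(self):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.08):0.07);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        ids = ["A", "B", "C", "D"]
        pm = patristic_matrix(tree, ids)
        nj = neighbor_joining(DistanceMatrix(ids, pm))
        assert np.allclose(patristic_matrix(nj, ids), pm, atol=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        nj = neighbor_joining(DistanceMatrix(ids, d))
        assert np.allclose(patristic_matrix(nj, ids), d, atol=1e-9)

    def test_additive_recovery_on_random_trees(self, rng):
        """NJ inverts tree -> matrix -> tree on 5-8 taxon additive matrices."""
        for _ in range(25):
            n = int(rng.integers(5, 9))
            tree, ids = random_ultrametric_like_tree(rng, n)
            pm = patristic_matrix(tree, ids)
            nj = neighbor_joining(DistanceMatrix(ids, pm))
            assert np.allclose(patristic_matrix(nj, ids), pm, atol=1e-8)

    def test_permuted_input_gives_same_tree(self, rng):
        tree, ids = random_ultrametric_like_tree(rng, 7)
        pm = patristic_matrix(tree, ids)
        noisy = pm + 0.005 * (lambda m: m + m.T)(
            np.triu(rng.normal(0, 1, pm.shape), 1)
        )
        np.fill_diagonal(noisy, 0.0)
        noisy = np.abs(noisy)
        nj1 = neighbor_joining(DistanceMatrix(ids, noisy))
        perm = list(rng.permutation(len(ids)))
        nj2 = neighbor_joining(
            DistanceMatrix([ids[p] for p in perm], noisy[np.ix_(perm, perm)])
        )
        assert np.allclose(
            patristic_matrix(nj1, ids), patristic_matrix(nj2, ids), atol=1e-9
        )

    def test_agrees_with_skbio_topology(self, rng):
        """Independent cross-check against scikit-bio's NJ on a noisy matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        tree, ids = random_ultrametric_like_tree(rng, 6)
        pm = patristic_matrix(tree, ids)
        sym = rng.normal(0, 0.01, pm.shape)
        noisy = np.abs(pm + np.triu(sym, 1) + np.triu(sym, 1).T)
        np.fill_diagonal(noisy, 0.0)
        ours = neighbor_joining(DistanceMatrix(ids, noisy))
        theirs = skbio_nj(SkbioDM(noisy, ids))
        theirs_dp = dendropy.Tree.get(
            data=str(theirs), schema="newick", preserve_underscores=True,
            taxon_namespace=ours.taxon_namespace,
        )
        for t in (ours, theirs_dp):  # compare unrooted shapes
            t.is_rooted = False
            t.update_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(ours, theirs_dp)
        assert rf == 0

    def test_infinite_distance_names_the_pair(self):
        vals = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        dm = DistanceMatrix(["a", "b", "c"], vals)
        with pytest.raises(ValueError, match="'a' and 'c'"):
            neighbor_joining(dm)

    def test_outgroup_rooting_places_outgroup_basal(self):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,OUT:0.8):0.07);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        ids = ["A", "B", "C", "OUT"]
        pm = patristic_matrix(tree, ids)
        nj = neighbor_joining(DistanceMatrix(ids, pm), outgroup="OUT")
        root_children = nj.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in ch.leaf_iter()} for ch in root_children
        ]
        assert {"OUT"} in sides


class TestNPRS:
    def test_clock_like_tree_is_fixed_point(self):
        nwk = "((A:0.1,B:0.1):0.2,(C:0.15,D:0.15):0.15);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        out = nprs_smooth(tree, root_age=1.0)
        assert is_ultrametric(out, tol=1e-9)
        assert out.nprs_objective == pytest.approx(0.0, abs=1e-12)
        # ages proportional to path lengths: A-B split at 0.1/0.3 of root age
        from intetax.trees import node_ages

        ages = node_ages(out)
        internal = sorted(
            ages[id(nd)] for nd in out.preorder_node_iter() if not nd.is_leaf()
        )
        assert internal[0] == pytest.approx(0.1 / 0.3, rel=1e-6)
        assert internal[1] == pytest.approx(0.15 / 0.3, rel=1e-6)

    def test_two_tip_tree_solved_by_hand(self):
        tree = dendropy.Tree.get(data="(A:0.2,B:0.6);", schema="newick")
        out = nprs_smooth(tree, root_age=1.0)
        assert is_ultrametric(out, tol=1e-9)
        # both tips at 0, root at 1: rates are the branch lengths; the root
        # objective is the summed squared deviation from the mean rate
        assert out.nprs_objective == pytest.approx((0.2 - 0.4) ** 2 + (0.6 - 0.4) ** 2)

    def test_output_is_ultrametric_on_noisy_nj_tree(self, default_dataset, rng):
        from intetax import distance_matrix

        *_, aln = default_dataset
        sub, _ = collapse_haplotypes(aln)
        nj = neighbor_joining(distance_matrix(sub))
        assert not is_ultrametric(nj, tol=1e-6)
        out = nprs_smooth(nj)
        assert is_ultrametric(out, tol=1e-6)

    def test_objective_not_worse_than_initialization(self, rng):
        for _ in range(5):
            tree, ids = random_ultrametric_like_tree(rng, 8)
            smoothed = nprs_smooth(tree)
            assert smoothed.nprs_objective <= smoothed.nprs_objective_init + 1e-12
            # feasibility: parent older than child everywhere
            from intetax.trees import node_ages

            ages = node_ages(smoothed)
            for nd in smoothed.preorder_node_iter():
                for ch in nd.child_nodes():
                    assert ages[id(nd)] >= ages[id(ch)] - 1e-9

    def test_invariant_to_uniform_branch_scaling(self, rng):
        tree, ids = random_ultrametric_like_tree(rng, 7)
        scaled = tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * 3.7
        a1 = patristic_matrix(nprs_smooth(tree), ids)
        a2 = patristic_matrix(nprs_smooth(scaled), ids)
        assert np.allclose(a1, a2, atol=1e-5)

    def test_unrooted_input_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        with pytest.raises(ValueError):
            nprs_smooth(tree)


class TestUltrametricCheck:
    def test_tolerance_infinite_accepts_anything(self):
        tree = dendropy.Tree.get(data="((A:1,B:9):1,C:0.1);", schema="newick")
        assert is_ultrametric(tree, tol=np.inf)
        assert not is_ultrametric(tree, tol=1e-6)


class TestHaplotypeCollapse:
    def test_identical_sequences_collapse_to_representative(self):
        aln = LabeledAlignment(
            ["a", "b", "c"], ["g", "g", "h"], ["ACGT", "ACGT", "AGGT"]
        )
        sub, members = collapse_haplotypes(aln)
        assert sub.ids == ["a", "c"]
        assert members["a"] == ["a", "b"]
        assert members["c"] == ["c"]
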