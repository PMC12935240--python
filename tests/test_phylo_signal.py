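"""Blomberg's K, Grafen branch lengths, covariance matrix, permutations."""

import dendropy
import numpy as np
import pytest

from conftest import random_topology_newick
from phenoshift.phylo_signal import (
    blomberg_k,
    grafen_branch_lengths,
    load_tree,
    permutation_test,
    phylo_vcv,
    prune_to,
    repair_near_zero,
)

# Independent reference: picante::Kcalc in R on the same tree and trait
R_K_4TIP = 1.661965003964
# ape::compute.brlen(method="Grafen", power=1) on ((((A,B),C),D),E);
R_GRAFEN_5TIP = "((((A:0.25,B:0.25):0.25,C:0.5):0.25,D:0.75):0.25,E:1);"


def get_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def edge_lengths(tree):
    return {
        tuple(sorted(l.taxon.label for l in e.head_node.leaf_iter())): round(e.length, 10)
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None
    }


class TestGrafen:
    def test_two_tip_tree(self):
        g = grafen_branch_lengths(get_tree("(A,B);"))
        assert [e.length for e in g.preorder_edge_iter() if e.tail_node is not None] == [1.0, 1.0]

    def test_balanced_four_tips(self):
        g = grafen_branch_lengths(get_tree("((A,B),(C,D));"))
        lengths = sorted(
            e.length for e in g.preorder_edge_iter() if e.tail_node is not None
        )
        assert lengths == pytest.approx([1 / 3] * 4 + [2 / 3] * 2)

    def test_caterpillar_three_tips(self):
        g = grafen_branch_lengths(get_tree("((A,B),C);"))
        got = edge_lengths(g)
        assert got[("A", "B")] == pytest.approx(0.5)
        assert got[("A",)] == pytest.approx(0.5)
        assert got[("C",)] == pytest.approx(1.0)

    def test_matches_ape_reference(self):
        g = grafen_branch_lengths(get_tree("((((A,B),C),D),E);"))
        ref = get_tree(R_GRAFEN_5TIP)
        assert edge_lengths(g) == edge_lengths(ref)


class TestRepairNearZero:
    def test_raises_short_branches_only(self):
        t = get_tree("((A:0.0,B:0.5):0.3,C:0.8);")
        fixed = repair_near_zero(t, epsilon=1e-6)
        got = edge_lengths(fixed)
        assert got[("A",)] == 1e-6
        assert got[("B",)] == 0.5

    def test_identity_when_all_long(self):
        t = get_tree("((A:0.2,B:0.5):0.3,C:0.8);")
        assert edge_lengths(repair_near_zero(t, 1e-6)) == edge_lengths(t)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            repair_near_zero(get_tree("(A:1,B:1);"), epsilon=0.0)

    def test_height_perturbation_bounded(self):
        t = get_tree("((A:0.0,B:0.0):0.0,(C:0.4,D:0.4):0.6);")
        eps = 1e-3
        fixed = repair_near_zero(t, epsilon=eps)
        _, v0 = phylo_vcv(t)
        _, v1 = phylo_vcv(fixed)
        assert np.abs(np.diag(v1) - np.diag(v0)).max() <= 2 * eps + 1e-12


class TestPhyloVCV:
    def test_star_tree_identity(self):
        newick = "(" + ",".join(f"t{i}:1.0" for i in range(6)) + ");"
        _, v = phylo_vcv(get_tree(newick))
        assert np.allclose(v, np.eye(6))

    def test_sisters_share_stem(self):
        labels, v = phylo_vcv(get_tree("((A:0.1,B:0.1):0.9,C:1.0);"))
        i, j = labels.index("A"), labels.index("B")
        assert v[i, j] == pytest.approx(0.9)
        assert v[i, i] == pytest.approx(1.0)

    def test_matches_pairwise_mrca_brute_force(self):
        tree = get_tree(random_topology_newick(8, seed=99))
        tree = grafen_branch_lengths(tree)
        labels, v = phylo_vcv(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        depth = {l: v[i, i] for i, l in enumerate(labels)}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    continue
                d = pdm.patristic_distance(taxa[a], taxa[b])
                shared = (depth[a] + depth[b] - d) / 2.0
                assert v[i, j] == pytest.approx(shared, abs=1e-12)


class TestBlombergK:
    def test_star_tree_k_exactly_one(self):
        newick = "(" + ",".join(f"t{i}:1.0" for i in range(12)) + ");"
        tree = get_tree(newick)
        rng = np.random.default_rng(0)
        for _ in range(5):
            trait = {f"t{i}": float(v) for i, v in enumerate(rng.normal(size=12))}
            assert blomberg_k(tree, trait) == pytest.approx(1.0, abs=1e-9)

    def test_matches_picante_reference(self):
        tree = get_tree("((A:0.6,B:0.6):0.4,(C:0.3,D:0.3):0.7);")
        trait = {"A": 1.2, "B": 0.9, "C": -0.4, "D": -0.1}
        assert blomberg_k(tree, trait) == pytest.approx(R_K_4TIP, abs=1e-9)

    def test_affine_invariance(self, tree33):
        rng = np.random.default_rng(1)
        labels = [t.label for t in tree33.taxon_namespace]
        x = rng.normal(size=len(labels))
        k1 = blomberg_k(tree33, dict(zip(labels, x)))
        k2 = blomberg_k(tree33, dict(zip(labels, 3.7 * x - 11.0)))
        assert k1 == pytest.approx(k2, abs=1e-9)

    def test_branch_rescale_invariance(self, tree33):
        rng = np.random.default_rng(2)
        labels = [t.label for t in tree33.taxon_namespace]
        trait = dict(zip(labels, rng.normal(size=len(labels))))
        scaled = tree33.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.tail_node is not None:
                e.length *= 13.0
        assert blomberg_k(tree33, trait) == pytest.approx(blomberg_k(scaled, trait), abs=1e-9)

    def test_bm_traits_give_k_near_one(self, tree33):
        from phenoshift.synthetic_data import simulate_bm_trait

        ks = [blomberg_k(tree33, simulate_bm_trait(tree33, 1.0, seed=s)) for s in range(100)]
        assert 0.8 < np.mean(ks) < 1.2

    def test_missing_tip_trait_rejected(self, tree33):
        with pytest.raises(ValueError, match="missing"):
            blomberg_k(tree33, {"t01": 1.0})


class TestPermutationTest:
    def test_constant_trait_p_one(self, tree33):
        labels = [t.label for t in tree33.taxon_namespace]
        res = permutation_test(tree33, {l: 2.0 for l in labels}, 99, seed=0)
        assert res.p_value == 1.0

    def test_clade_structured_trait_significant(self):
        tree = grafen_branch_lengths(get_tree(random_topology_newick(16, seed=5)))
        labels, v = phylo_vcv(tree)
        # trait = indicator of the clade containing the first tip's
        # closest relatives: maximal phylogenetic structure
        anchor = 0
        trait = {l: float(v[anchor, i] > 0.4) for i, l in enumerate(labels)}
        if len(set(trait.values())) == 1:  # degenerate split, widen
            trait = {l: float(v[anchor, i] > 0.2) for i, l in enumerate(labels)}
        res = permutation_test(tree, trait, 1000, seed=1)
        assert res.p_value <= 0.01

    def test_seed_determinism(self, tree33):
        rng = np.random.default_rng(7)
        labels = [t.label for t in tree33.taxon_namespace]
        trait = dict(zip(labels, rng.normal(size=len(labels))))
        a = permutation_test(tree33, trait, 200, seed=3)
        b = permutation_test(tree33, trait, 200, seed=3)
        assert a == b

    def test_p_floor(self, tree33):
        rng = np.random.default_rng(8)
        labels = [t.label for t in tree33.taxon_namespace]
        trait = dict(zip(labels, rng.normal(size=len(labels))))
        res = permutation_test(tree33, trait, 50, seed=4)
        assert res.p_value >= 1 / 51


class TestPruning:
    def test_prune_then_compute_equals_prepruned(self, tree33):
        labels = sorted(t.label for t in tree33.taxon_namespace)[:10]
        rng = np.random.default_rng(9)
        trait = dict(zip(labels, rng.normal(size=10)))
        pruned = prune_to(tree33, labels)
        k_pruned = blomberg_k(pruned, trait)
        rebuilt = dendropy.Tree.get(
            data=pruned.as_string(schema="newick"), schema="newick"
        )
        assert blomberg_k(rebuilt, trait) == pytest.approx(k_pruned, abs=1e-9)

    def test_prune_missing_label_rejected(self, tree33):
        with pytest.raises(ValueError, match="absent"):
            prune_to(tree33, ["t01", "zz"])
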