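"""Phylogenetic signal in shift magnitudes: Blomberg's K with a
permutation test.

Blomberg's K compares the variance structure of a tip trait with the
expectation under Brownian motion on the tree:

    K = (MSE0 / MSE) / E[MSE0 / MSE]

where a_hat = (1' V^-1 x) / (1' V^-1 1) is the GLS estimate of the root
state, MSE0 = (x - a_hat)'(x - a_hat) / (n - 1) is the ordinary trait
variance about it, MSE = (x - a_hat)' V^-1 (x - a_hat) / (n - 1) the
phylogenetically corrected one, and the Brownian expectation of their
ratio is (tr V - n / (1' V^-1 1)) / (n - 1).  V is the phylogenetic
covariance matrix of shared root-to-MRCA path lengths.  K = 1 matches
Brownian motion; K < 1 means relatives resemble each other less than
Brownian motion predicts.  Significance comes from shuffling trait
values across tips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloSignalResult",
    "load_tree",
    "prune_to",
    "grafen_branch_lengths",
    "repair_near_zero",
    "phylo_vcv",
    "blomberg_k",
    "permutation_test",
]


@dataclass(frozen=True)
class PhyloSignalResult:
    K: float
    p_value: float
    n_permutations: int
    seed: int
    n_tips: int


def load_tree(path) -> dendropy.Tree:
    """Read a Newick tree; unrooted trees with branch lengths are
    midpoint-rooted so node heights are defined."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    has_lengths = all(
        e.length is not None for e in tree.preorder_edge_iter() if e.tail_node is not None
    )
    if not tree.is_rooted and has_lengths:
        n_leaves = len(tree.leaf_nodes())
        candidate = tree.clone(depth=1)
        candidate.reroot_at_midpoint(update_bipartitions=False)
        # guard: when the midpoint falls exactly on a leaf's attachment
        # dendropy can demote that leaf to the root node
        if len(candidate.leaf_nodes()) == n_leaves:
            logger.info("unrooted input tree: midpoint rooting")
            tree = candidate
        else:
            logger.info("unrooted input tree: keeping as-parsed rooting")
        tree.is_rooted = True
    return tree


def prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Clone the tree pruned to the given tip labels."""
    pruned = tree.clone(depth=1)
    keep = set(labels)
    tips = {t.label for t in pruned.taxon_namespace}
    missing = keep - tips
    if missing:
        raise ValueError(f"labels absent from tree: {sorted(missing)}")
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


def grafen_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign branch lengths from clade-size node heights.

    Node height = (number of descendant tips - 1) / (n - 1), so the root
    sits at height 1 and every tip at 0; each branch length is the
    height difference between parent and child.  All lengths are
    positive for strictly nested clades.
    """
    out = tree.clone(depth=1)
    tips = out.leaf_nodes()
    n = len(tips)
    if n < 2:
        raise ValueError("need at least 2 tips")
    heights: dict[int, float] = {}
    for node in out.postorder_node_iter():
        k = sum(1 for _ in node.leaf_iter())
        heights[id(node)] = (k - 1) / (n - 1)
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        node.edge.length = heights[id(node.parent_node)] - heights[id(node)]
    return out


def repair_near_zero(tree: dendropy.Tree, epsilon: float | None = None) -> dendropy.Tree:
    """Raise near-zero branch lengths to a small constant.

    Default epsilon is 1e-6 times the maximum root-to-tip height, so the
    repair is negligible relative to tree depth while making the
    covariance matrix invertible.
    """
    out = tree.clone(depth=1)
    if epsilon is None:
        depth = _tip_depths(out)
        epsilon = 1e-6 * max(depth.values(), default=1.0)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    n_fixed = 0
    for edge in out.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None or edge.length < epsilon:
            edge.length = epsilon
            n_fixed += 1
    if n_fixed:
        logger.info("repaired %d near-zero branches to %.3g", n_fixed, epsilon)
    return out


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depths[id(parent)] + (node.edge.length or 0.0)
        depths[id(node)] = d
        if node.is_leaf():
            out[node.taxon.label] = d
    return out


def phylo_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance matrix under Brownian motion.

    V[i, j] is the root-to-MRCA shared path length of tips i and j; the
    diagonal holds root-to-tip distances.  Returns (tip labels, V) with
    labels in the tree's leaf order.
    """
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    depths: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[id(node)] = (
            0.0 if parent is None else depths[id(parent)] + (node.edge.length or 0.0)
        )
    vcv = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            vcv[i, i] = depths[id(node)]
        else:
            h = depths[id(node)]  # MRCA depth for tips in different children
            groups = [below.pop(id(c)) for c in node.child_nodes()]
            for gi, g in enumerate(groups):
                for other in groups[gi + 1:]:
                    for i in g:
                        for j in other:
                            vcv[i, j] = vcv[j, i] = h
            below[id(node)] = [i for g in groups for i in g]
    return labels, vcv


def blomberg_k(tree: dendropy.Tree, trait: dict[str, float]) -> float:
    """Blomberg's K for a tip trait on a (pruned, repaired) tree."""
    labels, vcv = phylo_vcv(tree)
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    x = np.array([trait[l] for l in labels])
    return _k_statistic(vcv, x)


def _k_pieces(vcv: np.ndarray):
    """Precompute the V-dependent pieces of K (reused across permutations)."""
    n = vcv.shape[0]
    try:
        vinv = np.linalg.inv(vcv)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular phylogenetic covariance matrix; repair near-zero "
            "branches first (repair_near_zero)"
        ) from err
    one = np.ones(n)
    vinv_one = vinv @ one
    denom = one @ vinv_one
    expected = (np.trace(vcv) - n / denom) / (n - 1)
    return vinv, vinv_one, denom, expected


def _k_statistic(vcv: np.ndarray, x: np.ndarray, pieces=None) -> float:
    vinv, vinv_one, denom, expected = pieces or _k_pieces(vcv)
    a_hat = (vinv_one @ x) / denom
    resid = x - a_hat
    mse0 = resid @ resid
    mse = resid @ vinv @ resid
    if mse <= 0:
        raise ValueError("non-positive phylogenetic mean square; check V")
    return float((mse0 / mse) / expected)


def permutation_test(
    tree: dendropy.Tree,
    trait: dict[str, float],
    n_permutations: int = 1000,
    seed: int = 0,
) -> PhyloSignalResult:
    """One-sided permutation test of K (high K = signal).

    Trait values are shuffled uniformly across tips;
    p = (1 + #{K_perm >= K_obs}) / (1 + n_permutations), so the smallest
    attainable p is 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels, vcv = phylo_vcv(tree)
    x = np.array([trait[l] for l in labels])
    if np.allclose(x, x[0]):
        logger.warning("constant trait: every permutation is identical, p = 1")
        return PhyloSignalResult(
            K=float("nan"), p_value=1.0, n_permutations=n_permutations,
            seed=seed, n_tips=len(labels),
        )
    pieces = _k_pieces(vcv)
    k_obs = _k_statistic(vcv, x, pieces)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        k_perm = _k_statistic(vcv, rng.permutation(x), pieces)
        if k_perm >= k_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PhyloSignalResult(
        K=k_obs, p_value=p, n_permutations=n_permutations, seed=seed, n_tips=len(labels)
    )
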