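"""Phylogenetic covariance and consensus-tree utilities (dendropy-backed)."""

from __future__ import annotations

import numpy as np
import dendropy

from .errors import AltishiftError


def phylo_covariance(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix: C[i, j] = depth of MRCA(i, j) from the root.

    The diagonal holds tip depths (constant for an ultrametric tree). Computed
    from root distances and patristic distances: depth(MRCA) = (r_i + r_j - d_ij) / 2.
    """
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise AltishiftError(f"negative branch length {e.length} in tree")
    labels = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in labels]
    if missing:
        raise AltishiftError(f"species missing from tree: {missing}")
    tree.calc_node_root_distances()
    root_dist = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in root_dist]
    if missing:
        raise AltishiftError(f"species are not tips of the tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    n = len(species)
    C = np.zeros((n, n))
    for i, si in enumerate(species):
        C[i, i] = root_dist[si]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(labels[si], labels[species[j]])
            C[i, j] = C[j, i] = 0.5 * (root_dist[si] + root_dist[species[j]] - d)
    return C


def simulate_brownian(tree: dendropy.Tree, species: list[str], rate: float,
                      rng: np.random.Generator, mean: float = 0.0) -> np.ndarray:
    """One Brownian trait realisation on the tree (multivariate normal with covariance rate*C)."""
    C = phylo_covariance(tree, species)
    L = np.linalg.cholesky(rate * C + 1e-12 * np.eye(len(species)))
    return mean + L @ rng.standard_normal(len(species))


def grafen_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign branch lengths by Grafen's rule: node height proportional to clade size.

    Each internal node gets height ((n_descendant_tips - 1) / (n_total - 1)) ** rho,
    tips get height 0, and edge lengths are parent height minus child height.
    The resulting tree is ultrametric with height 1.
    """
    n_total = len(tree.leaf_nodes())
    if n_total < 2:
        raise AltishiftError("Grafen lengths need at least two tips")
    heights = {}
    for node in tree.postorder_node_iter():
        n_desc = len(node.leaf_nodes())
        heights[node] = 0.0 if node.is_leaf() else ((n_desc - 1) / (n_total - 1)) ** rho
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
    return tree


def consensus_with_lengths(trees: list[dendropy.Tree], min_freq: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus topology with Grafen branch lengths.

    Consensus topologies carry no meaningful branch lengths, so lengths are
    re-assigned by Grafen's method — a deliberate methodological choice that
    yields an ultrametric, positive-definite covariance structure.
    """
    if not trees:
        raise AltishiftError("no trees given")
    tns = trees[0].taxon_namespace
    ref = frozenset(lf.taxon.label for lf in trees[0].leaf_node_iter())
    for tr in trees:
        tips = frozenset(lf.taxon.label for lf in tr.leaf_node_iter())
        if tips != ref:
            raise AltishiftError("trees have conflicting tip sets")
    tl = dendropy.TreeList(trees, taxon_namespace=tns)
    cons = tl.consensus(min_freq=min_freq)
    cons.is_rooted = True
    return grafen_lengths(cons)
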