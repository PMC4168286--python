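"""Neighbour-joining and UPGMA tree construction from a distance matrix.

Both builders are deterministic: ties in the merge criterion are broken by
the lexicographically smallest pair of cluster labels, where a cluster is
labelled by its smallest member accession id. Negative NJ branch-length
estimates are clamped to zero (the clamped total is recorded on the tree as
``negative_branch_clamp_total`` and logged). Matrices containing undefined
(saturated) pairs are refused rather than imputed.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distance import DistanceMatrix, UndefinedDistanceError
from .io import BarcodevalError

logger = logging.getLogger(__name__)


def _check_defined(dm: DistanceMatrix) -> None:
    if not dm.fully_defined:
        pairs = dm.undefined_pairs()
        raise UndefinedDistanceError(
            f"{len(pairs)} undefined distance pair(s), e.g. {pairs[:3]}; "
            "cannot build a tree from a saturated matrix"
        )


def _pick_pair(crit: np.ndarray, labels: list[str]) -> tuple[int, int]:
    """Index pair minimizing ``crit`` (i<j); ties -> smallest label pair."""
    m = crit.shape[0]
    iu = np.triu_indices(m, k=1)
    vals = crit[iu]
    best = vals.min()
    cand = [
        (i, j)
        for i, j, v in zip(iu[0], iu[1], vals)
        if v == best
    ]
    key = lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]])))
    i, j = min(cand, key=key)
    return int(i), int(j)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining; returns an unrooted dendropy tree.

    Uses the Q-criterion ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` and the
    standard limb-length assignment. Consistent on additive matrices.
    """
    _check_defined(dm)
    n = len(dm.taxa)
    if n < 3:
        raise BarcodevalError(f"neighbor_joining: need >=3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.taxa
    ]
    labels = list(dm.taxa)  # cluster label = smallest member accession id
    D = dm.d.copy().astype(float)
    clamped_total = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped_total
        if x < 0.0:
            clamped_total += -x
            return 0.0
        return x

    while len(labels) > 3:
        m = len(labels)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _pick_pair(Q, labels)
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(vi)
        nodes[j].edge.length = clamp(vj)
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = new_row[keep]
        D_new[:-1, -1] = new_row[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final three clusters joined at an internal node with analytic limbs
    (a, b, c) = (0, 1, 2)
    center = dendropy.Node()
    limbs = (
        0.5 * (D[a, b] + D[a, c] - D[b, c]),
        0.5 * (D[a, b] + D[b, c] - D[a, c]),
        0.5 * (D[a, c] + D[b, c] - D[a, b]),
    )
    for k, limb in zip((a, b, c), limbs):
        center.add_child(nodes[k])
        nodes[k].edge.length = clamp(limb)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    tree.negative_branch_clamp_total = clamped_total
    if clamped_total > 0:
        logger.info(
            "neighbor_joining: clamped %.6g of negative branch length to 0",
            clamped_total,
        )
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA: rooted ultrametric tree from average-linkage agglomeration."""
    _check_defined(dm)
    n = len(dm.taxa)
    if n < 2:
        raise BarcodevalError(f"upgma: need >=2 taxa, got {n}")
    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.taxa]
    labels = list(dm.taxa)
    heights = [0.0] * n
    sizes = [1] * n
    D = dm.d.copy().astype(float)

    while len(labels) > 1:
        m = len(labels)
        crit = D.copy()
        np.fill_diagonal(crit, np.inf)
        i, j = _pick_pair(crit, labels)
        h = 0.5 * D[i, j]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, h - heights[i])
        nodes[j].edge.length = max(0.0, h - heights[j])
        new_row = (sizes[i] * D[i, :] + sizes[j] * D[j, :]) / (sizes[i] + sizes[j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = new_row[keep]
        D_new[:-1, -1] = new_row[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]
        heights = [heights[k] for k in keep] + [h]
        sizes_new = sizes[i] + sizes[j]
        sizes = [sizes[k] for k in keep] + [sizes_new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def collapse_zero_branches(tree: dendropy.Tree, tol: float = 1e-9) -> dendropy.Tree:
    """Contract internal edges with length <= tol into polytomies.

    Leaf edges are never touched. Returns a new tree; the input is unchanged.
    """
    if tol < 0:
        raise BarcodevalError("collapse_zero_branches: tol must be >= 0")
    out = tree.clone(depth=1)
    to_collapse = [
        nd.edge
        for nd in out.preorder_node_iter()
        if nd.parent_node is not None
        and not nd.is_leaf()
        and (nd.edge.length or 0.0) <= tol
    ]
    for edge in to_collapse:
        edge.collapse()
    out.is_rooted = tree.is_rooted
    return out


def tree_path_distances(tree: dendropy.Tree) -> tuple[tuple[str, ...], np.ndarray]:
    """Leaf-to-leaf path-length matrix (taxa sorted), for consistency checks."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    n = len(taxa)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.distance(taxa[i], taxa[j])
    return tuple(t.label for t in taxa), M
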