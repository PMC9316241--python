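"""Neighbour-joining tree construction and monophyly queries.

Trees are scikit-bio ``TreeNode`` objects with an unrooted (trifurcating-root)
topology, so newick round-trips and bipartition queries come for free. The
agglomeration itself is implemented here: Q-criterion pair selection, the
two-taxon branch-length split, and matrix reduction. Negative branch lengths —
a routine by-product of noisy distances — are clamped to zero and the deficit
logged.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import TreeNode

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a finite distance matrix.

    Ties in the Q-criterion break on the lowest (i, j) index pair, which makes
    the topology deterministic for a given input ordering.
    """
    if len(dm) < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {len(dm)}")
    if dm.saturated_pairs:
        raise ValueError(
            f"non-finite (saturated) distances for pairs: {dm.saturated_pairs}"
        )

    d = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]

    def clamp(length: float, where: str) -> float:
        if length < 0:
            logger.warning(
                "clamped negative NJ branch length %.6g to 0 at %s", length, where
            )
            return 0.0
        return length

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li, f"join({a.name or 'internal'})")
        b.length = clamp(lj, f"join({b.name or 'internal'})")
        parent.extend([a, b])
        # distances from the new node to everything else
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dn[keep]])
        d = np.hstack([d, np.append(dn[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-taxon star: closed-form branch lengths
    (da_bc, da_c, db_c) = (d[0, 1], d[0, 2], d[1, 2])
    root = TreeNode()
    lengths = (
        0.5 * (da_bc + da_c - db_c),
        0.5 * (da_bc + db_c - da_c),
        0.5 * (da_c + db_c - da_bc),
    )
    for node, length in zip(nodes, lengths):
        node.length = clamp(length, f"root({node.name or 'internal'})")
        root.append(node)
    return root


def species_monophyly(
    tree: TreeNode, labels: dict[str, str]
) -> dict[str, bool]:
    """Is each species' leaf set a single clade of the unrooted tree?

    A species is monophyletic iff removing one edge separates exactly its
    leaves from the rest — i.e. its leaf set, or the complement, appears as a
    subtree of the (arbitrarily rooted) tree.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")
    all_leaves = frozenset(leaves)
    subtree_sets = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
    subtree_sets |= {frozenset([l]) for l in leaves}
    result = {}
    for species in sorted(set(labels[l] for l in leaves)):
        s = frozenset(l for l in leaves if labels[l] == species)
        result[species] = s in subtree_sets or (all_leaves - s) in subtree_sets
    return result


def write_newick(tree: TreeNode, path) -> None:
    """Write the tree as newick with 6-decimal branch lengths."""
    for node in tree.traverse():
        if node.length is not None:
            node.length = round(node.length, 6)
    tree.write(str(path), format="newick")
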