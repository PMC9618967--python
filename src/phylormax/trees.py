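"""Phylogenetic covariance from rooted trees, and Pagel's lambda transform.

Under Brownian-motion trait evolution on a rooted tree, the covariance of
trait values between two tips equals the length of the evolutionary history
they share: C[i, j] is the root-to-MRCA path length of tips i and j, and the
diagonal holds each tip's root-to-tip depth. Pagel's lambda rescales the
off-diagonal entries, interpolating between independent residuals (lambda=0,
ordinary least squares) and pure Brownian motion (lambda=1).
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "read_newick",
    "read_newick_trees",
    "write_newick",
    "tip_labels",
    "phylo_covariance",
    "lambda_transform",
]


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree, preserving underscores in labels."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def read_newick_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (one tree per line)."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for t in trees:
        t.is_rooted = True
    return list(trees)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_covariance(
    tree: dendropy.Tree, tip_order: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of a rooted tree.

    Parameters
    ----------
    tree
        Rooted tree with branch lengths (missing lengths count as 0).
    tip_order
        Species order for the matrix rows/columns; defaults to the tree's
        leaf-iteration order. Every name must be a tip of the tree.

    Returns
    -------
    (C, order)
        ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j;
        the diagonal is each tip's root-to-tip depth. Symmetric PSD.

    Notes
    -----
    Computed by a single postorder pass: each internal node's depth from the
    root is credited to every tip pair whose MRCA it is.
    """
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        raise ValueError("tree tip labels are not unique")
    if tip_order is None:
        tip_order = labels
    missing = set(tip_order) - set(labels)
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    index = {name: i for i, name in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))

    # node depths from root
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        depth[id(node)] = depth[id(node.parent_node)] + edge

    # postorder: tips under each child subtree meet at this node
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            tips_below[id(node)] = (
                [index[lbl]] if lbl in index else []
            )
            if lbl in index:
                C[index[lbl], index[lbl]] = depth[id(node)]
            continue
        children = [tips_below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = d
                        C[j, i] = d
        tips_below[id(node)] = [i for ch in children for i in ch]
    return C, list(tip_order)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal elements of ``C`` by ``lam`` (Pagel's lambda).

    lambda=1 leaves the Brownian covariance unchanged; lambda=0 yields a
    diagonal matrix, i.e. ordinary least squares residuals.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be a square matrix")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out
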