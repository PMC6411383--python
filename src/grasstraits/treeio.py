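"""Phylogenetic trees and the Brownian-motion covariance structure.

A rooted tree with branch lengths induces the expected covariance of a
continuously evolving character among its tips: under Brownian motion,
``C[i, j]`` is the length of the root-to-MRCA path shared by tips *i* and
*j*, and ``C[i, i]`` is the root-to-tip depth of tip *i*.  Pagel's lambda
rescales the off-diagonal (shared-history) part of ``C`` and is the single
knob the regression layer profiles by maximum likelihood.

Newick parsing and writing are delegated to :mod:`dendropy`; this module
adds validation, pruning that preserves root-to-tip depths, and the
covariance construction itself.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "PhyloCovariance",
    "TreeParseError",
    "parse_newick",
    "write_newick",
    "prune_to",
    "phylo_covariance",
    "lambda_transform",
    "stabilized_inverse_factor",
]


class TreeParseError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Tree:
    """A rooted phylogeny with branch lengths, wrapping a dendropy tree.

    Tip labels are unique; branch lengths are nonnegative and live on every
    non-root edge.  Multifurcations are permitted.
    """

    _dtree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out = {}
        for leaf in self._dtree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def is_ultrametric(self, rel_tol: float = 1e-4) -> bool:
        d = np.array(list(self.depths().values()))
        if d.max() <= 0:
            return True
        return (d.max() - d.min()) / d.max() < rel_tol


@dataclass
class PhyloCovariance:
    """Tip covariance matrix C with bookkeeping of the applied lambda.

    ``lambda_applied`` is the string ``"raw"`` until :func:`lambda_transform`
    stamps a numeric value; the regression layer refuses to re-transform an
    already transformed matrix.
    """

    taxa: list[str]
    C: np.ndarray
    lambda_applied: float | str = "raw"

    def subset(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.C[np.ix_(idx, idx)], self.lambda_applied)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a validated :class:`Tree`.

    Raises :class:`TreeParseError` for unbalanced parentheses, duplicate tip
    labels, or a missing branch length on any non-root edge.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises a zoo of error classes
        raise TreeParseError(f"malformed Newick: {exc}") from exc

    labels = [leaf.taxon.label if leaf.taxon else None for leaf in dtree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise TreeParseError("tip without a label")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise TreeParseError(f"duplicate tip labels: {sorted(dupes)}")

    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise TreeParseError(f"missing branch length on edge above {where}")
        if node.edge.length < 0:
            raise TreeParseError(f"negative branch length {node.edge.length}")

    tree = Tree(dtree)
    if tree.n_tips >= 2 and not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric; covariance built from raw path lengths")
    return tree


def write_newick(tree: Tree) -> str:
    """Serialize to Newick with 6 significant digits on branch lengths."""
    s = tree._dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )
    return s.strip()


def prune_to(tree: Tree, taxa) -> Tree:
    """Restrict the tree to ``taxa``, collapsing unary nodes.

    Root-to-tip depths of retained tips are preserved exactly (collapsed
    edges have their lengths summed).
    """
    taxa = set(taxa)
    missing = sorted(taxa - set(tree.tip_labels))
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")
    dtree = tree._dtree.clone(depth=1)
    # drop unwanted leaves, then collapse unary non-root nodes by summing
    # edge lengths; the root is kept even if unary so depths are preserved
    changed = True
    while changed:
        changed = False
        for leaf in list(dtree.leaf_node_iter()):
            if leaf.taxon is None or leaf.taxon.label not in taxa:
                leaf.parent_node.remove_child(leaf)
                changed = True
    for node in list(dtree.preorder_node_iter()):
        parent = node.parent_node
        if parent is not None and len(node.child_nodes()) == 1:
            (child,) = node.child_nodes()
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent.remove_child(node)
            parent.add_child(child)
    return Tree(dtree)


def phylo_covariance(tree: Tree, taxa_order: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance matrix of the tips.

    ``C[i, j]`` is the depth of the MRCA of tips *i* and *j*; the diagonal
    holds root-to-tip depths.  Row/column order follows ``taxa_order`` when
    given (normally the trait-table row order) so data vectors align with
    the matrix by construction.
    """
    labels = tree.tip_labels
    if taxa_order is None:
        taxa_order = labels
    else:
        missing = sorted(set(taxa_order) - set(labels))
        if missing:
            raise KeyError(f"taxa absent from tree: {missing}")
    pos = {lab: i for i, lab in enumerate(taxa_order)}
    n = len(taxa_order)
    C = np.zeros((n, n))

    # node depth by preorder accumulation; each internal node contributes its
    # depth to all tip pairs that split at it
    depth = {}
    for node in tree._dtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[parent] + (node.edge.length or 0.0)

    for node in tree._dtree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = (
                [pos[node.taxon.label]] if node.taxon.label in pos else []
            )
            if node._tipset:
                i = node._tipset[0]
                C[i, i] = depth[node]
            continue
        children_sets = [ch._tipset for ch in node.child_nodes()]
        for a in range(len(children_sets)):
            for b in range(a + 1, len(children_sets)):
                for i in children_sets[a]:
                    for j in children_sets[b]:
                        C[i, j] = C[j, i] = depth[node]
        node._tipset = [i for s in children_sets for i in s]

    return PhyloCovariance(list(taxa_order), C, "raw")


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariances by Pagel's lambda in [0, 1]."""
    if cov.lambda_applied != "raw":
        raise ValueError("lambda already applied to this covariance")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = cov.C * lam
    np.fill_diagonal(V, np.diag(cov.C))
    return PhyloCovariance(list(cov.taxa), V, lam)


def stabilized_inverse_factor(V: np.ndarray) -> np.ndarray:
    """Cholesky factor of V, with a tiny diagonal jitter if near-singular.

    Supertree extracts often carry zero-length terminal edges which can make
    V numerically singular; when the condition number exceeds 1e12 a jitter
    of 1e-10 x mean depth is added to the diagonal (and noted via a warning)
    before factorization.
    """
    V = np.asarray(V, float)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        warnings.warn(f"covariance near-singular (cond={cond:.3g}); adding jitter {jitter:.3g}")
        V = V + jitter * np.eye(V.shape[0])
    return np.linalg.cholesky(V)
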