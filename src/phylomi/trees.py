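"""Phylogeny input, validation and the Brownian-motion covariance matrix.

The phylogeny is the backbone of every downstream stage: under Brownian
motion, the covariance between two species' trait values is proportional to
the branch length shared on their root-to-tip paths.  This module reads and
validates Newick trees, repairs zero-length branches (used by time trees to
encode polytomies), enforces ultrametricity, and builds the phylogenetic
variance-covariance matrix C with C[i, j] = depth of the most recent common
ancestor of tips i and j.

Tip order is lexicographic by label everywhere, so matrices and vectors are
reproducible across runs and trivially alignable with trait tables.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "resolve_zero_branches",
    "phylo_vcv",
    "is_ultrametric",
    "NewickParseError",
    "TreeValidationError",
]


class NewickParseError(ValueError):
    """Raised when a Newick string/file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural requirement."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, tips ordered by label.

    Thin wrapper around a :class:`dendropy.Tree`.  All phylomi functions
    treat the wrapped tree as immutable; operations that modify branch
    lengths return a new :class:`Phylogeny`.
    """

    tree: dendropy.Tree
    tips: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if any(lb is None for lb in labels):
            raise TreeValidationError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue  # root edge may be lengthless
            if edge.length is None:
                raise TreeValidationError("tree has branches without lengths")
            if edge.length < 0:
                raise TreeValidationError("tree has negative branch lengths")
        self.tips = sorted(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path length for every tip, indexed by label."""
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else node.parent_node._phylomi_depth
            node._phylomi_depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._phylomi_depth
        return pd.Series(depths).loc[self.tips]

    @property
    def depth(self) -> float:
        return float(self.tip_depths().max())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def prune_to(self, taxa) -> "Phylogeny":
        """Subtree induced by ``taxa`` (labels must be a subset of tips)."""
        taxa = list(taxa)
        missing = set(taxa) - set(self.tips)
        if missing:
            raise TreeValidationError(f"taxa not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(taxa)
        return Phylogeny(sub)


@dataclass
class PhyloCovariance:
    """Symmetric PSD matrix of shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    taxa: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def submatrix(self, taxa) -> "PhyloCovariance":
        """Row/column selection — the exact marginal of the implied MVN."""
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(taxa))


def read_newick(path) -> Phylogeny:
    """Read a Newick file into a :class:`Phylogeny`.

    Raises :class:`NewickParseError` on malformed input (dendropy's message
    names the offending position) and :class:`TreeValidationError` on
    duplicate tips or missing branch lengths.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise NewickParseError(f"malformed Newick in {path}: {exc}") from exc
    return Phylogeny(tree)


def read_newick_string(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(file=io.StringIO(newick), schema="newick")
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    return Phylogeny(tree)


def is_ultrametric(tree: Phylogeny, tol: float = 1e-8) -> bool:
    """True iff all root-to-tip depths agree within ``tol`` (relative)."""
    depths = tree.tip_depths().to_numpy()
    dmax = depths.max()
    if dmax == 0:
        return True
    return bool(depths.max() - depths.min() <= tol * dmax)


def ultrametricize(tree: Phylogeny) -> Phylogeny:
    """Extend terminal branches so every tip reaches the maximum depth."""
    out = tree.copy()
    depths = out.tip_depths()
    dmax = float(depths.max())
    for leaf in out.tree.leaf_node_iter():
        leaf.edge.length += dmax - depths[leaf.taxon.label]
    return Phylogeny(out.tree)


def resolve_zero_branches(tree: Phylogeny, fraction: float = 1e-4) -> Phylogeny:
    """Inflate zero-length branches and re-ultrametricize.

    Every zero-length branch is set to ``fraction`` x the median of the
    *positive* branch lengths (zeros excluded so they cannot drag the median
    down), then terminal branches are extended so the tree is ultrametric
    again.  A tree with no zero branches is returned with bit-identical
    lengths.  Idempotent.
    """
    lengths = np.array(
        [e.length for e in tree.tree.preorder_edge_iter() if e.tail_node is not None]
    )
    if lengths.size and (lengths > 0).sum() == 0:
        raise TreeValidationError("degenerate tree: all branches have zero length")
    if not np.any(lengths == 0):
        return tree.copy()
    eps = fraction * float(np.median(lengths[lengths > 0]))
    out = tree.copy()
    for edge in out.tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length == 0:
            edge.length = eps
    return ultrametricize(Phylogeny(out.tree))


def phylo_vcv(tree: Phylogeny, ultrametric_tol: float = 1e-6) -> PhyloCovariance:
    """Brownian-motion variance-covariance matrix of a tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the diagonal
    holds root-to-tip depths.  Rows/columns follow ``tree.tips`` (sorted
    labels).  Non-ultrametric trees only warn: BM itself does not require
    ultrametricity.
    """
    if not is_ultrametric(tree, ultrametric_tol):
        warnings.warn(
            "tree is not ultrametric within tolerance; covariance computed anyway",
            stacklevel=2,
        )
    tips = tree.tips
    index = {lb: i for i, lb in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    # Postorder sweep: each node knows its depth and the tip indices below it;
    # tips in different child subtrees covary by the node's depth.
    for node in tree.tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._phylomi_depth
        node._phylomi_depth = parent_depth + (node.edge.length or 0.0)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            node._phylomi_below = [i]
            C[i, i] = node._phylomi_depth
        else:
            groups = [child._phylomi_below for child in node.child_nodes()]
            d = node._phylomi_depth
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        C[a, groups[gj]] = d
                        C[groups[gj], a] = d
            node._phylomi_below = [i for g in groups for i in g]
    return PhyloCovariance(C, list(tips))
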