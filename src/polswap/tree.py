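"""Genome tree construction, ultrametrization and fixed-depth clade cutting.

The tree is built from the RBH-coverage distance matrix by neighbor joining
and midpoint-rooted.  Because NJ branch lengths do not place all leaves at
the same depth, the tree is then *ultrametrized* by iteratively balancing
subtrees from the leaves toward the root: at an internal node whose children
c_1..c_k subtend (already balanced) subtrees of stem-inclusive heights
H_1..H_k, the target height is the mean H_0 = (H_1 + ... + H_k)/k and every
edge inside subtree i, including its stem edge, is multiplied by
q_i = H_0/H_i.  After one post-order pass all leaves are exactly equidistant
from the root and the topology is unchanged.

Fixed-depth clades are the maximal subtrees of height <= d on the
ultrametric tree; on phage genome trees a depth of 0.15 corresponds roughly
to the genus level and is the unit within which DNA-polymerase heterogeneity
is assessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .orfs import InputError, InvariantError

__all__ = [
    "build_tree",
    "ultrametrize",
    "subtree_height",
    "cut_clades",
    "Clade",
    "CladePartition",
    "read_newick",
    "write_newick",
    "leaf_depths",
]

#: Relative leaf-depth spread above which a tree is rejected as non-ultrametric.
ULTRAMETRIC_RTOL = 1e-9


def build_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix, midpoint-rooted.

    Negative NJ branch-length estimates are clamped to zero.  The result is
    deterministic for a given matrix (taxon order fixes all tie-breaks).
    """
    if not isinstance(matrix, DistanceMatrix):
        matrix = DistanceMatrix(np.asarray(matrix[0]), matrix[1])
    if not np.all(np.isfinite(matrix.data)):
        raise InputError("distance matrix contains non-finite values")
    if matrix.shape[0] < 3:
        raise InputError("need at least 3 taxa to build a tree")
    unrooted = nj(matrix, neg_as_zero=True)
    rooted = unrooted.root_at_midpoint()
    for node in rooted.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    rooted.length = 0.0
    return rooted


def _scale_subtree(node: TreeNode, q: float) -> None:
    for n in node.traverse(include_self=True):
        n.length = (n.length or 0.0) * q


def ultrametrize(tree: TreeNode) -> TreeNode:
    """Balance subtrees leaves-to-root so all leaf depths become equal.

    Stem-inclusive child heights H_i are averaged to H_0 and each child
    subtree (stem edge included) is rescaled by H_0/H_i; a zero-height child
    branch (H_i = 0) cannot be rescaled, so its stem edge is set to H_0
    directly, the limiting behaviour of the scaling.  The input is not
    modified; topology, leaf labels and node names are preserved.
    """
    out = tree.copy()
    height: dict[int, float] = {}
    for node in out.postorder(include_self=True):
        if node.is_tip():
            height[id(node)] = 0.0
            continue
        hs = [(child.length or 0.0) + height[id(child)] for child in node.children]
        h0 = float(np.mean(hs))
        for child, hi in zip(node.children, hs):
            if hi == 0.0:
                child.length = h0
            else:
                _scale_subtree(child, h0 / hi)
        height[id(node)] = h0
    return out


def leaf_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-leaf path length for every leaf."""
    depths: dict[str, float] = {}
    stack = [(tree, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_tip():
            depths[node.name] = d
        else:
            for child in node.children:
                stack.append((child, d + (child.length or 0.0)))
    return depths


def _heights_checked(tree: TreeNode) -> dict[int, float]:
    """Subtree height (uniform leaf depth) per node, validating ultrametricity."""
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            lo[id(node)] = hi[id(node)] = 0.0
        else:
            lo[id(node)] = min((c.length or 0.0) + lo[id(c)] for c in node.children)
            hi[id(node)] = max((c.length or 0.0) + hi[id(c)] for c in node.children)
    total = hi[id(tree)]
    if hi[id(tree)] - lo[id(tree)] > ULTRAMETRIC_RTOL * max(total, 1.0):
        raise InvariantError(
            f"tree is not ultrametric: leaf depths span "
            f"[{lo[id(tree)]:.6g}, {hi[id(tree)]:.6g}]"
        )
    return hi


def subtree_height(tree: TreeNode, node: TreeNode | None = None) -> float:
    """Common leaf depth below ``node`` (the root if omitted); 0 for leaves."""
    node = tree if node is None else node
    heights = _heights_checked(node)
    return heights[id(node)]


@dataclass
class Clade:
    clade_id: str
    node: TreeNode
    leaves: list[str]
    height: float

    @property
    def is_singleton(self) -> bool:
        return len(self.leaves) == 1


@dataclass
class CladePartition:
    """Maximal subtrees of height <= depth; their leaf sets partition the tree."""

    depth: float
    clades: list[Clade]

    def clade_of(self, leaf: str) -> Clade:
        for c in self.clades:
            if leaf in c.leaves:
                return c
        raise KeyError(leaf)

    @property
    def leaf_to_clade(self) -> dict[str, str]:
        return {leaf: c.clade_id for c in self.clades for leaf in c.leaves}


def cut_clades(tree: TreeNode, depth: float = 0.15) -> CladePartition:
    """Cut an ultrametric tree into its maximal subtrees of height <= depth.

    Every returned subtree root has height <= depth while its parent's
    subtree exceeds depth (the tree root is returned whole if the entire
    tree fits).  Singleton clades (one genome) are flagged downstream so
    heterogeneity analysis can restrict itself to multi-genome clades.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    heights = _heights_checked(tree)
    tol = ULTRAMETRIC_RTOL * max(heights[id(tree)], 1.0)
    clades: list[Clade] = []

    def visit(node: TreeNode) -> None:
        if heights[id(node)] <= depth + tol:
            leaves = [tip.name for tip in node.tips()] if not node.is_tip() else [node.name]
            clades.append(
                Clade(
                    clade_id=f"clade{len(clades):04d}",
                    node=node,
                    leaves=leaves,
                    height=heights[id(node)],
                )
            )
            return
        for child in node.children:
            visit(child)

    visit(tree)
    return CladePartition(depth=depth, clades=clades)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_clades_tsv(partition: CladePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_id\tgenome_id\tclade_height\tis_singleton\n")
        for c in partition.clades:
            for leaf in c.leaves:
                fh.write(f"{c.clade_id}\t{leaf}\t{c.height:.6f}\t{int(c.is_singleton)}\n")


__all__.append("write_clades_tsv")
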