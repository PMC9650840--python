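"""Guide trees for homoplasy inference.

The homoplasy engine only needs a reasonable topology with branch
lengths on a relative scale, so guide trees are built by neighbor
joining on closed-form (K2P by default) distances. Trees are held as
scikit-bio ``TreeNode`` objects; this module adds the thin layer the
rest of the package needs: construction from a distance matrix,
deterministic leaf pruning, newick round-trips, and flattened postorder
arrays for vectorised parsimony.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import skbio
from skbio.tree import nj

from .distances import DistanceMatrix

__all__ = ["GuideTree", "build_guide_tree"]


class TreeError(ValueError):
    pass


@dataclass
class FitchArrays:
    """Binarised postorder representation of a rooted tree.

    Nodes 0..n_leaves-1 are leaves (in ``leaf_names`` order); internal
    nodes follow in postorder, each with exactly two children.
    """

    leaf_names: list[str]
    left: np.ndarray  # child indices per internal node, postorder
    right: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)


@dataclass
class GuideTree:
    """Unrooted tree over a genome set (stored with an arbitrary root)."""

    tree: skbio.TreeNode
    _fitch: FitchArrays | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for node in self.tree.postorder():
            if node.length is not None and node.length < 0:
                node.length = 0.0  # NJ can estimate tiny negative lengths

    # -- basics -----------------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.tree.tips()]

    def total_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.tree.postorder() if not n.is_root()))

    def copy(self) -> "GuideTree":
        return GuideTree(self.tree.copy())

    def scale(self, factor: float) -> "GuideTree":
        t = self.tree.copy()
        for node in t.postorder():
            if node.length is not None:
                node.length *= factor
        return GuideTree(t)

    # -- pruning ----------------------------------------------------------
    def prune_leaf(self, name: str) -> "GuideTree":
        """Tree with one leaf removed and unary nodes collapsed."""
        keep = [n for n in self.leaf_names if n != name]
        if len(keep) == len(self.leaf_names):
            raise TreeError(f"leaf {name!r} not in tree")
        if len(keep) < 2:
            raise TreeError("cannot prune below 2 leaves")
        return GuideTree(self.tree.shear(keep))

    # -- serialisation -----------------------------------------------------
    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "GuideTree":
        return cls(skbio.TreeNode.read(io.StringIO(newick)))

    # -- flattened form for parsimony --------------------------------------
    def fitch_arrays(self) -> FitchArrays:
        """Binarised postorder arrays (cached; topology only)."""
        if self._fitch is not None:
            return self._fitch
        leaves = [n for n in self.tree.tips()]
        names = [n.name for n in leaves]
        index = {id(n): i for i, n in enumerate(leaves)}
        next_id = len(leaves)
        left: list[int] = []
        right: list[int] = []

        def visit(node) -> int:
            nonlocal next_id
            if node.is_tip():
                return index[id(node)]
            child_ids = [visit(c) for c in node.children]
            if len(child_ids) == 1:  # collapse unary nodes
                return child_ids[0]
            # resolve multifurcations with zero-length extra nodes;
            # parsimony scores are unchanged by such refinements
            acc = child_ids[0]
            for cid in child_ids[1:]:
                left.append(acc)
                right.append(cid)
                acc = next_id
                next_id += 1
            return acc

        root = visit(self.tree)
        if root != next_id - 1 or not left:
            raise TreeError("tree must contain at least one internal node")
        self._fitch = FitchArrays(names, np.array(left), np.array(right))
        return self._fitch


def build_guide_tree(D: DistanceMatrix) -> GuideTree:
    """Neighbor-joining tree from a distance matrix.

    Negative branch-length estimates are clamped to zero. At least three
    genomes are required for the tree to be defined.
    """
    if len(D.ids) < 3:
        raise TreeError("neighbor joining needs at least 3 genomes")
    dm = skbio.DistanceMatrix(D.values, ids=D.ids)
    return GuideTree(nj(dm))
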