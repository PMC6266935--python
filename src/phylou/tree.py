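"""Gene-family phylogenies and their temporal structure.

A gene family's evolutionary history is represented by a rooted tree whose
tips are gene identifiers and whose branch lengths are treated directly as
process time for the Ornstein-Uhlenbeck machinery (expected replacements per
site; the drift and diffusion matrices absorb any overall time scale).

The covariance mathematics only needs the *temporal* structure of the tree:
the root-to-tip depth of every tip and, for every pair of tips, the depth of
their most recent common ancestor.  :class:`TreeStructure` extracts exactly
that, plus a preorder edge list used by the covariance propagation and the
Monte-Carlo simulator.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeStructure", "parse_newick", "tree_structure"]


class Phylogeny:
    """A rooted gene-family tree with branch lengths on every edge.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the input
    contract: unique non-empty tip labels, non-negative branch lengths on
    all non-root edges, and at least two tips.  Polytomies are accepted.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise ValueError(f"malformed Newick string: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        leaves = list(self._tree.leaf_node_iter())
        if len(leaves) < 2:
            raise ValueError("phylogeny must have at least 2 tips")
        labels = []
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if not label:
                raise ValueError("every tip must carry a non-empty label")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            length = node.edge.length
            if length is None:
                raise ValueError("missing branch length on an edge")
            if length < 0:
                raise ValueError(f"negative branch length: {length}")
        zero_pendant = [
            (leaf.taxon.label if leaf.taxon else leaf.label)
            for leaf in leaves
            if leaf.edge.length == 0
        ]
        if zero_pendant:
            warnings.warn(
                "zero-length pendant edge(s) at tips "
                f"{zero_pendant}: these tips are perfectly correlated with "
                "their sister lineage",
                stacklevel=3,
            )

    # -- accessors ---------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in lexicographic order."""
        return sorted(
            (leaf.taxon.label if leaf.taxon else leaf.label)
            for leaf in self._tree.leaf_node_iter()
        )

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


@dataclass
class TreeStructure:
    """Temporal structure of a rooted phylogeny.

    Attributes
    ----------
    tip_order : list of str
        Fixed (lexicographic) ordering of tips; all matrices follow it.
    depths : (n,) ndarray
        Root-to-tip path length per tip, ``T_i``.
    shared_depths : (n, n) ndarray
        Root-to-MRCA path length per tip pair, ``t_ij``; the diagonal
        equals ``depths``.
    edges : list of (parent, child, length)
        Preorder edge list over internal node ids; node 0 is the root.
    leaf_nodes : (n,) ndarray of int
        Node id of each tip, in ``tip_order``.
    mrca_nodes : (n, n) ndarray of int
        Node id of the MRCA of each tip pair (a tip's own node on the
        diagonal).
    """

    tip_order: list[str]
    depths: np.ndarray
    shared_depths: np.ndarray
    edges: list[tuple[int, int, float]]
    leaf_nodes: np.ndarray
    mrca_nodes: np.ndarray
    n_nodes: int = field(default=0)

    @property
    def n_tips(self) -> int:
        return len(self.tip_order)

    @property
    def height(self) -> float:
        return float(self.depths.max())


def parse_newick(text: str) -> Phylogeny:
    """Parse a strict Newick string (lengths required on all edges)."""
    return Phylogeny.from_newick(text)


def tree_structure(tree: Phylogeny) -> TreeStructure:
    """Compute tip depths, pairwise MRCA depths and the preorder edge list.

    Depths are exact sums of edge lengths; a root edge length, if present,
    is ignored (the root sits at time zero).  The shared-depth matrix of any
    valid rooted tree satisfies the three-point condition: among
    ``{t_ij, t_ik, t_jk}`` the two smallest are equal.
    """
    dtree = tree.dendropy_tree
    tip_order = tree.tips
    tip_index = {label: i for i, label in enumerate(tip_order)}
    n = len(tip_order)

    # preorder node ids; root id 0, root depth 0
    node_id: dict[int, int] = {}
    edges: list[tuple[int, int, float]] = []
    depth_of_node: list[float] = []
    for node in dtree.preorder_node_iter():
        nid = len(depth_of_node)
        node_id[id(node)] = nid
        if node is dtree.seed_node:
            depth_of_node.append(0.0)
        else:
            pid = node_id[id(node.parent_node)]
            length = float(node.edge.length)
            depth_of_node.append(depth_of_node[pid] + length)
            edges.append((pid, nid, length))

    depths = np.zeros(n)
    leaf_nodes = np.zeros(n, dtype=int)
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        i = tip_index[label]
        depths[i] = depth_of_node[node_id[id(leaf)]]
        leaf_nodes[i] = node_id[id(leaf)]

    shared = np.zeros((n, n))
    mrca = np.zeros((n, n), dtype=int)
    np.fill_diagonal(shared, depths)
    mrca[np.diag_indices(n)] = leaf_nodes

    # postorder: tips below each node; cross-child pairs have this node
    # as their MRCA (polytomies: all pairs across distinct children)
    below: dict[int, list[int]] = {}
    for node in dtree.postorder_node_iter():
        nid = node_id[id(node)]
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            below[nid] = [tip_index[label]]
            continue
        child_sets = [below[node_id[id(c)]] for c in node.child_nodes()]
        merged: list[int] = []
        for a_idx, set_a in enumerate(child_sets):
            for set_b in child_sets[a_idx + 1 :]:
                for i in set_a:
                    for j in set_b:
                        shared[i, j] = shared[j, i] = depth_of_node[nid]
                        mrca[i, j] = mrca[j, i] = nid
            merged.extend(set_a)
        below[nid] = merged

    return TreeStructure(
        tip_order=tip_order,
        depths=depths,
        shared_depths=shared,
        edges=edges,
        leaf_nodes=leaf_nodes,
        mrca_nodes=mrca,
        n_nodes=len(depth_of_node),
    )
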