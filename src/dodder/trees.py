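"""Rooted phylogenies: Newick I/O, indexing, MRCAs, ultrametricity checks.

Dendropy does the parsing and writing; likelihood code works on a flat
array-indexed view (:class:`IndexedTree`) so that pruning and simulation are
plain numpy loops over a postorder schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "IndexedTree", "is_ultrametric"]


@dataclass
class IndexedTree:
    """Array view of a rooted tree.

    Nodes are numbered 0..n_nodes-1 with tips first (0..n_tips-1, in the
    order of ``tip_labels``); ``postorder`` visits children before parents and
    ends at the root.  ``edge_length[i]`` is the length of the branch above
    node i (0.0 for the root).
    """

    tip_labels: list[str]
    parent: np.ndarray          # int, -1 for root
    edge_length: np.ndarray     # float
    children: list[list[int]]
    postorder: np.ndarray       # int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def tree_length(self) -> float:
        return float(self.edge_length.sum())

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    def mrca(self, labels) -> int:
        """Index of the most recent common ancestor of the given tip labels."""
        want = {self.tip_index(lab) for lab in labels}
        below: list[set] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder:
            node = int(node)
            if not self.children[node]:
                below[node] = {node}
            else:
                for ch in self.children[node]:
                    below[node] |= below[ch]
            if want <= below[node]:
                return node
        raise ValueError(f"no common ancestor found for {labels!r}")

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            node = int(node)
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + self.edge_length[node]
        return depth

    def node_ages(self) -> np.ndarray:
        """Ages (time before the youngest tip) assuming an ultrametric tree."""
        depth = self.node_depths()
        return depth.max() - depth


class Phylogeny:
    """A rooted phylogeny with named tips and branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` that guarantees unique tip
    labels and provides the array view used by the numerical modules.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ValueError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- basic structure ----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def drop_tips(self, labels) -> "Phylogeny":
        """Return a copy with the given tips removed (unsampled taxa etc.)."""
        keep = [lab for lab in self.tip_labels if lab not in set(labels)]
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree)

    def index(self) -> IndexedTree:
        """Flatten to the array view (tips first, postorder schedule)."""
        leaves = list(self._tree.leaf_node_iter())
        internals = [n for n in self._tree.preorder_node_iter() if not n.is_leaf()]
        order = {id(n): i for i, n in enumerate(leaves)}
        for j, n in enumerate(internals):
            order[id(n)] = len(leaves) + j
        n_nodes = len(leaves) + len(internals)
        parent = np.full(n_nodes, -1, dtype=int)
        edge = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for node in self._tree.preorder_node_iter():
            i = order[id(node)]
            edge[i] = node.edge.length or 0.0
            if node.parent_node is not None:
                p = order[id(node.parent_node)]
                parent[i] = p
                children[p].append(i)
        post = [order[id(n)] for n in self._tree.postorder_node_iter()]
        return IndexedTree(
            tip_labels=[leaf.taxon.label for leaf in leaves],
            parent=parent,
            edge_length=edge,
            children=children,
            postorder=np.asarray(post, dtype=int),
        )

    # -- metrics ------------------------------------------------------------

    @property
    def tree_length(self) -> float:
        return self.index().tree_length

    def mrca_tips(self, labels) -> set[str]:
        """Tip labels descending from the MRCA of ``labels``."""
        idx = self.index()
        node = idx.mrca(labels)
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if not idx.children[n]:
                out.append(idx.tip_labels[n])
            stack.extend(idx.children[n])
        return set(out)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        return is_ultrametric(self, tol)


def is_ultrametric(tree: Phylogeny, tol: float = 1e-8) -> bool:
    """True iff all root-to-tip depths agree within relative tolerance.

    A single-tip tree is vacuously ultrametric.
    """
    idx = tree.index()
    depths = idx.node_depths()[: idx.n_tips]
    if len(depths) <= 1:
        return True
    dmax, dmin = float(depths.max()), float(depths.min())
    if dmax == 0:
        return True
    return dmax / max(dmin, np.finfo(float).tiny) - 1.0 <= tol
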