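"""Rooted strain trees with branch lengths in substitutions per site.

:class:`StrainTree` is a light array-backed representation optimised for the
repeated traversals done by the likelihood and clade machinery.  Parsing and
serialisation go through dendropy; polytomies are preserved.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["StrainTree", "read_newick", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed or invalid input trees."""


@dataclass
class StrainTree:
    """Rooted tree; node 0 is the root, nodes are in a preorder numbering.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 for the root.
    lengths : (n_nodes,) float array of branch lengths (edge above each
        node); 0.0 for the root.
    children : list of lists of child indices.
    labels : node labels; every leaf carries a genome ID, internal nodes
        get stable ``N<i>`` labels if the source tree had none.
    """

    parent: np.ndarray
    lengths: np.ndarray
    children: list
    labels: list

    _postorder: np.ndarray = field(default=None, repr=False, compare=False)

    # ---------------------------------------------------------------- basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def leaf_labels(self) -> list:
        return [self.labels[i] for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def postorder(self) -> np.ndarray:
        if self._postorder is None:
            order, stack = [], [0]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1])
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != 0:
                depth[v] = depth[self.parent[v]] + self.lengths[v]
        return depth

    def leaf_set(self, node: int) -> list:
        """Indices of leaves descending from ``node`` (node itself if leaf)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(v)
        return out

    def descendants(self, node: int) -> list:
        """All proper descendants of ``node`` (preorder)."""
        out, stack = [], list(self.children[node])
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def label_index(self) -> dict:
        return {self.labels[i]: i for i in range(self.n_nodes)}

    def leaf_label_index(self) -> dict:
        return {self.labels[i]: i for i in self.leaf_indices}

    # ----------------------------------------------------------- validation
    def validate(self) -> None:
        if np.any(self.lengths[1:] < 0):
            raise TreeError("negative branch length")
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    # ---------------------------------------------------------- conversion
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "StrainTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list = [[] for _ in range(n)]
        labels = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    raise TreeError(
                        f"missing branch length above node "
                        f"{nd.taxon.label if nd.taxon else i}"
                    )
                lengths[i] = nd.edge.length
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        for i in range(n):
            if labels[i] is None:
                if not children[i]:
                    raise TreeError("leaf without label")
                labels[i] = f"N{i}"
        tree = cls(parent=parent, lengths=lengths, children=children, labels=labels)
        tree.validate()
        return tree

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_leaf(i):
                dnodes[i].taxon = taxa.new_taxon(self.labels[i])
            else:
                dnodes[i].label = self.labels[i]
            if i != 0:
                dnodes[self.parent[i]].add_child(dnodes[i])
                dnodes[i].edge.length = float(self.lengths[i])
        dtree.seed_node = dnodes[0]
        return dtree

    def write_newick(self, path) -> None:
        self.to_dendropy().write(
            path=str(path),
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )

    def newick_string(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_newick(source) -> StrainTree:
    """Parse a rooted Newick tree; every non-root edge must carry a length.

    ``source`` may be a path or a Newick string.
    """
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    if text is None:
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            file=_io.StringIO(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return StrainTree.from_dendropy(dtree)
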