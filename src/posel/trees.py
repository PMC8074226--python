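"""Rooted phylogenies with branch lengths, backed by simple arrays.

Branch lengths are expected substitutions per codon site throughout the
package. Newick parsing and writing is delegated to dendropy; internally a
tree is held as a parent array in postorder, which is what the pruning
likelihood and the simulator consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class PhyloTree:
    """A rooted tree over named leaves.

    Node ids are 0..n_nodes-1 arranged in postorder (every child precedes its
    parent; the root is last). ``parent[i]`` is the parent id of node i (-1
    for the root) and ``edge_length[i]`` the length of the branch above node
    i (0.0 for the root). Leaves are the nodes with no children; their names
    are in ``leaf_names`` keyed by node id order of appearance.
    """

    parent: np.ndarray  # int array, len n_nodes, postorder
    edge_length: np.ndarray  # float array, len n_nodes
    leaf_ids: np.ndarray  # int array of node ids that are leaves
    leaf_names: tuple[str, ...]  # names aligned with leaf_ids
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not self.children:
            kids: list[list[int]] = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    kids[p].append(i)
            self.children = kids
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("leaf names must be unique")
        if np.any(self.edge_length < 0):
            raise ValueError("branch lengths must be non-negative")

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def tree_length(self) -> float:
        """Sum of all branch lengths (expected substitutions per codon site)."""
        return float(self.edge_length.sum())

    def leaf_index(self) -> dict[str, int]:
        return {name: int(i) for name, i in zip(self.leaf_names, self.leaf_ids)}

    def with_edge_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        """Copy of this tree with branch lengths replaced (root entry forced 0)."""
        el = np.asarray(lengths, dtype=float).copy()
        if el.shape != self.edge_length.shape:
            raise ValueError("length vector does not match node count")
        el[self.root] = 0.0
        if np.any(el < 0):
            raise ValueError("branch lengths must be non-negative")
        return PhyloTree(
            parent=self.parent.copy(),
            edge_length=el,
            leaf_ids=self.leaf_ids.copy(),
            leaf_names=self.leaf_names,
        )

    def scaled(self, factor: float) -> "PhyloTree":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return self.with_edge_lengths(self.edge_length * factor)

    # -- distances (used by tests and the subtree invariant) --------------
    def path_length(self, a: str, b: str) -> float:
        """Patristic distance between two leaves."""
        idx = self.leaf_index()
        pa, pb = idx[a], idx[b]
        anc_a: dict[int, float] = {}
        node, d = pa, 0.0
        while node != -1:
            anc_a[node] = d
            d += float(self.edge_length[node])
            node = int(self.parent[node])
        node, d = pb, 0.0
        while node not in anc_a:
            d += float(self.edge_length[node])
            node = int(self.parent[node])
        return d + anc_a[node]

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        nodes = list(dtree.postorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        edge_length = np.zeros(len(nodes), dtype=float)
        leaf_ids, leaf_names = [], []
        for nd in nodes:
            i = ids[id(nd)]
            if nd.parent_node is not None:
                parent[i] = ids[id(nd.parent_node)]
                edge_length[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                leaf_ids.append(i)
                leaf_names.append(nd.taxon.label if nd.taxon else "")
        return cls(
            parent=parent,
            edge_length=edge_length,
            leaf_ids=np.array(leaf_ids, dtype=int),
            leaf_names=tuple(leaf_names),
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as e:  # dendropy raises schema-specific subclasses
            raise ValueError(f"malformed newick: {e}") from e
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        labels: dict[int, str] = {
            int(i): name for i, name in zip(self.leaf_ids, self.leaf_names)
        }

        def render(node: int) -> str:
            if not self.children[node]:
                s = labels[node]
            else:
                s = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return s
            return f"{s}:{self.edge_length[node]:.10g}"

        return render(self.root) + ";"

    def subtree(self, keep: list[str]) -> "PhyloTree":
        """Induced subtree on a subset of leaves; path lengths are preserved
        (suppressed degree-2 nodes have their edges summed)."""
        missing = set(keep) - set(self.leaf_names)
        if missing:
            raise ValueError(f"unknown leaves: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("subtree needs at least 2 leaves")
        dtree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        taxa = [t for t in dtree.taxon_namespace if t.label in set(keep)]
        dtree.retain_taxa(taxa)
        return PhyloTree.from_dendropy(dtree)
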