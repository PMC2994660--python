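"""Phylogenetic tree container used by the codon-model machinery.

Trees are read from Newick (via dendropy) and converted to a flat
parent-array representation that the pruning likelihood and the
sequence simulator share.  Branch lengths are expected substitutions
per codon.  A basal bifurcation is collapsed on input so that an
n-taxon binary tree exposes 2n - 3 branches, each identified by the
label of the node below it (its child node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree"]


@dataclass
class PhyloTree:
    """Rooted-for-computation tree over ``taxa`` with per-branch lengths.

    Nodes are indexed 0..n_nodes-1 with tips first (in ``taxa`` order)
    and the root last.  ``parent[i]`` is the parent index (-1 for the
    root) and ``lengths[i]`` the length of the branch above node ``i``
    (0 for the root).  Because the substitution models used here are
    time-reversible, the likelihood does not depend on the placement of
    this computational root.
    """

    taxa: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        if not self.node_labels:
            self.node_labels = list(self.taxa) + [
                f"n{i}" for i in range(len(self.taxa), self.n_nodes)
            ]
        # children lists and a postorder over internal nodes
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self._children[p].append(i)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self._children[v])
        self.postorder = [v for v in reversed(order) if self._children[v]]

    # -- basic structure -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def edges(self) -> list[int]:
        """Branch identifiers: every non-root node indexes the branch above it."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def branch_label(self, node: int) -> str:
        return self.node_labels[node]

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(self.taxa, self.parent.copy(), np.asarray(lengths, float),
                         list(self.node_labels))

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    # -- Newick I/O ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string or file path.

        A degree-2 root is collapsed (the two basal branch lengths are
        summed) so branch counts match the unrooted tree.
        """
        if "(" in source:
            dt = dendropy.Tree.get(data=source, schema="newick")
        else:
            dt = dendropy.Tree.get(path=source, schema="newick")
        root = dt.seed_node
        if len(root.child_nodes()) == 2:
            dt.collapse_basal_bifurcation()
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        tips = [lf for lf in dt.leaf_node_iter()]
        taxa = [lf.taxon.label for lf in tips]
        internal = [nd for nd in dt.postorder_node_iter() if not nd.is_leaf()]
        # tips first, then internal nodes in postorder (root ends up last)
        index = {id(nd): i for i, nd in enumerate(tips)}
        for j, nd in enumerate(internal):
            index[id(nd)] = len(tips) + j
        n = len(tips) + len(internal)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        for nd in dt.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        labels = list(taxa) + [
            (nd.label or f"n{len(tips) + j}") for j, nd in enumerate(internal)
        ]
        return cls(taxa, parent, lengths, labels)

    def to_newick(self, annotations: dict[str, str] | None = None) -> str:
        """Serialize with branch lengths; optional per-branch annotations
        (keyed by child-node label) are appended as ``[&key]`` comments."""

        def fmt(node: int) -> str:
            if not self._children[node]:
                s = self.taxa[node]
            else:
                s = "(" + ",".join(fmt(c) for c in self._children[node]) + ")"
            if self.parent[node] >= 0:
                s += f":{self.lengths[node]:.6g}"
                if annotations and self.node_labels[node] in annotations:
                    s += f"[&{annotations[self.node_labels[node]]}]"
            return s

        return fmt(self.root) + ";"

    # -- convenience constructors ---------------------------------------
    @classmethod
    def five_taxon_default(cls, scale: float = 1.2) -> "PhyloTree":
        """A 5-taxon tree of the Saccharomyces sensu stricto shape with
        branch lengths ``scale`` times a fixed relative profile.

        The default total length (~4.3 expected substitutions per codon)
        represents a rapidly evolving gene across this clade, where
        synonymous-site divergence between the outermost species pairs
        is substantial.
        """
        nwk = (
            "((Scer:{a},Spar:{a}):{b},Smik:{c},(Skud:{c},Sbay:{d}):{b});"
        ).format(a=0.3 * scale, b=0.5 * scale, c=0.6 * scale, d=0.8 * scale)
        return cls.from_newick(nwk)
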