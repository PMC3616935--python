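"""Phylogenetic trees with optional foreground-branch marking.

Trees are parsed from Newick with :mod:`dendropy` and converted to a flat
array representation convenient for pruning: nodes are indexed 0..N-1 in a
postorder with the root last; every non-root node carries the branch to its
parent.  A branch can be marked *foreground* for branch-site models, either
with the codeml-style ``#1`` suffix in the Newick string or programmatically
by node label / leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_BRANCH_LENGTH = 0.1


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Rooted representation of a (possibly unrooted-convention) tree.

    Attributes
    ----------
    parent:
        parent[i] = index of node i's parent (-1 for the root).
    children:
        children[i] = tuple of child indices (empty for leaves).
    branch_lengths:
        branch_lengths[i] = length of the branch above node i, in expected
        substitutions per codon; unused entry for the root.
    labels:
        node labels; all leaves labelled, internal labels optional ("").
    foreground:
        boolean mask over nodes; True marks the branch above that node as
        foreground for branch-site models.
    """

    parent: np.ndarray
    children: list[tuple[int, ...]]
    branch_lengths: np.ndarray
    labels: list[str]
    foreground: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.foreground is None:
            self.foreground = np.zeros(self.n_nodes, dtype=bool)
        leaves = self.leaf_labels()
        if len(set(leaves)) != len(leaves):
            raise TreeError("duplicate leaf labels")

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices()]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        seen: list[int] = []
        while stack:
            v = stack.pop()
            seen.append(v)
            stack.extend(self.children[v])
        return list(reversed(seen))

    def branch_indices(self) -> list[int]:
        """Nodes that carry a branch (all but the root)."""
        r = self.root
        return [i for i in range(self.n_nodes) if i != r]

    def total_length(self) -> float:
        return float(sum(self.branch_lengths[i] for i in self.branch_indices()))

    # -- foreground marking ------------------------------------------------
    def with_foreground(self, label: str) -> "PhyloTree":
        """Copy of the tree with the branch above the named node marked."""
        t = self.copy()
        matches = [i for i, l in enumerate(t.labels) if l == label]
        if not matches:
            raise TreeError(f"no node labelled {label!r}")
        t.foreground[:] = False
        t.foreground[matches[0]] = True
        return t

    def foreground_labels(self) -> list[str]:
        return [self.labels[i] or f"node{i}" for i in np.where(self.foreground)[0]]

    def internal_branch_labels(self) -> list[str]:
        """Labels of internal (non-leaf, non-root) branches."""
        r = self.root
        return [
            self.labels[i] or f"node{i}"
            for i in range(self.n_nodes)
            if i != r and not self.is_leaf(i)
        ]

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            children=[tuple(c) for c in self.children],
            branch_lengths=self.branch_lengths.copy(),
            labels=list(self.labels),
            foreground=self.foreground.copy(),
        )

    def with_branch_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        t = self.copy()
        t.branch_lengths = np.asarray(lengths, dtype=float).copy()
        return t

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        def rec(i: int) -> str:
            fg = "#1" if self.foreground[i] else ""
            if self.is_leaf(i):
                return f"{self.labels[i]}{fg}:{self.branch_lengths[i]:.10g}"
            inner = ",".join(rec(c) for c in self.children[i])
            if i == self.root:
                return f"({inner}){self.labels[i]}"
            return f"({inner}){self.labels[i]}{fg}:{self.branch_lengths[i]:.10g}"

        return rec(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.full(len(nodes), np.nan)
    labels: list[str] = []
    children: list[tuple[int, ...]] = []
    fg = np.zeros(len(nodes), dtype=bool)
    for i, n in enumerate(nodes):
        if n.parent_node is not None:
            parent[i] = index[id(n.parent_node)]
        raw = n.taxon.label if n.taxon is not None else (n.label or "")
        label = raw or ""
        if label.endswith("#1"):
            fg[i] = True
            label = label[:-2].strip()
        labels.append(label)
        blen[i] = n.edge.length if n.edge.length is not None else np.nan
        children.append(tuple(index[id(c)] for c in n.child_nodes()))
    blen = np.where(np.isnan(blen), DEFAULT_BRANCH_LENGTH, blen)
    blen[parent == -1] = 0.0  # the root carries no branch
    return PhyloTree(
        parent=parent, children=children, branch_lengths=blen, labels=labels,
        foreground=fg,
    )


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (codeml-style ``#1`` foreground tags allowed)."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree(path) -> PhyloTree:
    """Read one tree from a Newick file.

    Branch lengths absent from the file default to
    :data:`DEFAULT_BRANCH_LENGTH`; a trailing ``#1`` on any label marks the
    branch above that node as foreground.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"empty tree file: {path}")
    return parse_newick(text)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
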