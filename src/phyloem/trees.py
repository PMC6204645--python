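"""Phylogenetic tree structure, balanced simulation trees, Newick I/O.

Trees are stored rooted for computation (the likelihood model is
time-reversible, so root placement is arbitrary); the simulation trees are
unrooted topologies represented with a trifurcating root node.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "make_balanced_tree",
    "parse_newick",
    "write_newick",
    "tree_length",
    "NewickError",
]


class NewickError(ValueError):
    """Raised for malformed Newick input."""


class PhyloTree:
    """A rooted phylogeny with branch lengths.

    Parameters
    ----------
    parent
        ``parent[i]`` is the node index of the parent of node ``i``
        (``-1`` for the root). Parents must precede children.
    lengths
        ``lengths[i]`` is the length, in expected substitutions per site,
        of the branch joining node ``i`` to its parent (ignored for the
        root). All lengths must be non-negative.
    labels
        ``labels[i]`` is the taxon label for leaf ``i`` and ``None`` for
        internal nodes. Leaf labels must be unique.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("parent, lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        if np.any(self.parent[np.arange(n)] >= np.arange(n)):
            raise ValueError("parents must precede children in node order")
        if np.any(self.lengths[np.arange(n) != self.root] < 0):
            raise ValueError("branch lengths must be non-negative")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                self.children[p].append(i)
        leaf_labels = [self.labels[i] for i in self.leaf_indices()]
        if any(l is None for l in leaf_labels):
            raise ValueError("every leaf must carry a label")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError("leaf labels must be unique")

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices())

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> Iterator[int]:
        """Node indices, children before parents."""
        stack = [self.root]
        order: list[int] = []
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return iter(reversed(order))

    def tree_length(self) -> float:
        """Sum of all branch lengths (the tree length l)."""
        mask = np.arange(self.n_nodes) != self.root
        return float(self.lengths[mask].sum())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths.copy(), list(self.labels))

    def internal_branch_indices(self) -> list[int]:
        """Indices of non-root internal nodes (= internal branches)."""
        return [
            i
            for i in range(self.n_nodes)
            if i != self.root and not self.is_leaf(i)
        ]

    # -- rerooting --------------------------------------------------------

    def rerooted(self, new_root: int) -> "PhyloTree":
        """Return an equivalent tree rooted at ``new_root``.

        Branch lengths are carried over unchanged (an edge keeps its length
        whichever direction it points). If the old root is left with a
        single child it is spliced out and the two incident branch lengths
        are summed, so rerooting never creates a degree-two node.
        """
        if self.is_leaf(new_root):
            raise ValueError("cannot root at a leaf")
        n = self.n_nodes
        # neighbour lists with edge lengths in the unrooted sense
        nbrs: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                nbrs[i].append((p, float(self.lengths[i])))
                nbrs[p].append((i, float(self.lengths[i])))
        # splice old root if it would become degree-2
        drop = -1
        if len(self.children[self.root]) == 2 and new_root != self.root:
            a, b = self.children[self.root]
            la = float(self.lengths[a])
            lb = float(self.lengths[b])
            drop = self.root
            for node, other, lo in ((a, b, lb), (b, a, la)):
                nbrs[node] = [
                    (other, la + lb) if x == drop else (x, l)
                    for x, l in nbrs[node]
                ]
        # BFS from the new root: order guarantees parents precede children
        order = [new_root]
        visited = {new_root}
        if drop >= 0:
            visited.add(drop)
        par_of: dict[int, tuple[int, float]] = {}
        pos = 0
        while pos < len(order):
            v = order[pos]
            pos += 1
            for w, l in nbrs[v]:
                if w not in visited:
                    visited.add(w)
                    par_of[w] = (v, l)
                    order.append(w)
        idx = {v: k for k, v in enumerate(order)}
        par = [-1] * len(order)
        lens = [0.0] * len(order)
        labs: list[str | None] = [self.labels[v] for v in order]
        for w, (v, l) in par_of.items():
            par[idx[w]] = idx[v]
            lens[idx[w]] = l
        return PhyloTree(par, lens, labs)

    # -- dendropy bridge --------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=write_newick(self), schema="newick")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhyloTree(n_leaves={self.n_leaves}, "
            f"length={self.tree_length():.6g})"
        )


# -- construction ---------------------------------------------------------


def _balanced_splits(n: int) -> list[int]:
    """Split n leaves over the three root subtrees as evenly as possible."""
    base, rem = divmod(n, 3)
    return [base + (1 if i < rem else 0) for i in range(3)]


def make_balanced_tree(
    n_taxa: int,
    branch_length: float,
    long_internal: float | None = None,
    labels: Sequence[str] | None = None,
) -> PhyloTree:
    """Build the maximally balanced unrooted tree used in the simulations.

    The tree has a central degree-3 node whose three subtrees hold the
    taxa split as evenly as possible (6 -> 2/2/2 giving the three-cherry
    shape, 24 -> 8/8/8, 96 -> 32/32/32); each subtree is a balanced rooted
    binary tree. All 2*n_taxa-3 branches get ``branch_length``; if
    ``long_internal`` is given, the first internal branch in preorder (for
    the 6-taxon tree, the branch joining the first cherry to the center)
    is set to that value instead.
    """
    if n_taxa < 3:
        raise ValueError("a balanced unrooted tree needs at least 3 taxa")
    if branch_length <= 0:
        raise ValueError("branch_length must be positive")
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")

    parent: list[int] = [-1]
    lengths: list[float] = [0.0]
    labs: list[str | None] = [None]
    next_leaf = iter(labels)

    def build(m: int, par: int) -> None:
        idx = len(parent)
        parent.append(par)
        lengths.append(branch_length)
        if m == 1:
            labs.append(next(next_leaf))
        else:
            labs.append(None)
            hi = (m + 1) // 2
            build(hi, idx)
            build(m - hi, idx)

    for size in _balanced_splits(n_taxa):
        build(size, 0)

    tree = PhyloTree(parent, lengths, labs)
    if long_internal is not None:
        if long_internal <= 0:
            raise ValueError("long_internal must be positive")
        internals = tree.internal_branch_indices()
        if not internals:
            raise ValueError("tree has no internal branch to lengthen")
        tree.lengths[internals[0]] = float(long_internal)
    return tree


# -- Newick I/O -----------------------------------------------------------


def parse_newick(text: str, allow_missing_lengths: bool = False) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required; with ``allow_missing_lengths`` a missing
    length is mapped to 0 instead of raising.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick string: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent: list[int] = []
    lengths: list[float] = []
    labs: list[str | None] = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is None:
            parent.append(-1)
            lengths.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            if nd.edge.length is None:
                if not allow_missing_lengths:
                    label = nd.taxon.label if nd.taxon else "<internal>"
                    raise NewickError(
                        f"missing branch length on node {label!r} "
                        f"(node {i} in preorder)"
                    )
                lengths.append(0.0)
            else:
                lengths.append(float(nd.edge.length))
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickError(f"leaf without label (node {i} in preorder)")
            labs.append(nd.taxon.label.replace(" ", "_"))
        else:
            labs.append(None)
    return PhyloTree(parent, lengths, labs)


def write_newick(tree: PhyloTree, digits: int = 10) -> str:
    """Serialize to Newick with branch lengths (default 10 significant digits)."""

    def fmt(x: float) -> str:
        return f"{x:.{digits}g}"

    def render(i: int) -> str:
        if tree.is_leaf(i):
            body = tree.labels[i]
        else:
            body = "(" + ",".join(render(c) for c in tree.children[i]) + ")"
        if i == tree.root:
            return body
        return f"{body}:{fmt(float(tree.lengths[i]))}"

    return render(tree.root) + ";"


def tree_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths, in expected substitutions per site."""
    return tree.tree_length()
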