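"""Phylogenetic primitives: Faith's PD, turnover components, depth rescaling.

Trees are stored in a flat preorder layout (``parent[i] < i`` for every
non-root node) so depth and subtree computations are plain array scans.
Newick parsing is delegated to :mod:`dendropy`; writing is done directly.

Conventions
-----------
* PD is *rooted*: the branch set of a community always includes the path
  from the community's most recent common ancestor up to the tree root.
  This makes ``a + b + c == PD(union)`` exact for the turnover partition.
* Node "depth" is distance from the root.  For an ultrametric tree of
  height ``h``, a depth ``d`` corresponds to an age (time before present)
  of ``h - d``.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "Community",
    "BranchPartition",
    "faith_pd",
    "branch_partition",
    "phylo_simpson",
    "delta_transform",
    "truncate_tree",
    "read_newick_trees",
    "write_newick_trees",
]

#: A community is simply a set of tip labels.
Community = frozenset


class Phylogeny:
    """Rooted tree with branch lengths in flat preorder arrays.

    Parameters
    ----------
    parent
        ``parent[i]`` is the index of node ``i``'s parent; the root is node
        0 with ``parent[0] == -1``.  Nodes must be in preorder
        (``parent[i] < i``).
    lengths
        Branch length above each node (``lengths[0]`` is ignored, kept 0).
    labels
        Node labels; every tip (childless node) must carry a unique label.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.labels = list(labels)
        n = self.parent.size
        if n == 0 or self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent == -1)")
        if np.sum(self.parent == -1) != 1:
            raise ValueError("exactly one root is required")
        if n > 1 and (
            np.any(self.parent[1:] < 0)
            or np.any(self.parent[1:] >= np.arange(1, n))
        ):
            raise ValueError("nodes must be in preorder (parent index < node index)")
        if np.any(self.lengths[1:] < 0):
            raise ValueError("branch lengths must be non-negative")
        self.lengths[0] = 0.0
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            children[self.parent[i]].append(i)
        self._children = children
        self.tip_nodes = np.array(
            [i for i in range(n) if not children[i]], dtype=np.int64
        )
        tip_labels = [self.labels[i] for i in self.tip_nodes]
        if any(lbl is None for lbl in tip_labels):
            raise ValueError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("tip labels must be unique")
        self._tip_node_of = {self.labels[i]: int(i) for i in self.tip_nodes}
        self._depths: np.ndarray | None = None
        self._incidence: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tips(self) -> list[str]:
        """Tip labels in node order."""
        return [self.labels[i] for i in self.tip_nodes]

    @property
    def n_tips(self) -> int:
        return self.tip_nodes.size

    def children(self, i: int) -> list[int]:
        return self._children[i]

    @property
    def node_depths(self) -> np.ndarray:
        """Distance from the root for every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):
                d[i] = d[self.parent[i]] + self.lengths[i]
            self._depths = d
        return self._depths

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return float(self.node_depths[self.tip_nodes].max())

    def tip_node(self, label: str) -> int:
        try:
            return self._tip_node_of[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def edge_tip_incidence(self) -> np.ndarray:
        """Boolean matrix ``(n_nodes, n_tips)``: tip j descends from node i.

        Row ``i`` describes the branch *above* node ``i`` (the root row is
        all-True but carries zero length).
        """
        if self._incidence is None:
            inc = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            tip_col = {int(node): j for j, node in enumerate(self.tip_nodes)}
            for i in range(self.n_nodes - 1, -1, -1):
                if i in tip_col:
                    inc[i, tip_col[i]] = True
                if i > 0:
                    inc[self.parent[i]] |= inc[i]
            self._incidence = inc
        return self._incidence

    def tip_distance_matrix(self) -> np.ndarray:
        """Pairwise patristic distances between tips (tip-node order)."""
        inc = self.edge_tip_incidence().astype(float)
        weighted = inc * self.lengths[:, None]
        shared = weighted.T @ inc  # depth of the MRCA path shared by i and j
        depths = self.node_depths[self.tip_nodes]
        return depths[:, None] + depths[None, :] - 2.0 * shared

    # -- Newick I/O ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"invalid newick: {exc}") from exc
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = []
        for i, nd in enumerate(nodes):
            parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError(
                        "branch lengths are required on every non-root edge"
                    )
                lengths[i] = float(nd.edge.length)
            label = None
            if nd.taxon is not None:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            labels.append(label)
        return cls(parent, lengths, labels)

    def to_newick(self) -> str:
        def fmt_label(label: str | None) -> str:
            if not label:
                return ""
            if re.search(r"[\s,():;'\[\]]", label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(i: int) -> str:
            kids = self._children[i]
            inner = (
                "(" + ",".join(render(c) for c in kids) + ")" if kids else ""
            )
            blen = "" if i == 0 else f":{self.lengths[i]:.12g}"
            return f"{inner}{fmt_label(self.labels[i])}{blen}"

        return render(0) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, height {self.height:.4g}>"


@dataclass(frozen=True)
class BranchPartition:
    """Branch-length components of a community pair.

    ``a`` is shared branch length, ``b``/``c`` the lengths unique to the
    first/second community (rooted PD convention).
    """

    a: float
    b: float
    c: float


def faith_pd(tree: Phylogeny, comm: Iterable[str]) -> float:
    """Rooted Faith's PD: total branch length of the union of root-to-tip
    paths over the community's members.  Empty community -> 0.
    """
    members = set(comm)
    if not members:
        return 0.0
    marked = np.zeros(tree.n_nodes, dtype=bool)
    parent = tree.parent
    for label in members:
        i = tree.tip_node(label)  # raises KeyError naming the label
        while i >= 0 and not marked[i]:
            marked[i] = True
            i = parent[i]
    return float(tree.lengths[marked].sum())


def branch_partition(
    tree: Phylogeny, comm1: Iterable[str], comm2: Iterable[str]
) -> BranchPartition:
    """Decompose a pair of communities into shared / unique branch lengths."""
    c1, c2 = set(comm1), set(comm2)
    if not c1 or not c2:
        raise ValueError("turnover is undefined for an empty community")
    pd1 = faith_pd(tree, c1)
    pd2 = faith_pd(tree, c2)
    pdu = faith_pd(tree, c1 | c2)
    return BranchPartition(a=pd1 + pd2 - pdu, b=pdu - pd2, c=pdu - pd1)


def phylo_simpson(
    tree: Phylogeny, comm1: Iterable[str], comm2: Iterable[str]
) -> float:
    """Phylogenetic Simpson (true turnover): ``min(b,c) / (a + min(b,c))``.

    Symmetric in its community arguments; 0 when one community's branch
    set nests inside the other's.
    """
    part = branch_partition(tree, comm1, comm2)
    m = min(part.b, part.c)
    if m <= 0.0:
        return 0.0
    denom = part.a + m
    if denom <= 0.0:  # degenerate: no shared structure and no turnover
        logger.warning("degenerate community pair with a=0 and min(b,c)=0")
        return 0.0
    return m / denom


def delta_transform(
    tree: Phylogeny, delta: float, preserve_height: bool = True
) -> Phylogeny:
    """Power-transform node depths: depth ``d`` (normalized by tree height)
    becomes ``d**delta``.

    ``delta > 1`` stretches recent branches, ``delta < 1`` stretches deep
    branches; ``delta == 1`` is the identity.  With ``preserve_height``
    (default) the result is rescaled back to the input height.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    h = tree.height
    if h <= 0:
        raise ValueError("tree height must be positive")
    depths = tree.node_depths / h
    new_depths = depths**delta
    if preserve_height:
        new_depths = new_depths * h
    lengths = new_depths - new_depths[tree.parent]
    lengths[0] = 0.0
    if np.any(lengths < -1e-12):  # monotone transform cannot invert depths
        raise AssertionError("delta transform produced a negative branch length")
    return Phylogeny(tree.parent, np.maximum(lengths, 0.0), tree.labels)


def truncate_tree(
    tree: Phylogeny, depth: float
) -> tuple[Phylogeny, dict[str, str]]:
    """Cut the tree at a given depth from the root and collapse every
    branch crossing the cut into a single tip.

    The cut is half-open: a branch from parent depth ``dp`` to child depth
    ``dc`` is crossed iff ``dp <= depth < dc``.  Returns the truncated tree
    and a mapping from every original tip label to the label of the
    collapsed tip whose clade contains it (occurrence columns should be
    OR-ed per mapping group by the caller).
    """
    h = tree.height
    if not 0.0 <= depth < h:
        raise ValueError(f"truncation depth must lie in [0, height={h:g}), got {depth}")
    d = tree.node_depths
    parent = tree.parent
    inc = tree.edge_tip_incidence()
    tip_labels = tree.tips

    new_parent: list[int] = []
    new_lengths: list[float] = []
    new_labels: list[str | None] = []
    index_map: dict[int, int] = {}
    mapping: dict[str, str] = {}
    clade_counter = 0
    for i in range(tree.n_nodes):
        if d[i] <= depth:
            # node survives untouched (its whole edge lies above the cut)
            index_map[i] = len(new_parent)
            new_parent.append(-1 if i == 0 else index_map[parent[i]])
            new_lengths.append(0.0 if i == 0 else float(tree.lengths[i]))
            new_labels.append(tree.labels[i])
            if not tree.children(i):
                mapping[tree.labels[i]] = tree.labels[i]
        elif parent[i] in index_map and d[parent[i]] <= depth:
            # crossed edge: collapse the subtree into a tip at the cut
            group = [tip_labels[j] for j in np.flatnonzero(inc[i])]
            if len(group) == 1:
                label = group[0]
            else:
                clade_counter += 1
                label = f"clade_{clade_counter}"
            for lbl in group:
                mapping[lbl] = label
            new_parent.append(index_map[parent[i]])
            new_lengths.append(float(depth - d[parent[i]]))
            new_labels.append(label)
    truncated = Phylogeny(new_parent, new_lengths, new_labels)
    return truncated, mapping


# -- multi-tree files (one Newick per line) ----------------------------

def read_newick_trees(path) -> list[Phylogeny]:
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(Phylogeny.from_newick(line))
    return trees


def write_newick_trees(trees: Iterable[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")
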