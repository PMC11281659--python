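"""Unrooted and rooted tree structures with deterministic traversal.

The parsimony engine works on :class:`UnrootedTree`, a mutable adjacency
structure over integer node ids with labeled leaves.  Node ids are assigned
in creation order, and edges are enumerated in a canonical DFS preorder, so
tie-breaking by edge index is reproducible.  Rooted trees (the chronology
side) are immutable :class:`RNode` hierarchies.  Newick parsing is delegated
to dendropy; writing is direct (labels always single-quoted, SCOP ids
contain dots).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    pass


class UnrootedTree:
    """Unrooted tree over integer node ids; leaves carry string labels.

    Internal nodes of a binary unrooted tree have degree 3; leaves degree 1.
    """

    def __init__(self):
        self.adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    # -- construction -----------------------------------------------------

    def _new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def _link(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def _unlink(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    @classmethod
    def from_triplet(cls, a: str, b: str, c: str) -> "UnrootedTree":
        t = cls()
        center = t._new_node()
        for lab in (a, b, c):
            leaf = t._new_node(lab)
            t._link(center, leaf)
        return t

    @classmethod
    def from_pair(cls, a: str, b: str) -> "UnrootedTree":
        t = cls()
        na, nb = t._new_node(a), t._new_node(b)
        t._link(na, nb)
        return t

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t.labels = dict(self.labels)
        t._next = self._next
        return t

    # -- queries ----------------------------------------------------------

    @property
    def leaf_ids(self) -> list[int]:
        return sorted(n for n in self.adj if len(self.adj[n]) <= 1)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[n] for n in self.leaf_ids]

    def node_of_label(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label:
                return n
        raise TreeError(f"no leaf labeled {label!r}")

    def is_binary(self) -> bool:
        return all(len(nb) in (1, 3) for nb in self.adj.values())

    def _anchor(self) -> int:
        return min(self.adj)

    def edges(self) -> list[tuple[int, int]]:
        """Edges as (parent, child) in canonical DFS preorder from the anchor."""
        root = self._anchor()
        out: list[tuple[int, int]] = []

        def walk(node: int, parent: int | None):
            for nb in sorted(self.adj[node]):
                if nb != parent:
                    out.append((node, nb))
                    walk(nb, node)

        walk(root, None)
        return out

    def split_of_edge(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the v-side of edge (u, v)."""
        side: set[str] = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node in self.labels:
                side.add(self.labels[node])
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        return frozenset(side)

    def splits(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Canonical bipartitions: each split is the side NOT containing the
        lexicographically smallest leaf label."""
        ref = min(self.leaf_labels)
        out: set[frozenset[str]] = set()
        for u, v in self.edges():
            side = self.split_of_edge(u, v)
            if ref in side:
                side = frozenset(set(self.leaf_labels) - side)
            if not include_trivial and (
                len(side) < 2 or len(side) > len(self.leaf_labels) - 2
            ):
                continue
            if side:
                out.add(side)
        return out

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Hashable identity of the unrooted topology."""
        return frozenset(self.splits(include_trivial=True))

    # -- mutation ---------------------------------------------------------

    def insert_leaf(self, edge: tuple[int, int], label: str) -> int:
        """Insert a new leaf on an edge, creating one internal node."""
        u, v = edge
        self._unlink(u, v)
        w = self._new_node()
        leaf = self._new_node(label)
        self._link(u, w)
        self._link(w, v)
        self._link(w, leaf)
        return leaf

    def attach_node(self, edge: tuple[int, int], node: int) -> int:
        """Attach an existing (detached) node on an edge via a new internal node."""
        u, v = edge
        self._unlink(u, v)
        w = self._new_node()
        self._link(u, w)
        self._link(w, v)
        self._link(w, node)
        return w

    def detach_subtree(self, u: int, v: int) -> None:
        """Cut edge (u, v), keeping the v-side as a detached subtree, and
        suppress the degree-2 node left at u."""
        self._unlink(u, v)
        if len(self.adj[u]) == 2:
            a, b = self.adj[u]
            self._unlink(u, a)
            self._unlink(u, b)
            del self.adj[u]
            self.labels.pop(u, None)
            self._link(a, b)

    # -- newick -----------------------------------------------------------

    def to_newick(self) -> str:
        root = self._anchor()
        if len(self.adj[root]) == 1 and len(self.adj) > 2:
            root = self.adj[root][0]

        def fmt(node: int, parent: int | None) -> str:
            kids = [nb for nb in sorted(self.adj[node]) if nb != parent]
            if not kids:
                return _quote_label(self.labels[node])
            return "(" + ",".join(fmt(k, node) for k in kids) + ")"

        return fmt(root, None) + ";"


def _quote_label(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


@dataclass
class RNode:
    """Node of a rooted tree."""

    label: str | None = None
    children: list["RNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["RNode"]:
        if self.is_leaf:
            return [self]
        out: list[RNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def to_newick(self) -> str:
        def fmt(n: RNode) -> str:
            if n.is_leaf:
                return _quote_label(n.label or "")
            return "(" + ",".join(fmt(c) for c in n.children) + ")"

        return fmt(self) + ";"


def rooted_from_unrooted(tree: UnrootedTree, edge: tuple[int, int]) -> RNode:
    """Root an unrooted tree on an edge: the root gets two children, one per side."""
    u, v = edge

    def build(node: int, parent: int) -> RNode:
        kids = [nb for nb in sorted(tree.adj[node]) if nb != parent]
        if not kids:
            return RNode(label=tree.labels[node])
        return RNode(children=[build(k, node) for k in kids])

    return RNode(children=[build(u, v), build(v, u)])


def rnode_from_newick(text: str) -> RNode:
    dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def conv(nd) -> RNode:
        if nd.is_leaf():
            return RNode(label=nd.taxon.label if nd.taxon else nd.label)
        return RNode(children=[conv(c) for c in nd.child_nodes()])

    return conv(dt.seed_node)


def unrooted_from_newick(text: str) -> UnrootedTree:
    rn = rnode_from_newick(text)
    t = UnrootedTree()

    def build(n: RNode) -> int:
        nid = t._new_node(n.label if n.is_leaf else None)
        for c in n.children:
            cid = build(c)
            t._link(nid, cid)
        return nid

    root = build(rn)
    # suppress a degree-2 root left by a rooted newick
    if len(t.adj[root]) == 2:
        a, b = t.adj[root]
        t._unlink(root, a)
        t._unlink(root, b)
        del t.adj[root]
        t._link(a, b)
    return t


def random_topology(labels: list[str], rng) -> UnrootedTree:
    """Uniform-ish random binary topology by sequential random-edge addition."""
    if len(labels) < 3:
        if len(labels) == 2:
            return UnrootedTree.from_pair(labels[0], labels[1])
        raise TreeError("need >= 2 labels")
    t = UnrootedTree.from_triplet(labels[0], labels[1], labels[2])
    for lab in labels[3:]:
        edges = t.edges()
        e = edges[int(rng.integers(len(edges)))]
        t.insert_leaf(e, lab)
    return t


def enumerate_topologies(labels: list[str]):
    """Yield every unrooted binary topology on the given labels (oracle use)."""
    if len(labels) < 3:
        raise TreeError("need >= 3 labels")
    base = UnrootedTree.from_triplet(labels[0], labels[1], labels[2])
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for e in t.edges():
                t2 = t.copy()
                t2.insert_leaf(e, lab)
                nxt.append(t2)
        trees = nxt
    yield from trees
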