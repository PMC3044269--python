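"""Rooted binary trees, newick I/O, ancestry order and the lca-mapping.

Conventions used throughout the package:

* Nodes carry stable integer ids assigned in **preorder** at construction
  time (root is id 0, children in the left-to-right order they were written).
  Every per-node map in the package is keyed, or indexed, by these ids.
* The ancestry order ``<=`` reads "is a descendant of": ``x <= y`` iff ``y``
  lies on the path from the root to ``x``.  The root is the maximum.
* Species trees attach a branch length ``|s|`` to every non-root node ``s``;
  it is the length of the edge connecting ``s`` to its parent.  An optional
  root branch length may be present (``root:x`` in newick).
* Gene-tree leaves are labelled by species names, repeats allowed; species
  tree leaves are uniquely labelled.  Branch lengths on gene trees, if
  present in the input, are parsed and ignored by the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterator, Sequence

from Bio import Phylo


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree queries."""


@dataclass
class Node:
    id: int
    parent: int | None
    children: tuple[int, ...]
    label: str | None = None
    length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RootedTree:
    """A rooted binary leaf-labelled tree with preorder integer node ids.

    ``kind`` is ``"gene"`` or ``"species"``; species trees additionally carry
    branch lengths and uniquely labelled leaves (enforced by
    :func:`parse_newick`).
    """

    def __init__(self, nodes: Sequence[Node], kind: str = "gene",
                 root_length: float | None = None):
        self.nodes: list[Node] = list(nodes)
        self.kind = kind
        self.root = 0
        #: branch length of the (optional) edge above the root
        self.root_length = root_length
        for i, nd in enumerate(self.nodes):
            if nd.id != i:
                raise TreeError("node ids must be contiguous preorder indices")
        self._depth = [0] * len(self.nodes)
        for nd in self.nodes:
            if nd.parent is not None:
                self._depth[nd.id] = self._depth[nd.parent] + 1
        self._postorder = self._compute_postorder()

    # -- basic structure ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.nodes[v].children)
        order.reverse()
        return order

    def postorder(self) -> list[int]:
        """Node ids, children always before parents."""
        return list(self._postorder)

    def preorder(self) -> list[int]:
        return list(range(len(self.nodes)))

    def children(self, v: int) -> tuple[int, ...]:
        return self.nodes[v].children

    def parent(self, v: int) -> int | None:
        return self.nodes[v].parent

    def is_leaf(self, v: int) -> bool:
        return self.nodes[v].is_leaf

    def label(self, v: int) -> str | None:
        return self.nodes[v].label

    def length(self, v: int) -> float | None:
        """Branch length of the edge above ``v`` (root: ``root_length``)."""
        if v == self.root:
            return self.root_length
        return self.nodes[v].length

    def depth(self, v: int) -> int:
        return self._depth[v]

    def leaves(self) -> list[int]:
        return [nd.id for nd in self.nodes if nd.is_leaf]

    def internal_nodes(self) -> list[int]:
        return [nd.id for nd in self.nodes if not nd.is_leaf]

    def leaf_labels(self) -> list[str]:
        """Labels of leaves, in preorder (with multiplicity)."""
        return [nd.label for nd in self.nodes if nd.is_leaf]  # type: ignore[misc]

    def subtree(self, v: int) -> list[int]:
        """All node ids of the subtree rooted at ``v`` (preorder)."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(self.nodes[u].children))
        return out

    # -- order and lca -----------------------------------------------------

    def is_ancestor_or_self(self, x: int, y: int) -> bool:
        """True iff ``x <= y``, i.e. ``y`` is on the root-to-``x`` path."""
        while self._depth[x] > self._depth[y]:
            x = self.nodes[x].parent  # type: ignore[assignment]
        return x == y

    def path_up(self, x: int, y: int) -> list[int]:
        """Nodes on the path from ``x`` up to ``y`` inclusive (x <= y)."""
        if not self.is_ancestor_or_self(x, y):
            raise TreeError("path_up requires x <= y")
        out = [x]
        while x != y:
            x = self.nodes[x].parent  # type: ignore[assignment]
            out.append(x)
        return out

    def edge_distance(self, x: int, y: int) -> int:
        """Number of edges from ``x`` up to its ancestor ``y``."""
        return len(self.path_up(x, y)) - 1


def lca(tree: RootedTree, nodes) -> int:
    """Least common ancestor: the unique smallest upper bound under ``<=``."""
    it: Iterator[int] = iter(nodes)
    try:
        a = next(it)
    except StopIteration:
        raise TreeError("empty query") from None
    for b in it:
        while a != b:
            if tree.depth(a) >= tree.depth(b):
                a = tree.parent(a)  # type: ignore[assignment]
            else:
                b = tree.parent(b)  # type: ignore[assignment]
    return a


# -- newick ----------------------------------------------------------------


def parse_newick(text: str, kind: str = "gene") -> RootedTree:
    """Parse a newick string into a :class:`RootedTree`.

    ``kind="species"`` additionally requires unique leaf labels and a branch
    length on every non-root node.  Multifurcating (or unary) internal nodes
    are rejected for either kind.  Internal node labels are permitted and
    ignored.
    """
    if kind not in ("gene", "species"):
        raise TreeError(f"unknown tree kind {kind!r}")
    try:
        phylo_tree = Phylo.read(StringIO(text), "newick")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise TreeError(f"malformed newick: {exc}") from exc

    nodes: list[Node] = []

    def build(clade, parent: int | None) -> int:
        nid = len(nodes)
        nodes.append(Node(id=nid, parent=parent, children=(),
                          label=None, length=clade.branch_length))
        kids = list(clade.clades)
        if kids:
            if len(kids) != 2:
                raise TreeError(
                    f"non-binary: internal node with {len(kids)} children")
            child_ids = tuple(build(k, nid) for k in kids)
            nodes[nid].children = child_ids
        else:
            if not clade.name:
                raise TreeError("leaf without label")
            nodes[nid].label = str(clade.name)
        return nid

    build(phylo_tree.root, None)
    root_length = nodes[0].length
    nodes[0].length = None

    if len(nodes) == 1:
        raise TreeError("non-binary: single-node tree")

    if kind == "species":
        labels = [nd.label for nd in nodes if nd.is_leaf]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"label clash: duplicate species labels {dup}")
        for nd in nodes:
            if nd.id != 0 and nd.length is None:
                raise TreeError(f"missing length on node {nd.id}")
            if nd.length is not None and nd.length < 0:
                raise TreeError(f"negative length on node {nd.id}")
    return RootedTree(nodes, kind=kind, root_length=root_length)


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: RootedTree, lengths: bool | None = None) -> str:
    """Serialise to newick; species trees emit branch lengths (6 sig. digits)."""
    if lengths is None:
        lengths = tree.kind == "species"

    def rec(v: int) -> str:
        nd = tree.nodes[v]
        if nd.is_leaf:
            s = nd.label or ""
        else:
            s = "(" + ",".join(rec(c) for c in nd.children) + ")"
        if lengths and v != tree.root and nd.length is not None:
            s += ":" + _fmt_len(nd.length)
        return s

    s = rec(tree.root)
    if lengths and tree.root_length is not None:
        s += ":" + _fmt_len(tree.root_length)
    return s + ";"


# -- lca-mapping -----------------------------------------------------------


def lca_mapping(G: RootedTree, S: RootedTree) -> list[int]:
    """The lca-mapping ``m*``: gene node id -> species node id.

    Each gene node maps to the lca in ``S`` of the species labels of the
    leaves below it; this is the pointwise-minimal valid mapping.  Computed
    in a single postorder pass.
    """
    by_label: dict[str, int] = {}
    for v in S.leaves():
        by_label[S.label(v)] = v  # type: ignore[index]
    m = [0] * len(G)
    for g in G.postorder():
        if G.is_leaf(g):
            lab = G.label(g)
            if lab not in by_label:
                raise TreeError(f"unknown taxon {lab!r} not in species tree")
            m[g] = by_label[lab]
        else:
            c1, c2 = G.children(g)
            m[g] = lca(S, (m[c1], m[c2]))
    return m


def is_lca_speciation(G: RootedTree, mstar: Sequence[int], g: int) -> bool:
    """True iff neither child of ``g`` is lca-mapped to ``mstar[g]``."""
    if G.is_leaf(g):
        raise TreeError("not internal: leaves are neither event")
    return all(mstar[c] != mstar[g] for c in G.children(g))


def lca_speciations(G: RootedTree, mstar: Sequence[int]) -> list[int]:
    """All lca-speciation node ids of ``G``, in preorder."""
    return [g for g in G.internal_nodes() if is_lca_speciation(G, mstar, g)]


def phi(G: RootedTree, S: RootedTree, m: Sequence[int]) -> list[int]:
    """phi(m, s): number of internal gene nodes mapped into ``S(s)``, per s.

    Returns a list indexed by species node id.
    """
    counts = [0] * len(S)
    for g in G.internal_nodes():
        counts[m[g]] += 1
    out = [0] * len(S)
    for s in S.postorder():
        out[s] = counts[s] + sum(out[c] for c in S.children(s))
    return out
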