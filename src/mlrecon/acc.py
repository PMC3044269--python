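"""Dual/free subtree decomposition, SeqPair, and acceptable-triplet queries.

At a species node ``s`` with children ``s1, s2``, the maximal gene subtrees
lca-mapped into ``S(s1)`` or ``S(s2)`` decompose into *dual pairs* — the two
child subtrees of each lca-speciation mapped to ``s`` — and *free* trees.
A triplet ``<sigma, k1, k2>`` is *acceptable* if some reconciliation has
exactly ``sigma`` speciations at ``s`` and ``k_j`` internal gene nodes
mapped into ``S(s_j)``.  Keeping a speciation forces both trees of its dual
pair below ``s``, so the largest feasible ``sigma`` given side budgets
``(k1, k2)`` is a two-budget longest-subsequence problem (*SeqPair*) over
the dual pairs' internal-node counts; all other nodes may be raised freely,
so acceptability is otherwise only bounded by the side totals and is
downward-closed in ``sigma``.

One knapsack-style table per node answers all budget queries; the
constrained variant (raised/locked node sets, used by the constrained
dynamic program) reuses the same machinery on a modified decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import RootedTree, TreeError, lca_mapping, lca_speciations

NEG_INF = float("-inf")


# -- SeqPair ---------------------------------------------------------------


@dataclass(frozen=True)
class SeqPairInstance:
    """Budgets ``(alpha, beta)`` and a sequence of non-negative count pairs."""

    alpha: int
    beta: int
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("invalid budgets")
        if any(a < 0 or b < 0 for a, b in self.pairs):
            raise ValueError("invalid budgets: pair entries must be >= 0")


class SeqPairTable:
    """Precomputed DP table answering every SeqPair budget query in O(1).

    ``query(a, b)`` returns the length of the longest subsequence of the
    pair sequence whose first components sum to at most ``a`` and second
    components to at most ``b``.  Budgets beyond the total sums saturate.
    """

    def __init__(self, pairs):
        self.pairs = tuple((int(a), int(b)) for a, b in pairs)
        A = sum(a for a, _ in self.pairs)
        B = sum(b for _, b in self.pairs)
        self.A, self.B = A, B
        T = np.zeros((A + 1, B + 1), dtype=np.int16)
        for a, b in self.pairs:
            shifted = np.full_like(T, -1)
            shifted[a:, b:] = T[:T.shape[0] - a, :T.shape[1] - b] + 1
            np.maximum(T, shifted, out=T)
        self.T = T

    def query(self, a: int, b: int) -> int:
        if a < 0 or b < 0:
            raise ValueError("invalid budgets")
        return int(self.T[min(a, self.A), min(b, self.B)])

    def query_grid(self, a_budgets: np.ndarray, b_budgets: np.ndarray) -> np.ndarray:
        """Vectorized: sigma* for the outer grid of two budget vectors."""
        ai = np.clip(a_budgets, None, self.A)
        bi = np.clip(b_budgets, None, self.B)
        ok = (ai[:, None] >= 0) & (bi[None, :] >= 0)
        out = np.full((len(ai), len(bi)), -1, dtype=np.int16)
        out[ok] = self.T[np.maximum(ai, 0)[:, None],
                         np.maximum(bi, 0)[None, :]][ok]
        return out


def seqpair_solve(inst: SeqPairInstance) -> int:
    """Longest subsequence of ``inst.pairs`` within the two budgets."""
    return SeqPairTable(inst.pairs).query(inst.alpha, inst.beta)


# -- decomposition ---------------------------------------------------------


@dataclass
class DualPair:
    spec_node: int          # the lca-speciation mapped to s
    root1: int              # root of the s1-side subtree
    root2: int              # root of the s2-side subtree
    count1: int             # internal gene nodes in the s1-side subtree
    count2: int


@dataclass
class FreeTree:
    root: int
    side: int               # 1 or 2
    count: int


@dataclass
class DualFreeDecomposition:
    """Per-species-node dual pairs and free trees with internal-node counts."""

    s: int
    s1: int
    s2: int
    pairs: list[DualPair]
    free: list[FreeTree]

    @property
    def n1_free(self) -> int:
        return sum(t.count for t in self.free if t.side == 1)

    @property
    def n2_free(self) -> int:
        return sum(t.count for t in self.free if t.side == 2)

    @property
    def n1(self) -> int:
        return sum(p.count1 for p in self.pairs) + self.n1_free

    @property
    def n2(self) -> int:
        return sum(p.count2 for p in self.pairs) + self.n2_free


def _internal_count(G: RootedTree, root: int) -> int:
    return sum(1 for v in G.subtree(root) if not G.is_leaf(v))


def decompose(G: RootedTree, S: RootedTree, s: int,
              mstar=None) -> DualFreeDecomposition:
    """Dual/free decomposition of ``G_s`` at internal species node ``s``.

    Subtree roots are visited in preorder, so ordering is deterministic.
    """
    if S.is_leaf(s):
        raise TreeError("leaf has no children")
    if mstar is None:
        mstar = lca_mapping(G, S)
    s1, s2 = S.children(s)

    def side_of(x: int) -> int:
        if S.is_ancestor_or_self(x, s1):
            return 1
        if S.is_ancestor_or_self(x, s2):
            return 2
        return 0

    # dual pairs: child subtrees of lca-speciations mapped to s, in preorder
    pairs: list[DualPair] = []
    dual_roots: set[int] = set()
    for g in sorted(lca_speciations(G, mstar)):
        if mstar[g] != s:
            continue
        c1, c2 = G.children(g)
        if side_of(mstar[c1]) == 1:
            r1, r2 = c1, c2
        else:
            r1, r2 = c2, c1
        pairs.append(DualPair(spec_node=g, root1=r1, root2=r2,
                              count1=_internal_count(G, r1),
                              count2=_internal_count(G, r2)))
        dual_roots.update((r1, r2))

    # maximal subtrees lca-mapped into a side whose parent is not
    free: list[FreeTree] = []
    for v in range(len(G)):
        side = side_of(mstar[v])
        if side == 0 or v in dual_roots:
            continue
        p = G.parent(v)
        if p is not None and side_of(mstar[p]) != 0:
            continue  # not maximal
        free.append(FreeTree(root=v, side=side, count=_internal_count(G, v)))
    return DualFreeDecomposition(s=s, s1=s1, s2=s2, pairs=pairs, free=free)


# -- unconstrained Acc queries --------------------------------------------


class AccTables:
    """Per-species-node decompositions and SeqPair tables, built lazily."""

    def __init__(self, G: RootedTree, S: RootedTree, mstar=None):
        self.G, self.S = G, S
        self.mstar = list(mstar) if mstar is not None else lca_mapping(G, S)
        self._dec: dict[int, DualFreeDecomposition] = {}
        self._tab: dict[int, SeqPairTable] = {}

    def decomposition(self, s: int) -> DualFreeDecomposition:
        if s not in self._dec:
            self._dec[s] = decompose(self.G, self.S, s, self.mstar)
        return self._dec[s]

    def table(self, s: int) -> SeqPairTable:
        if s not in self._tab:
            dec = self.decomposition(s)
            self._tab[s] = SeqPairTable([(p.count1, p.count2)
                                         for p in dec.pairs])
        return self._tab[s]


def acc_query(G: RootedTree, S: RootedTree, s: int, k1: int, k2: int,
              tables: AccTables | None = None) -> int | None:
    """Maximum acceptable ``sigma`` at ``s`` for side counts ``(k1, k2)``.

    Returns ``None`` when no triplet with these side counts is acceptable
    (a side count exceeds the side total).  Acceptable sets are downward
    closed in ``sigma``, so ``<sigma, k1, k2>`` is acceptable iff
    ``0 <= sigma <= acc_query(...)``.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("invalid: side counts must be >= 0")
    if tables is None:
        tables = AccTables(G, S)
    dec = tables.decomposition(s)
    if k1 > dec.n1 or k2 > dec.n2:
        return None
    return tables.table(s).query(k1, k2)


def acc_set(G: RootedTree, S: RootedTree, s: int,
            tables: AccTables | None = None) -> set[tuple[int, int, int]]:
    """The full acceptable-triplet set at ``s`` (small trees only)."""
    if tables is None:
        tables = AccTables(G, S)
    dec = tables.decomposition(s)
    out = set()
    for k1 in range(dec.n1 + 1):
        for k2 in range(dec.n2 + 1):
            smax = acc_query(G, S, s, k1, k2, tables)
            if smax is None:
                continue
            for sg in range(smax + 1):
                out.add((sg, k1, k2))
    return out


# -- constrained Acc queries ----------------------------------------------


@dataclass
class ConstrainedDecomposition:
    """Acc inputs at ``s`` under raised (F) and locked (L) node sets.

    Relative to the unconstrained decomposition: dual pairs of locked
    speciations at ``s`` are removed and their subtree nodes become forced
    side contributions; dual pairs of raised lca-speciations become free
    trees; nodes forced below by locked constraints (side-blocked nodes)
    are excluded from every optional tree and accumulated in ``forced1`` /
    ``forced2``.
    """

    s: int
    locked_sigma: int                     # speciations at s forced by L
    forced1: int                          # internal nodes forced into S(s1)
    forced2: int
    opt_pairs: tuple[tuple[int, int], ...]  # optional dual-pair counts
    n1_opt: int                           # optional side totals
    n2_opt: int
    table: SeqPairTable = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.table is None:
            self.table = SeqPairTable(self.opt_pairs)


def constrained_decomposition(tables: AccTables, s: int,
                              F: frozenset[int], L: frozenset[int],
                              ) -> ConstrainedDecomposition:
    G, S = tables.G, tables.S
    mstar = tables.mstar
    dec = tables.decomposition(s)
    s1, s2 = dec.s1, dec.s2

    # internal nodes forced into S(s_j): subtrees of locked nodes lca-mapped
    # into S(s_j), plus the side-j child subtrees of locked speciations at s
    forced: tuple[set[int], set[int]] = (set(), set())
    for g in L:
        for j, sj in ((0, s1), (1, s2)):
            if S.is_ancestor_or_self(mstar[g], sj):
                forced[j].update(v for v in G.subtree(g) if not G.is_leaf(v))
    locked_sigma = 0
    for p in dec.pairs:
        if p.spec_node in L:
            locked_sigma += 1
            forced[0].update(v for v in G.subtree(p.root1) if not G.is_leaf(v))
            forced[1].update(v for v in G.subtree(p.root2) if not G.is_leaf(v))

    def opt_count(root: int, j: int) -> int:
        return sum(1 for v in G.subtree(root)
                   if not G.is_leaf(v) and v not in forced[j])

    opt_pairs = []
    n1_opt = n2_opt = 0
    for p in dec.pairs:
        if p.spec_node in L:
            continue
        a = opt_count(p.root1, 0)
        b = opt_count(p.root2, 1)
        if p.spec_node in F:
            # raised: the pair's trees become free
            n1_opt += a
            n2_opt += b
        else:
            opt_pairs.append((a, b))
            n1_opt += a
            n2_opt += b
    for t in dec.free:
        j = t.side - 1
        c = opt_count(t.root, j)
        if t.side == 1:
            n1_opt += c
        else:
            n2_opt += c

    return ConstrainedDecomposition(
        s=s, locked_sigma=locked_sigma,
        forced1=len(forced[0]), forced2=len(forced[1]),
        opt_pairs=tuple(opt_pairs), n1_opt=n1_opt, n2_opt=n2_opt)


def acc_query_constrained(G: RootedTree, S: RootedTree, s: int,
                          k1: int, k2: int,
                          F: frozenset[int] = frozenset(),
                          L: frozenset[int] = frozenset(),
                          tables: AccTables | None = None,
                          cdec: ConstrainedDecomposition | None = None,
                          ) -> int | None:
    """Maximum acceptable ``sigma`` at ``s`` within ``Rec(F, L)``.

    With empty constraint sets this coincides with :func:`acc_query`.  The
    caller is responsible for ``L`` being closed (the dynamic program closes
    it); an unclosed ``L`` raises.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("invalid: side counts must be >= 0")
    if tables is None:
        tables = AccTables(G, S)
    if cdec is None:
        from .dp import closure  # local import to avoid a cycle
        if closure(G, S, L, tables.mstar) != frozenset(L):
            raise TreeError("constraint not closed")
        cdec = constrained_decomposition(tables, s, frozenset(F), frozenset(L))
    b1 = k1 - cdec.forced1
    b2 = k2 - cdec.forced2
    if b1 < 0 or b2 < 0 or b1 > cdec.n1_opt or b2 > cdec.n2_opt:
        return None
    return cdec.locked_sigma + cdec.table.query(b1, b2)
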