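"""The maximum-likelihood dynamic program, plain and constrained.

``M(s, kappa)`` is the best log-likelihood contribution of the part of an
embedding that lies inside ``S(s)`` when exactly ``kappa`` internal gene
nodes (duplications and speciations) are placed there.  At a leaf this is
the probability of ``kappa`` duplications on the leaf branch; at an internal
node it maximizes over acceptable triplets ``<sigma, k1, k2>`` and
duplication counts ``delta`` with ``kappa = k1 + k2 + sigma + delta``:

    M(s, kappa) = max  log p(s, delta) + M(s1, k1) + M(s2, k2)

The value at ``(root, |L(G)| - 1)`` is an upper bound on the optimal
reconciliation log-likelihood and is exact whenever one of the DS settings
reconstructed from the table's argmax tuples is realizable (validated by
:mod:`mlrecon.dsr`); instances where none validates are the *hard* ones.

The constrained variant restricts the search to ``Rec(F, L)`` — raised
lca-speciations (``F``) are forced to be duplications, locked nodes (``L``)
keep their lca mapping and lca event status — by shrinking the per-node
``kappa``/``sigma``/``delta`` ranges and querying the constrained acceptable
sets.  ``L`` is closed under two propagation rules before use (see
:func:`closure`).

All arithmetic is in log space; ``-inf`` encodes impossible states.  Ties
in the maximum are detected at relative tolerance 1e-9 and all tying argmax
tuples are kept, ordered by ``(delta, sigma, k1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acc import (
    AccTables,
    ConstrainedDecomposition,
    constrained_decomposition,
)
from .phylo import RootedTree, TreeError, lca_speciations, phi
from .recon import DSSetting, branch_lengths

NEG_INF = float("-inf")
TIE_RTOL = 1e-9


# -- constraints -----------------------------------------------------------


def closure(G: RootedTree, S: RootedTree, L, mstar=None) -> frozenset[int]:
    """Minimal superset of ``L`` closed under the locking propagation rules.

    (i) a non-lca-speciation child of a locked lca-speciation is locked when
    its lca image is a species-child of the parent's (its mapping interval
    degenerates to a point); (ii) an lca-speciation child of a locked
    duplication is locked; (iii) a non-lca-speciation child of a locked
    duplication sharing the parent's lca image is locked (its mapping
    interval is the same single point — the same forcing as rule (i), and
    without it the constrained table undercounts forced duplications on
    chains of equal-image duplications).  Idempotent.
    """
    if mstar is None:
        from .phylo import lca_mapping
        mstar = lca_mapping(G, S)
    sigma_star = set(lca_speciations(G, mstar))
    closed = set(L)
    for g in closed:
        if G.is_leaf(g):
            raise TreeError("locked nodes must be internal")
    work = list(closed)
    while work:
        g = work.pop()
        for c in G.children(g):
            if G.is_leaf(c) or c in closed:
                continue
            if g in sigma_star:
                if c not in sigma_star and S.parent(mstar[c]) == mstar[g]:
                    closed.add(c)
                    work.append(c)
            else:
                if c in sigma_star or mstar[c] == mstar[g]:
                    closed.add(c)
                    work.append(c)
    return frozenset(closed)


@dataclass(frozen=True)
class Constraint:
    """Raised (``F``) and locked (``L``) internal gene nodes.

    Build through :meth:`make`, which closes ``L`` and rejects inconsistent
    sets (a raised node may not be a locked lca-speciation; raised nodes
    must be lca-speciations).
    """

    F: frozenset[int]
    L: frozenset[int]

    @classmethod
    def make(cls, G: RootedTree, S: RootedTree, F=(), L=(),
             mstar=None) -> "Constraint":
        if mstar is None:
            from .phylo import lca_mapping
            mstar = lca_mapping(G, S)
        sigma_star = set(lca_speciations(G, mstar))
        F = frozenset(F)
        if not F <= sigma_star:
            raise TreeError("raised nodes must be lca-speciations")
        Lc = closure(G, S, L, mstar)
        if F & Lc & sigma_star:
            raise TreeError("contradiction: node both raised and locked speciation")
        return cls(F=F, L=Lc)

    @property
    def empty(self) -> bool:
        return not self.F and not self.L


EMPTY_CONSTRAINT = Constraint(F=frozenset(), L=frozenset())


# -- the table -------------------------------------------------------------


@dataclass
class _NodeMeta:
    cdec: ConstrainedDecomposition | None  # None for leaves
    sigma_min: int
    sigma_max: int
    delta_min: int
    blocked: int


class DPTable:
    """Memoized ``M(s, kappa)`` vectors plus everything needed to backtrace.

    ``M[s]`` is a dense vector over ``kappa = 0 .. phi(m*, s)``; values are
    log-probabilities, ``-inf`` marks impossible states.  Argmax tuples
    ``(delta, sigma, k1, k2)`` are recomputed on demand from the children's
    vectors and cached, so the table stays O(|S| * |G|) in memory.
    """

    def __init__(self, G: RootedTree, S: RootedTree, model,
                 constraint: Constraint, root_length: float | None = None):
        self.G, self.S, self.model = G, S, model
        self.constraint = constraint
        self.tables = AccTables(G, S)
        self.mstar = self.tables.mstar
        self.phi = phi(G, S, self.mstar)
        self.lens = branch_lengths(S, root_length)
        self.sigma_star = set(lca_speciations(G, self.mstar))
        self.M: dict[int, np.ndarray] = {}
        self.meta: dict[int, _NodeMeta] = {}
        self._argmax_cache: dict[tuple[int, int], list] = {}
        self._blocked = self._blocked_counts()
        self._run()

    # number of internal gene nodes forced into S(s) by locked subtrees
    def _blocked_counts(self) -> list[int]:
        G, S, L = self.G, self.S, self.constraint.L
        cnt = [0] * len(S)
        if L:
            stack = [(self.G.root, None)]
            while stack:
                g, anchor = stack.pop()
                if g in L:
                    anchor = self.mstar[g]
                if not G.is_leaf(g):
                    if anchor is not None:
                        cnt[anchor] += 1
                    for c in G.children(g):
                        stack.append((c, anchor))
        out = [0] * len(S)
        for s in S.postorder():
            out[s] = cnt[s] + sum(out[c] for c in S.children(s))
        return out

    def _log_pmf_vec(self, s: int, n: int) -> np.ndarray:
        tau = self.lens[s]
        if tau is None:  # edge-less root: duplications carry no cost
            return np.zeros(n + 1)
        return np.array([self.model.log_pmf(tau, d) for d in range(n + 1)])

    def _node_cdec(self, s: int) -> ConstrainedDecomposition:
        c = self.constraint
        if c.empty:
            dec = self.tables.decomposition(s)
            return ConstrainedDecomposition(
                s=s, locked_sigma=0, forced1=0, forced2=0,
                opt_pairs=tuple((p.count1, p.count2) for p in dec.pairs),
                n1_opt=dec.n1, n2_opt=dec.n2, table=self.tables.table(s))
        return constrained_decomposition(self.tables, s, c.F, c.L)

    def _sigma_grid(self, s: int, n1: int, n2: int) -> np.ndarray:
        """Per-(k1,k2) maximum acceptable sigma; -1 marks infeasible cells."""
        meta = self.meta[s]
        cdec = meta.cdec
        assert cdec is not None
        b1 = np.arange(n1 + 1) - cdec.forced1
        b2 = np.arange(n2 + 1) - cdec.forced2
        q = cdec.table.query_grid(b1, b2).astype(np.int32)
        grid = np.where(q >= 0, cdec.locked_sigma + q, -1)
        grid[b1 > cdec.n1_opt, :] = -1
        grid[:, b2 > cdec.n2_opt] = -1
        return np.minimum(grid, meta.sigma_max)

    def _run(self) -> None:
        G, S = self.G, self.S
        c = self.constraint
        locked_at = {s: [] for s in range(len(S))}
        for g in c.L:
            locked_at[self.mstar[g]].append(g)
        raised_at: dict[int, int] = {s: 0 for s in range(len(S))}
        for g in c.F:
            raised_at[self.mstar[g]] += 1
        spec_star = [0] * len(S)
        for g in self.sigma_star:
            spec_star[self.mstar[g]] += 1

        for s in S.postorder():
            n = self.phi[s]
            blocked = self._blocked[s]
            if S.is_leaf(s):
                M = self._log_pmf_vec(s, n)
                M[:blocked] = NEG_INF
                self.M[s] = M
                self.meta[s] = _NodeMeta(cdec=None, sigma_min=0, sigma_max=0,
                                         delta_min=0, blocked=blocked)
                continue
            cdec = self._node_cdec(s)
            sigma_min = cdec.locked_sigma
            sigma_max = spec_star[s] - raised_at[s]
            delta_min = sum(1 for g in locked_at[s] if g not in self.sigma_star)
            self.meta[s] = _NodeMeta(cdec=cdec, sigma_min=sigma_min,
                                     sigma_max=sigma_max, delta_min=delta_min,
                                     blocked=blocked)
            s1, s2 = S.children(s)
            M1, M2 = self.M[s1], self.M[s2]
            n1, n2 = len(M1) - 1, len(M2) - 1
            C = M1[:, None] + M2[None, :]
            grid = self._sigma_grid(s, n1, n2)
            B = np.full(n1 + n2 + sigma_max + 1, NEG_INF)
            for sg in range(sigma_min, sigma_max + 1):
                Cm = np.where(grid >= sg, C, NEG_INF)
                D = _diag_max(Cm)
                B[sg:sg + len(D)] = np.maximum(B[sg:sg + len(D)], D)
            logp = self._log_pmf_vec(s, n)
            M = np.full(n + 1, NEG_INF)
            for d in range(delta_min, n + 1):
                if logp[d] == NEG_INF:
                    continue
                hi = min(n, d + len(B) - 1)
                if hi < d:
                    continue
                seg = logp[d] + B[:hi - d + 1]
                np.maximum(M[d:hi + 1], seg, out=M[d:hi + 1])
            M[:blocked] = NEG_INF
            self.M[s] = M

    @property
    def value(self) -> float:
        return float(self.M[self.S.root][self.phi[self.S.root]])

    # -- backtrace --------------------------------------------------------

    def argmax_tuples(self, s: int, kappa: int) -> list[tuple[int, int, int, int]]:
        """All ``(delta, sigma, k1, k2)`` achieving ``M(s, kappa)``.

        Ties are detected at relative tolerance 1e-9 and returned in
        ascending ``(delta, sigma, k1)`` order.  Empty for leaves.
        """
        key = (s, kappa)
        if key in self._argmax_cache:
            return self._argmax_cache[key]
        S = self.S
        out: list[tuple[int, int, int, int]] = []
        if not S.is_leaf(s):
            target = self.M[s][kappa]
            if target > NEG_INF:
                meta = self.meta[s]
                s1, s2 = S.children(s)
                M1, M2 = self.M[s1], self.M[s2]
                n1, n2 = len(M1) - 1, len(M2) - 1
                C = M1[:, None] + M2[None, :]
                grid = self._sigma_grid(s, n1, n2)
                logp = self._log_pmf_vec(s, self.phi[s])
                tol = TIE_RTOL * max(1.0, abs(target))
                for d in range(meta.delta_min, kappa + 1):
                    if logp[d] == NEG_INF:
                        continue
                    want = target - logp[d]
                    for sg in range(meta.sigma_min, meta.sigma_max + 1):
                        u = kappa - d - sg
                        if u < 0 or u > n1 + n2:
                            continue
                        k1_lo = max(0, u - n2)
                        k1_hi = min(n1, u)
                        for k1 in range(k1_lo, k1_hi + 1):
                            k2 = u - k1
                            if grid[k1, k2] < sg:
                                continue
                            if abs(C[k1, k2] - want) <= tol:
                                out.append((d, sg, k1, k2))
                out.sort()
        self._argmax_cache[key] = out
        return out


def _diag_max(C: np.ndarray) -> np.ndarray:
    """``D[u] = max over k1 + k2 = u of C[k1, k2]`` for a 2-D array."""
    n1, n2 = C.shape
    Z = np.full((n1, n1 + n2 - 1), NEG_INF)
    for i in range(n1):
        Z[i, i:i + n2] = C[i]
    return Z.max(axis=0)


# -- entry points ----------------------------------------------------------


def dp1(G: RootedTree, S: RootedTree, model,
        root_length: float | None = None) -> tuple[float, DPTable]:
    """Unconstrained DP: upper bound on the optimal log-likelihood."""
    table = DPTable(G, S, model, EMPTY_CONSTRAINT, root_length)
    return table.value, table


def dp2(G: RootedTree, S: RootedTree, model, constraint: Constraint,
        root_length: float | None = None) -> tuple[float, DPTable]:
    """Constrained DP over ``Rec(F, L)``; with empty sets equals :func:`dp1`."""
    table = DPTable(G, S, model, constraint, root_length)
    return table.value, table


def backtrace_settings(table: DPTable, cap: int = 10_000) -> list[DSSetting]:
    """DS settings achieving the DP optimum, deterministically ordered.

    Combines argmax tuples top-down (``dup(s) = delta``, ``spec(s) = sigma``
    at internal nodes; ``dup = kappa`` at leaves), truncating the expansion
    at ``cap`` distinct settings.
    """
    return list(iter_settings(table, cap))


def iter_settings(table: DPTable, cap: int = 10_000):
    """Lazy version of :func:`backtrace_settings`."""
    if cap <= 0:
        raise ValueError("empty request: cap must be >= 1")
    S = table.S
    if table.value == NEG_INF:
        return

    def gen(s: int, kappa: int):
        if S.is_leaf(s):
            yield ((s, kappa, 0),)
            return
        s1, s2 = S.children(s)
        for (d, sg, k1, k2) in table.argmax_tuples(s, kappa):
            for left in gen(s1, k1):
                for right in gen(s2, k2):
                    yield left + right + ((s, d, sg),)

    seen: set[DSSetting] = set()
    for combo in gen(S.root, table.phi[S.root]):
        dup = [0] * len(S)
        spec = [0] * len(S)
        for s, d, sg in combo:
            dup[s] = d
            spec[s] = sg
        st = DSSetting(dup=tuple(dup), spec=tuple(spec))
        if st in seen:
            continue
        seen.add(st)
        yield st
        if len(seen) >= cap:
            return
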