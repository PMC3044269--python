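"""End-to-end maximum-likelihood solve, branch-and-bound, parsimony rooting.

The pipeline: run the unconstrained dynamic program, backtrace candidate DS
settings from its table, and validate them.  If any setting is realizable
the DP value is exact and a witness reconciliation is returned.  Otherwise
the instance is *hard*: the true optimum is found by branch-and-bound over
the undecided lca-speciations, each branching step either forcing one to be
a duplication (raised) or pinning it as a speciation (locked, with closure),
and solving the constrained DP with validation in each branch.

``root_by_parsimony`` is the rooting utility: evaluate every edge of an
unrooted gene tree as a root position and keep the rootings minimizing the
lca-reconciliation duplication count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .acc import NEG_INF
from .dp import Constraint, DPTable, EMPTY_CONSTRAINT, dp2, iter_settings
from .dsr import validate_setting
from .phylo import (
    Node,
    RootedTree,
    TreeError,
    lca_mapping,
    lca_speciations,
)
from .recon import (
    DSSetting,
    PoissonModel,
    Reconciliation,
    setting_of,
)


class SolverExhausted(RuntimeError):
    """Branch-and-bound dead-end enumeration exceeded its cap."""


@dataclass
class SolveResult:
    log_likelihood: float
    settings: list[DSSetting]
    reconciliation: Reconciliation | None
    hard: bool
    n_settings_checked: int = 0
    bb_steps: int = 0
    dp_ms: float = 0.0           # dynamic program + validation time
    bb_ms: float = 0.0           # branch-and-bound time (hard instances)


def _validate_in_space(G, S, setting: DSSetting, constraint: Constraint,
                       sigma_star: frozenset[int]) -> Reconciliation | None:
    required = frozenset(constraint.L & sigma_star)
    forbidden = frozenset(constraint.F)
    mstar = lca_mapping(G, S)
    fixed = {g: mstar[g] for g in constraint.L if g not in sigma_star}
    return validate_setting(G, S, setting, required=required,
                            forbidden=forbidden, fixed=fixed)


def mle_solve(G: RootedTree, S: RootedTree, model=None, rate: float = 0.005,
              root_length: float | None = None, all_settings: bool = False,
              setting_cap: int = 10_000,
              enum_cap: int = 2_000_000) -> SolveResult:
    """Maximum-likelihood reconciliation of ``(G, S)``.

    Returns the optimal log-likelihood, the optimal DS setting(s), one
    witness reconciliation, and whether the instance was hard (solved by
    branch-and-bound rather than certified directly from the DP).

    Parameters
    ----------
    model : duplication-count model; defaults to ``PoissonModel(rate)``.
    rate : duplication rate used when ``model`` is None.
    root_length : optional branch length for the species-tree root; when
        neither this nor a root length in the newick is given, the root has
        no edge and its duplications carry no probability factor.
    all_settings : also collect every validated optimal setting (up to
        ``setting_cap``), not just the first.
    setting_cap : maximum number of backtraced settings examined before the
        instance is declared unresolved by the DP and passed to
        branch-and-bound.
    """
    import time

    if model is None:
        model = PoissonModel(rate)
    t0 = time.perf_counter()
    table = DPTable(G, S, model, EMPTY_CONSTRAINT, root_length)
    value = table.value
    sigma_star = frozenset(lca_speciations(G, table.mstar))

    checked = 0
    witness: Reconciliation | None = None
    good: list[DSSetting] = []
    for st in iter_settings(table, cap=setting_cap):
        checked += 1
        R = validate_setting(G, S, st)
        if R is not None:
            good.append(st)
            if witness is None:
                witness = R
            if not all_settings:
                break
    dp_ms = (time.perf_counter() - t0) * 1000.0
    if witness is not None:
        return SolveResult(log_likelihood=value, settings=good,
                           reconciliation=witness, hard=False,
                           n_settings_checked=checked, dp_ms=dp_ms)

    t1 = time.perf_counter()
    bb_value, bb_recon, steps = _branch_and_bound(
        G, S, model, EMPTY_CONSTRAINT, root_length, sigma_star,
        setting_cap=max(100, setting_cap // 10), enum_cap=enum_cap)
    settings = [setting_of(bb_recon)] if bb_recon is not None else []
    return SolveResult(log_likelihood=bb_value, settings=settings,
                       reconciliation=bb_recon, hard=True,
                       n_settings_checked=checked, bb_steps=steps,
                       dp_ms=dp_ms,
                       bb_ms=(time.perf_counter() - t1) * 1000.0)


def branch_and_bound(G: RootedTree, S: RootedTree, model,
                     F=(), L=(), root_length: float | None = None,
                     enum_cap: int = 2_000_000,
                     ) -> tuple[float, Reconciliation | None]:
    """Exact constrained optimum over ``Rec(F, L)`` (closure applied)."""
    mstar = lca_mapping(G, S)
    sigma_star = frozenset(lca_speciations(G, mstar))
    c = Constraint.make(G, S, F, L, mstar)
    v, r, _ = _branch_and_bound(G, S, model, c, root_length, sigma_star,
                                setting_cap=1000, enum_cap=enum_cap)
    return v, r


def _ext_dp(G, S, model, constraint, root_length, sigma_star, setting_cap):
    """Constrained DP plus validation.

    Returns ``(upper_bound, witness or None)``; a witness certifies the
    bound is attained inside the constrained space (the resolving case).
    """
    value, table = dp2(G, S, model, constraint, root_length)
    if value == NEG_INF:
        return NEG_INF, None
    for st in iter_settings(table, cap=setting_cap):
        R = _validate_in_space(G, S, st, constraint, sigma_star)
        if R is not None:
            return value, R
    return value, None


def _branching_candidates(G, S, mstar, sigma_star, constraint):
    undecided = [g for g in sorted(sigma_star)
                 if g not in constraint.F and g not in constraint.L]
    # deepest species image first, ties by preorder id
    undecided.sort(key=lambda g: (-S.depth(mstar[g]), g))
    return undecided


def _branch_and_bound(G, S, model, constraint, root_length, sigma_star,
                      setting_cap, enum_cap):
    mstar = lca_mapping(G, S)
    steps = 0

    def rec(c: Constraint, best: float):
        nonlocal steps
        steps += 1
        value, witness = _ext_dp(G, S, model, c, root_length, sigma_star,
                                 setting_cap)
        if witness is not None or value == NEG_INF:
            return value, witness
        if value <= best:
            # upper bound cannot beat an already-certified optimum
            return NEG_INF, None
        cands = _branching_candidates(G, S, mstar, sigma_star, c)
        if not cands:
            return _enumerate_rec_space(G, S, model, c, root_length,
                                        sigma_star, enum_cap)
        g = cands[0]
        out_v, out_r = NEG_INF, None
        branches = []
        try:
            branches.append(Constraint.make(G, S, c.F | {g}, c.L, mstar))
        except TreeError:
            pass
        try:
            branches.append(Constraint.make(G, S, c.F, c.L | {g}, mstar))
        except TreeError:
            pass
        for b in branches:
            v, r = rec(b, max(best, out_v))
            if r is not None and v > out_v:
                out_v, out_r = v, r
        return out_v, out_r

    v, r = rec(constraint, NEG_INF)
    return v, r, steps


def _enumerate_rec_space(G, S, model, constraint, root_length, sigma_star,
                         enum_cap):
    """Dead-end exact solve: every lca-speciation status is decided.

    With the speciation set fixed, each remaining duplication ``g`` may sit
    anywhere on the species path from its lca image up to its cap (the
    side-child of the nearest kept-speciation ancestor; a single pinned node
    for locked duplications), and the gene-tree monotonicity constraint does
    not further restrict the achievable per-node count vectors: any
    violating pair along a root path can be swapped without changing counts.
    Maximizing the likelihood therefore reduces to assigning duplications to
    per-node "k-th duplication" slots whose rewards are the (concave, hence
    decreasing) marginal log-probability gains — a rectangular assignment
    problem solved exactly.
    """
    from scipy.optimize import linear_sum_assignment

    from .recon import branch_lengths, log_pmf_at
    from .dsr import _dup_caps, allocate_duplications

    mstar = lca_mapping(G, S)
    sigma = frozenset(constraint.L & sigma_star)
    fixed = {g: mstar[g] for g in constraint.L if g not in sigma_star}
    lens = branch_lengths(S, root_length)
    base = sum(log_pmf_at(model, lens, s, 0) for s in range(len(S)))

    D = [g for g in G.postorder() if not G.is_leaf(g) and g not in sigma]
    if not D:
        R = Reconciliation(G=G, S=S, m=tuple(mstar), sigma=sigma)
        return base, R
    caps = _dup_caps(G, S, mstar, sigma)
    paths = []
    for g in D:
        if g in fixed:
            paths.append([fixed[g]])
        elif S.is_ancestor_or_self(mstar[g], caps[g]):
            paths.append(S.path_up(mstar[g], caps[g]))
        else:
            paths.append([])
    if any(not p for p in paths):
        return NEG_INF, None

    # per-node slots: reward of the k-th duplication at s is the marginal
    # log-probability gain, decreasing in k by concavity of the count pmf
    slot_node: list[int] = []
    slot_cost: list[float] = []
    slots_of: dict[int, list[int]] = {}
    need_nodes = sorted({s for p in paths for s in p})
    for s in need_nodes:
        mx = sum(1 for p in paths if s in p)
        prev = log_pmf_at(model, lens, s, 0)
        for k in range(1, mx + 1):
            cur = log_pmf_at(model, lens, s, k)
            slots_of.setdefault(s, []).append(len(slot_node))
            slot_node.append(s)
            slot_cost.append(-(cur - prev))
            prev = cur

    import numpy as np
    cost = np.full((len(D), len(slot_node)), np.inf)
    for i, p in enumerate(paths):
        for s in p:
            for j in slots_of[s]:
                cost[i, j] = slot_cost[j]
    try:
        rows, cols = linear_sum_assignment(cost)
    except ValueError:
        return NEG_INF, None
    if not np.isfinite(cost[rows, cols]).all():
        return NEG_INF, None
    dup = [0] * len(S)
    for j in cols:
        dup[slot_node[j]] += 1
    value = sum(log_pmf_at(model, lens, s, dup[s]) for s in range(len(S)))
    m = next(allocate_duplications(G, S, mstar, sigma, dup, fixed), None)
    if m is None:  # should not happen; counts proven achievable
        return NEG_INF, None
    return value, Reconciliation(G=G, S=S, m=m, sigma=sigma)


# -- parsimony rooting -----------------------------------------------------


@dataclass
class RootingResult:
    tree: RootedTree                 # first minimizer in edge order
    min_duplications: int
    optimal_edges: list[int]         # indices into ``edges``
    edges: list[tuple[int, int]]     # candidate edges (original node ids)
    counts: list[int] = field(repr=False, default_factory=list)


def root_by_parsimony(G: RootedTree, S: RootedTree) -> RootingResult:
    """Root an unrooted gene tree by minimizing lca-duplications.

    ``G`` is taken as an unrooted tree (its root, if of degree two, is
    suppressed); every edge is tried as a root position, the
    lca-reconciliation duplication count is computed for each rooting, and
    all co-minimal edges are reported.  The returned tree is the rooting on
    the first optimal edge in deterministic edge order.
    """
    if len(G.leaves()) < 3:
        raise TreeError("trivial tree: need at least 3 leaves to root")

    # unrooted adjacency with the old root suppressed
    adj: dict[int, list[int]] = {v: [] for v in range(len(G))}
    for v in range(len(G)):
        p = G.parent(v)
        if p is not None:
            adj[v].append(p)
            adj[p].append(v)
    r = G.root
    if len(adj[r]) == 2:
        u, w = adj[r]
        adj[u] = [x if x != r else w for x in adj[u]]
        adj[w] = [x if x != r else u for x in adj[w]]
        del adj[r]

    edges = sorted({tuple(sorted((a, b))) for a in adj for b in adj[a]})

    def build(edge: tuple[int, int]) -> RootedTree:
        a, b = edge
        nodes: list[Node] = [Node(id=0, parent=None, children=())]

        def grow(v: int, come_from: int, parent_id: int) -> int:
            nid = len(nodes)
            nbrs = [x for x in adj[v] if x != come_from]
            nodes.append(Node(id=nid, parent=parent_id, children=(),
                              label=G.label(v) if not nbrs else None))
            if nbrs:
                nodes[nid].children = tuple(grow(x, v, nid) for x in nbrs)
            return nid

        ca = grow(a, b, 0)
        cb = grow(b, a, 0)
        nodes[0].children = (ca, cb)
        return RootedTree(nodes, kind="gene")

    counts = []
    for e in edges:
        T = build(e)
        mstar = lca_mapping(T, S)
        dups = len(T.internal_nodes()) - len(lca_speciations(T, mstar))
        counts.append(dups)
    mn = min(counts)
    optimal = [i for i, cnt in enumerate(counts) if cnt == mn]
    return RootingResult(tree=build(edges[optimal[0]]),
                         min_duplications=mn, optimal_edges=optimal,
                         edges=list(edges), counts=counts)
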