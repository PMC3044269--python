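"""Setting realisation: is a DS setting achieved by some reconciliation?

A DS setting fixes per-species-node duplication and speciation counts; it is
*valid* if some reconciliation realizes exactly those counts.  The search
follows the two-phase scheme: first choose which lca-speciations are kept
(``Sigma``, matching the spec distribution per species node), filtering out
choices that are impossible by counting (the alpha filter); then allocate a
species node to every duplication by bottom-up backtracking, respecting the
mapping monotonicity, the strict below-the-speciation caps, and the target
per-node duplication counts.  The filter is sound but not complete: it never
rejects a realizable ``Sigma``, and allocation gives the final verdict.

Validation is exponential in the worst case but fast in practice; the solver
only calls it on the handful of settings backtraced from the DP optimum.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

from .phylo import RootedTree, TreeError, lca_mapping, lca_speciations, phi
from .recon import DSSetting, Reconciliation


def alpha(G: RootedTree, S: RootedTree, mstar: Sequence[int],
          sigma, s: int) -> int:
    """Number of gene nodes locked (strictly) below ``s`` by ``sigma``.

    Counts internal nodes with a proper ancestor in ``sigma`` whose lca
    image lies in ``S(s)``; those nodes must map strictly below ``s`` in any
    reconciliation keeping ``sigma``.
    """
    locked: set[int] = set()
    for g in sigma:
        if S.is_ancestor_or_self(mstar[g], s):
            locked.update(v for v in G.subtree(g)
                          if v != g and not G.is_leaf(v))
    return len(locked)


def filter_sigma(G: RootedTree, S: RootedTree, mstar: Sequence[int],
                 sigma, setting: DSSetting,
                 phi_list: Sequence[int] | None = None) -> bool:
    """Sound counting filter; ``False`` means no reconciliation can pair
    ``sigma`` with ``setting``.

    Rejects when (i) more nodes are locked strictly below ``s`` than the
    setting places there, or (ii) too few unlocked candidates remain for the
    duplications demanded at ``s``.
    """
    if phi_list is None:
        phi_list = phi(G, S, mstar)
    below = [0] * len(S)  # sum of dup+spec over proper descendants of s
    for s in S.postorder():
        below[s] = sum(below[c] + setting.dup[c] + setting.spec[c]
                       for c in S.children(s))
    for s in range(len(S)):
        a = alpha(G, S, mstar, sigma, s)
        if a > below[s]:
            return False
        if phi_list[s] - a - setting.spec[s] < setting.dup[s]:
            return False
    return True


def _sigma_candidates(G: RootedTree, S: RootedTree, mstar: Sequence[int],
                      setting: DSSetting,
                      required: frozenset[int] = frozenset(),
                      forbidden: frozenset[int] = frozenset(),
                      ) -> Iterator[frozenset[int]]:
    """Subsets of the lca-speciations matching the spec distribution.

    Grouped per species node (the groups are independent); within a group
    the required members are forced in, the forbidden ones out, and the
    remainder is chosen by lexicographic combinations.
    """
    groups: list[list[frozenset[int]]] = []
    by_node: dict[int, list[int]] = {}
    for g in lca_speciations(G, mstar):
        by_node.setdefault(mstar[g], []).append(g)
    for s in range(len(S)):
        want = setting.spec[s]
        avail = sorted(by_node.get(s, []))
        must = [g for g in avail if g in required]
        free = [g for g in avail if g not in required and g not in forbidden]
        extra = want - len(must)
        if extra < 0 or extra > len(free):
            return
        groups.append([frozenset(must) | frozenset(c)
                       for c in combinations(free, extra)])

    def rec(i: int, acc: frozenset[int]) -> Iterator[frozenset[int]]:
        if i == len(groups):
            yield acc
            return
        for choice in groups[i]:
            yield from rec(i + 1, acc | choice)

    yield from rec(0, frozenset())


def _dup_caps(G: RootedTree, S: RootedTree, mstar: Sequence[int],
              sigma) -> dict[int, int]:
    """Highest species node each duplication may map to.

    A duplication below a kept speciation ``g`` must stay strictly inside
    the child subtree of ``m*(g)`` on its side; otherwise it may rise to the
    cap of its parent (the root for unconstrained lineages).
    """
    caps: dict[int, int] = {}
    order = [v for v in range(len(G)) if not G.is_leaf(v)]  # preorder
    for g in order:
        p = G.parent(g)
        if p is None:
            caps[g] = S.root
        elif p in sigma:
            s1, s2 = S.children(mstar[p])
            caps[g] = s1 if S.is_ancestor_or_self(mstar[g], s1) else s2
        else:
            caps[g] = caps[p]
    return caps


def allocate_duplications(G: RootedTree, S: RootedTree, mstar: Sequence[int],
                          sigma, dup: Sequence[int],
                          fixed: dict[int, int] | None = None,
                          ) -> Iterator[tuple[int, ...]]:
    """All complete mappings realizing duplication counts ``dup`` with the
    kept speciations ``sigma``; lazy, deterministic (low candidates first).

    ``fixed`` pins individual duplications to a species node (used by the
    constrained solver for locked nodes).  Yields full gene-to-species
    mappings; yields nothing if the setting is unrealizable with ``sigma``.
    """
    fixed = fixed or {}
    D = [g for g in G.postorder()
         if not G.is_leaf(g) and g not in sigma]
    caps = _dup_caps(G, S, mstar, sigma)
    need = list(dup)
    m = list(mstar)

    def candidates(g: int) -> list[int]:
        lo = mstar[g]
        for c in G.children(g):
            if S.depth(m[c]) < S.depth(lo):
                lo = m[c]
        cap = caps[g]
        if not S.is_ancestor_or_self(lo, cap):
            return []
        path = S.path_up(lo, cap)
        if g in fixed:
            return [fixed[g]] if fixed[g] in path else []
        return path

    def rec(i: int) -> Iterator[tuple[int, ...]]:
        if i == len(D):
            yield tuple(m)
            return
        g = D[i]
        for x in candidates(g):
            if need[x] <= 0:
                continue
            need[x] -= 1
            m[g] = x
            yield from rec(i + 1)
            need[x] += 1
        m[g] = mstar[g]

    if sum(need) != len(D):
        return iter(())
    return rec(0)


def realize_setting(G: RootedTree, S: RootedTree, setting: DSSetting,
                    required: frozenset[int] = frozenset(),
                    forbidden: frozenset[int] = frozenset(),
                    fixed: dict[int, int] | None = None,
                    use_filter: bool = True,
                    ) -> Iterator[Reconciliation]:
    """Lazily yield every reconciliation whose DS setting equals ``setting``.

    ``required``/``forbidden``/``fixed`` restrict the search to a
    constrained reconciliation space (locked speciations must be kept,
    raised ones must not, locked duplications keep their lca mapping).
    """
    n_internal = len(G.internal_nodes())
    if setting.total() != n_internal:
        raise TreeError("count mismatch: setting does not conserve events")
    mstar = lca_mapping(G, S)
    phi_list = phi(G, S, mstar)
    for sigma in _sigma_candidates(G, S, mstar, setting, required, forbidden):
        if use_filter and not filter_sigma(G, S, mstar, sigma, setting,
                                           phi_list):
            logger.debug("sigma candidate %s rejected by counting filter",
                         sorted(sigma))
            continue
        produced = False
        for m in allocate_duplications(G, S, mstar, sigma, setting.dup,
                                       fixed):
            produced = True
            yield Reconciliation(G=G, S=S, m=m, sigma=sigma)
        if not produced:
            logger.debug("sigma candidate %s admits no allocation",
                         sorted(sigma))


def validate_setting(G: RootedTree, S: RootedTree, setting: DSSetting,
                     required: frozenset[int] = frozenset(),
                     forbidden: frozenset[int] = frozenset(),
                     fixed: dict[int, int] | None = None,
                     use_filter: bool = True,
                     ) -> Reconciliation | None:
    """First reconciliation realizing ``setting``, or ``None`` if invalid."""
    return next(realize_setting(G, S, setting, required, forbidden, fixed,
                                use_filter), None)
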