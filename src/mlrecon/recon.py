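"""Reconciliations, DS settings, the duplication-count likelihood, losses.

A reconciliation of a gene tree ``G`` with a species tree ``S`` is a pair
``<m, Sigma>``: a mapping ``m`` of gene nodes into species nodes (preserving
leaf labels, monotone with respect to ancestry, and dominating the
lca-mapping ``m*``) together with a set ``Sigma`` of internal gene nodes
designated as speciations.  Every member of ``Sigma`` must be an
lca-speciation kept at its lca image, with its two children mapped strictly
below, one into each child subtree of its image; all remaining internal
nodes are duplications.  The likelihood of a reconciliation multiplies, over
species nodes ``s``, the probability of observing ``dup(s)`` duplications on
the branch of length ``|s|`` above ``s`` — Poisson with mean ``rate * |s|``
by default, but any discrete distribution over counts can be plugged in.

Losses do not enter the likelihood; :func:`count_losses` reports them from
the embedding implied by a reconciliation.

:func:`enumerate_reconciliations` is an exponential-time exhaustive
enumerator used as the correctness oracle in the test-suite and behind the
``oracle`` CLI subcommand; it is deliberately independent of the dynamic
program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterator, Sequence

from .phylo import (
    RootedTree,
    TreeError,
    is_lca_speciation,
    lca,
    lca_mapping,
    lca_speciations,
)

NEG_INF = float("-inf")


# -- duplication-count models ---------------------------------------------


class PoissonModel:
    """Poisson duplication counts: ``P(tau, d) = exp(-r*tau) (r*tau)^d / d!``.

    ``rate`` is the duplication rate per unit branch length.  A zero-length
    branch carries zero duplications with probability one.
    """

    name = "poisson"

    def __init__(self, rate: float):
        if rate <= 0:
            raise ValueError("invalid rate: duplication rate must be > 0")
        self.rate = float(rate)

    def log_pmf(self, tau: float, d: int) -> float:
        if tau < 0 or d < 0:
            raise ValueError("invalid pmf arguments")
        mean = self.rate * tau
        if mean == 0.0:
            return 0.0 if d == 0 else NEG_INF
        return -mean + d * math.log(mean) - math.lgamma(d + 1)


class GeometricModel:
    """Geometric duplication counts with mean ``rate * tau``.

    ``P(tau, d) = theta^d / (1 + theta)^(d+1)`` with ``theta = rate * tau``.
    Provided as a second built-in to exercise the pluggable-distribution
    contract; heavier-tailed than Poisson at the same mean.
    """

    name = "geometric"

    def __init__(self, rate: float):
        if rate <= 0:
            raise ValueError("invalid rate: duplication rate must be > 0")
        self.rate = float(rate)

    def log_pmf(self, tau: float, d: int) -> float:
        if tau < 0 or d < 0:
            raise ValueError("invalid pmf arguments")
        theta = self.rate * tau
        if theta == 0.0:
            return 0.0 if d == 0 else NEG_INF
        return d * math.log(theta) - (d + 1) * math.log1p(theta)


def resolve_root_length(S: RootedTree,
                        root_length: float | None = None) -> float | None:
    """Branch length to use for the species-tree root, or ``None``.

    The root has no edge in the classical species tree, so by default its
    duplications carry no probability factor and ``None`` is returned.  An
    explicit ``root_length`` argument, or a ``root:x`` length present in the
    newick input, switches on the optional root-edge extension and makes
    root duplications cost like any other branch.
    """
    if root_length is not None:
        if root_length < 0:
            raise ValueError("invalid root length: must be >= 0")
        return float(root_length)
    if S.root_length is not None:
        return float(S.root_length)
    return None


def branch_lengths(S: RootedTree,
                   root_length: float | None = None) -> list[float | None]:
    """Per-node branch lengths ``|s|`` with the root policy applied.

    The root entry is ``None`` when the tree is used without a root edge;
    a ``None`` length contributes probability one for any duplication count.
    """
    out: list[float | None] = []
    for v in range(len(S)):
        if v == S.root:
            out.append(resolve_root_length(S, root_length))
        else:
            l = S.length(v)
            if l is None:
                raise TreeError(f"missing length on node {v}")
            out.append(float(l))
    return out


def log_pmf_at(model, lens, s: int, d: int) -> float:
    """Per-node likelihood factor; an edge-less node (length None) is free."""
    tau = lens[s]
    if tau is None:
        return 0.0
    return model.log_pmf(tau, d)


# -- reconciliations -------------------------------------------------------


@dataclass(frozen=True)
class DSSetting:
    """Per-species-node duplication and speciation counts."""

    dup: tuple[int, ...]
    spec: tuple[int, ...]

    def total(self) -> int:
        return sum(self.dup) + sum(self.spec)


@dataclass(frozen=True)
class Reconciliation:
    """A mapping plus a speciation set; the evolutionary scenario."""

    G: RootedTree
    S: RootedTree
    m: tuple[int, ...]
    sigma: frozenset[int]

    @property
    def duplications(self) -> frozenset[int]:
        return frozenset(g for g in self.G.internal_nodes()
                         if g not in self.sigma)


def check_mapping(G: RootedTree, S: RootedTree, m: Sequence[int]) -> None:
    """Raise unless ``m`` is a valid mapping (leaf labels, conditions 1-2)."""
    mstar = lca_mapping(G, S)
    for v in G.leaves():
        if m[v] != mstar[v]:
            raise TreeError(f"mapping does not preserve leaf label at {v}")
    for u in range(len(G)):
        p = G.parent(u)
        if p is not None and not S.is_ancestor_or_self(m[u], m[p]):
            raise TreeError(f"mapping not monotone at edge {p}->{u}")
    for g in G.internal_nodes():
        dom = lca(S, [m[v] for v in G.subtree(g) if G.is_leaf(v)])
        if not S.is_ancestor_or_self(dom, m[g]):
            raise TreeError(f"mapping below lca-domination at {g}")


def sigma_eligible(G: RootedTree, S: RootedTree, m: Sequence[int],
                   mstar: Sequence[int], g: int) -> bool:
    """Can ``g`` be a speciation under ``m``?

    Requires: ``g`` is an lca-speciation kept at ``m*``; its image is
    internal in ``S``; its children map strictly below, one into each child
    subtree of the image.
    """
    if G.is_leaf(g) or m[g] != mstar[g]:
        return False
    if not is_lca_speciation(G, mstar, g):
        return False
    if S.is_leaf(m[g]):
        return False
    s1, s2 = S.children(m[g])
    c1, c2 = G.children(g)
    a, b = m[c1], m[c2]
    return ((S.is_ancestor_or_self(a, s1) and S.is_ancestor_or_self(b, s2))
            or (S.is_ancestor_or_self(a, s2) and S.is_ancestor_or_self(b, s1)))


def check_reconciliation(R: Reconciliation) -> None:
    """Raise unless ``R`` satisfies the reconciliation invariants."""
    check_mapping(R.G, R.S, R.m)
    mstar = lca_mapping(R.G, R.S)
    for g in R.sigma:
        if not sigma_eligible(R.G, R.S, R.m, mstar, g):
            raise TreeError(f"node {g} is not a valid speciation")


def lca_reconciliation(G: RootedTree, S: RootedTree) -> Reconciliation:
    """The lca-reconciliation ``R* = <m*, Sigma*>``.

    The mapping is the pointwise-minimal one and every lca-speciation is
    kept as a speciation; all other internal nodes are duplications at their
    lca images.
    """
    mstar = lca_mapping(G, S)
    return Reconciliation(G=G, S=S, m=tuple(mstar),
                          sigma=frozenset(lca_speciations(G, mstar)))


def setting_of(R: Reconciliation) -> DSSetting:
    """The DS setting of ``R``: per-species-node (dup, spec) counts."""
    dup = [0] * len(R.S)
    spec = [0] * len(R.S)
    for g in R.G.internal_nodes():
        if g in R.sigma:
            spec[R.m[g]] += 1
        else:
            dup[R.m[g]] += 1
    return DSSetting(dup=tuple(dup), spec=tuple(spec))


def log_likelihood(S: RootedTree, G: RootedTree, R: Reconciliation, model,
                   root_length: float | None = None) -> float:
    """Log of ``L(S, G, R) = prod_s P(|s|, dup_R(s) | rate)``.

    The product runs over every node of ``S`` including the root, whose
    branch length follows :func:`resolve_root_length`.
    """
    setting = setting_of(R)
    lens = branch_lengths(S, root_length)
    return sum(log_pmf_at(model, lens, s, setting.dup[s]) for s in range(len(S)))


def setting_log_likelihood(S: RootedTree, setting: DSSetting, model,
                           root_length: float | None = None) -> float:
    """Likelihood of a DS setting (depends on duplication counts only)."""
    lens = branch_lengths(S, root_length)
    return sum(log_pmf_at(model, lens, s, setting.dup[s]) for s in range(len(S)))


def count_losses(R: Reconciliation) -> int:
    """Gene losses implied by the embedding of ``R`` into the species tree.

    Each gene edge ``u -> c`` descends in ``S`` from ``m(u)`` to ``m(c)``;
    every species node strictly passed on the way is a speciation whose
    other copy left no sampled descendant, i.e. one loss.  If ``u`` is a
    speciation its edge starts below ``m(u)``, so one step is event-bearing
    rather than lost.
    """
    G, S, m = R.G, R.S, R.m
    losses = 0
    for u in range(len(G)):
        for c in G.children(u):
            d = S.edge_distance(m[c], m[u])
            losses += d - (1 if u in R.sigma else 0)
    return losses


# -- exhaustive oracle -----------------------------------------------------


def enumerate_mappings(G: RootedTree, S: RootedTree) -> Iterator[tuple[int, ...]]:
    """All valid mappings of ``G`` into ``S``, deterministically ordered.

    Internal nodes are assigned in postorder; each may sit anywhere on the
    path from the maximum of its lca image and its children's images up to
    the root (this is exactly monotonicity plus lca-domination).
    """
    mstar = lca_mapping(G, S)
    internal = [g for g in G.postorder() if not G.is_leaf(g)]
    m = list(mstar)

    def rec(i: int) -> Iterator[tuple[int, ...]]:
        if i == len(internal):
            yield tuple(m)
            return
        g = internal[i]
        lo = mstar[g]
        for c in G.children(g):
            if S.depth(m[c]) < S.depth(lo):
                lo = m[c]
        for cand in S.path_up(lo, S.root):
            m[g] = cand
            yield from rec(i + 1)
        m[g] = mstar[g]

    return rec(0)


def _powerset(items: list[int]):
    return chain.from_iterable(combinations(items, r)
                               for r in range(len(items) + 1))


def enumerate_reconciliations(G: RootedTree, S: RootedTree,
                              cap: int = 9) -> Iterator[Reconciliation]:
    """Exhaustively enumerate all reconciliations of ``(G, S)``.

    Exponential in tree size; refuses gene trees with more than ``cap``
    leaves.  For each valid mapping, every subset of the speciation-eligible
    nodes yields a distinct reconciliation.
    """
    if len(G.leaves()) > cap:
        raise TreeError("instance too large for oracle")
    mstar = lca_mapping(G, S)
    for m in enumerate_mappings(G, S):
        eligible = [g for g in G.internal_nodes()
                    if sigma_eligible(G, S, m, mstar, g)]
        for subset in _powerset(eligible):
            yield Reconciliation(G=G, S=S, m=m, sigma=frozenset(subset))


def oracle_max(G: RootedTree, S: RootedTree, model,
               root_length: float | None = None, cap: int = 9,
               ) -> tuple[float, Reconciliation]:
    """Brute-force maximum of the likelihood over all reconciliations."""
    lens = branch_lengths(S, root_length)
    best: tuple[float, Reconciliation] | None = None
    for R in enumerate_reconciliations(G, S, cap=cap):
        dup = [0] * len(S)
        for g in G.internal_nodes():
            if g not in R.sigma:
                dup[R.m[g]] += 1
        ll = sum(log_pmf_at(model, lens, s, dup[s]) for s in range(len(S)))
        if best is None or ll > best[0]:
            best = (ll, R)
    assert best is not None
    return best


# -- export ----------------------------------------------------------------


def event_table(R: Reconciliation) -> list[tuple[int, str, int]]:
    """Rows of (gene node id, event in {spec,dup,leaf}, species node id)."""
    rows = []
    for g in range(len(R.G)):
        if R.G.is_leaf(g):
            ev = "leaf"
        elif g in R.sigma:
            ev = "spec"
        else:
            ev = "dup"
        rows.append((g, ev, R.m[g]))
    return rows


def annotated_newick(R: Reconciliation) -> str:
    """Newick of ``G`` with ``[event:species-node]`` comments on every node."""
    G = R.G

    def rec(v: int) -> str:
        if G.is_leaf(v):
            s = G.label(v) or ""
            ev = "leaf"
        else:
            s = "(" + ",".join(rec(c) for c in G.children(v)) + ")"
            ev = "spec" if v in R.sigma else "dup"
        return s + f"[{ev}:{R.m[v]}]"

    return rec(G.root) + ";"
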