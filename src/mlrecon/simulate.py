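"""Random reconciliation instances and the hard-instance-rate experiment.

The generator emulates the simulation design used to characterise the
solver: random binary species trees with ``n`` uniquely labelled leaves and
branch lengths drawn uniformly from ``[1, 20]`` (the root has no edge),
paired with random gene-tree topologies carrying ``ceil(1.25 * n)`` leaves
whose labels are sampled uniformly, with replacement, from the species set.
Topologies come from random sequential pair-joining by default (the
Yule/coalescent shape distribution); uniform (PDA) topologies are available
as an option for sensitivity checks.

``hard_instance_rate`` runs the full solve pipeline over replicate
instances and reports the fraction flagged hard by the solver itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Node, RootedTree
from .solve import mle_solve


@dataclass
class SimulationConfig:
    """Study conditions for the random-instance experiment."""

    n_min: int = 10
    n_max: int = 30
    replicates: int = 5000
    seed: int = 0
    rate: float = 0.005
    interval: tuple[float, float] = (1.0, 20.0)
    gene_leaf_factor: float = 1.25
    topology: str = "pairjoin"   # or "uniform"

    def __post_init__(self):
        if self.n_min < 2:
            raise ValueError("too small: need n >= 2")
        if self.interval[0] > self.interval[1]:
            raise ValueError("invalid branch-length interval")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _join_topology(n: int, rng: np.random.Generator) -> tuple:
    """Random sequential pair-joining over ``n`` labelled tips.

    Returns a nested-tuple topology over tip indices 0..n-1.
    """
    forest: list = list(range(n))
    while len(forest) > 1:
        i, j = sorted(rng.choice(len(forest), size=2, replace=False))
        b = forest.pop(j)
        a = forest.pop(i)
        forest.append((a, b))
    return forest[0]


def _uniform_topology(n: int, rng: np.random.Generator) -> tuple:
    """Uniform (PDA) rooted topology via random edge insertion."""
    if n == 1:
        return 0
    shape: tuple = (0, 1)
    for tip in range(2, n):
        # edges of the current rooted tree, plus the root edge
        edges: list[tuple] = []

        def collect(sub, path):
            edges.append(path)
            if isinstance(sub, tuple):
                collect(sub[0], path + (0,))
                collect(sub[1], path + (1,))

        collect(shape, ())
        pick = edges[int(rng.integers(len(edges)))]

        def insert(sub, path):
            if path == pick:
                return (sub, tip)
            if isinstance(sub, tuple):
                return (insert(sub[0], path + (0,)),
                        insert(sub[1], path + (1,)))
            return sub

        shape = insert(shape, ())
    return shape


def _tree_from_nested(shape, labels, lengths=None, kind="gene",
                      root_length=None) -> RootedTree:
    nodes: list[Node] = []

    def build(sub, parent):
        nid = len(nodes)
        nodes.append(Node(id=nid, parent=parent, children=()))
        if isinstance(sub, tuple):
            nodes[nid].children = tuple(build(x, nid) for x in sub)
        else:
            nodes[nid].label = labels[sub]
        return nid

    build(shape, None)
    if lengths is not None:
        for nd in nodes[1:]:
            nd.length = float(next(lengths))
    return RootedTree(nodes, kind=kind, root_length=root_length)


def random_species_tree(n: int, interval=(1.0, 20.0),
                        rng: np.random.Generator | None = None,
                        topology: str = "pairjoin") -> RootedTree:
    """Random species tree: ``n`` distinct labels ``t1..tn``, i.i.d. uniform
    branch lengths on ``interval``; the root carries no edge."""
    if n < 2:
        raise ValueError("too small: need n >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    shape = (_uniform_topology if topology == "uniform"
             else _join_topology)(n, rng)
    labels = [f"t{i + 1}" for i in range(n)]
    n_edges = 2 * n - 2
    lens = iter(rng.uniform(interval[0], interval[1], size=n_edges))
    return _tree_from_nested(shape, labels, lens, kind="species")


def random_gene_tree(S: RootedTree, leaf_count: int | None = None,
                     rng: np.random.Generator | None = None,
                     topology: str = "pairjoin") -> RootedTree:
    """Random gene tree labelled uniformly (with replacement) from ``L(S)``.

    Defaults to ``ceil(1.25 * |L(S)|)`` leaves; species coverage is not
    forced, only ``L(G) <= L(S)`` is guaranteed.
    """
    rng = rng if rng is not None else np.random.default_rng()
    species = sorted(S.leaf_labels())
    if leaf_count is None:
        leaf_count = math.ceil(1.25 * len(species))
    if leaf_count < 2:
        raise ValueError("too small: need at least 2 gene leaves")
    shape = (_uniform_topology if topology == "uniform"
             else _join_topology)(leaf_count, rng)
    labels = [species[int(i)]
              for i in rng.integers(len(species), size=leaf_count)]
    return _tree_from_nested(shape, labels, kind="gene")


@dataclass
class HardRateResult:
    rate: float                  # fraction of instances flagged hard
    count: int                   # hard instances
    n_instances: int
    table: pd.DataFrame = field(repr=False, default=None)  # per-size summary
    frame: pd.DataFrame = field(repr=False, default=None)  # per-replicate rows


def hard_instance_rate(cfg: SimulationConfig,
                       progress: bool = False) -> HardRateResult:
    """Fraction of random instances the unconstrained DP cannot certify.

    Per replicate: draw ``n`` uniformly from ``[n_min, n_max]``, generate a
    species/gene tree pair, run :func:`mlrecon.solve.mle_solve` with the
    configured duplication rate, and record the solver's own hard flag.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(cfg.replicates):
        n = int(rng.integers(cfg.n_min, cfg.n_max + 1))
        S = random_species_tree(n, cfg.interval, rng, cfg.topology)
        G = random_gene_tree(S, math.ceil(cfg.gene_leaf_factor * n), rng,
                             cfg.topology)
        res = mle_solve(G, S, rate=cfg.rate)
        rows.append((n, rep, res.log_likelihood, res.hard, res.dp_ms,
                     res.bb_ms))
        if progress and (rep + 1) % 500 == 0:
            print(f"  {rep + 1}/{cfg.replicates} instances", flush=True)
    df = pd.DataFrame(rows, columns=["n", "replicate", "logml", "hard",
                                     "dp_ms", "bb_ms"])
    per_size = df.groupby("n").agg(replicates=("hard", "size"),
                                   hard=("hard", "sum"),
                                   mean_dp_ms=("dp_ms", "mean"))
    count = int(df["hard"].sum())
    return HardRateResult(rate=count / len(df), count=count,
                          n_instances=len(df), table=per_size, frame=df)
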