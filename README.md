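# mlrecon

Maximum-likelihood gene-tree/species-tree reconciliation under a
per-branch duplication-count model.

## The problem

Gene families evolve inside a species phylogeny through speciations, gene
duplications and gene losses, so a gene tree *G* (leaves labelled by species
names, repeats allowed) usually disagrees with the species tree *S*.
Reconciliation maps that disagreement onto explicit events.  The classical
parsimony approach (lca-mapping) minimizes event counts but ignores
evolutionary time: a duplication is equally "cheap" on a one-million-year
branch and a hundred-million-year branch.  `mlrecon` is for phylogeneticists
and comparative genomicists who want duplication placements that use the
species tree's branch lengths.

## The model

A *reconciliation* of a rooted binary gene tree *G* with a rooted binary
species tree *S* is a pair ⟨m, Σ⟩: a mapping m of gene nodes into species
nodes that preserves leaf labels, is monotone with respect to ancestry and
dominates the lca-mapping m\*, plus a set Σ of internal nodes kept as
speciations (each an lca-speciation kept at its lca image, its children
mapped strictly below into the two child subtrees of the image).  All other
internal nodes are duplications.  Writing dup(s) for the number of
duplications mapped to species node s and |s| for the branch length above s,
the likelihood is

    L(S, G, R) = ∏_{s ∈ S} P(|s|, dup(s) | λ),

with P a pluggable discrete distribution over counts — Poisson with mean
λ·|s| by default (a geometric alternative ships too).  λ is the duplication
rate per unit branch length.  The root has no branch, so by default its
duplications carry no probability factor; pass an explicit root length (or
put one in the newick, `(...):x;`) to extend the model with a root edge.
Losses are implied by the embedding and reported, but do not enter the
likelihood.

The solver maximizes L over all reconciliations: a dynamic program over
per-node event counts (constrained by *acceptable triplets*, computed from a
dual/free subtree decomposition via a two-budget knapsack), followed by
validation of the reconstructed duplication/speciation settings by an
explicit realisation search.  When validation certifies a setting, the DP
value is exact.  The rare instances where no reconstructed setting is
realizable ("hard" instances) are solved exactly by branch-and-bound over
constrained reconciliation spaces.

## A worked example

The gene tree `((a,b),((a,(a,a)),b))` against the species tree `(a:1,b:1)`
with λ = 0.1 and a unit root branch:

    $ mlrecon solve --species S.nwk --gene G.nwk --rate 0.1 --root-length 1
    logML   -7.900902
    hard    0
    setting 0       1       2
    setting 1       2       0
    losses  0
    event   0       dup     0
    event   1       spec    0
    event   2       leaf    1
    ...
    tree    ((a[leaf:1],b[leaf:2])[spec:0],((a[leaf:1],(a[leaf:1],a[leaf:1])[dup:1])[dup:1],b[leaf:2])[spec:0])[dup:0];

Reading the output: the optimal reconciliation is the lca-reconciliation —
one duplication and two speciations on the root branch (species node 0),
two further duplications on the branch to species *a* (node 1), and no
losses.  Its log-likelihood is log[P(1,1)·P(1,2)·P(1,0)] ≈ −7.9009 with
Poisson means 0.1.  `hard 0` says the dynamic program's answer was
certified directly by validation.

The library API mirrors this:

```python
from mlrecon import parse_newick, mle_solve

S = parse_newick("(a:1,b:1);", kind="species")
G = parse_newick("((a,b),((a,(a,a)),b));", kind="gene")
res = mle_solve(G, S, rate=0.1, root_length=1.0)
res.log_likelihood      # -7.90090245954208
res.settings[0].dup     # (1, 2, 0): per species node
res.hard                # False
```

Other subcommands: `mlrecon simulate` (random-instance sweeps reporting the
hard-instance rate), `mlrecon root` (parsimony rooting of an unrooted gene
tree by minimizing lca-duplications), and `mlrecon oracle` (brute-force
enumeration cross-check, tiny trees only).

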