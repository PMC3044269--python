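# Methods

## Model

**Trees and mappings.** Gene trees and species trees are rooted, binary and
directed; species-tree leaves are uniquely labelled, gene-tree leaves carry
species names with repeats, and the gene label set must be a subset of the
species label set.  The ancestry order reads `x <= y` iff `y` lies on the
root-to-`x` path.  A *mapping* m sends gene nodes to species nodes,
preserves leaf labels, is monotone (`u <= v` implies `m(u) <= m(v)`) and
dominates the lca-mapping m\* (equivalently, every internal node sits on
the species path from its lca image to the root).  Branch lengths live on
the species tree only; lengths present on gene trees are parsed and
ignored.

**Reconciliations.** A reconciliation ⟨m, Σ⟩ keeps a subset Σ of the
lca-speciations at their lca images as speciations; every other internal
node is a duplication.  We additionally require the children of a kept
speciation to map strictly below its image, one into each child subtree
(*speciation-child strictness*).  This is the condition under which
reconciliations correspond one-to-one to explicit embedded scenarios whose
losses are detectable, and it is what the acceptable-triplet machinery
(below) counts; without it the two worked-example acceptable sets in the
test-suite would be larger than they are.

**Likelihood.** `L(S,G,R) = prod_s P(|s|, dup_R(s) | lambda)` with P a
per-branch duplication-count distribution parameterized by branch length.
Poisson with mean `lambda * |s|` is the default; any object with a
`log_pmf(tau, d)` summing to one over d qualifies (a geometric with the
same mean ships as a second built-in and as a contract test).  All
arithmetic is in log space; `-inf` encodes impossible states.  Speciation
membership does not enter the likelihood — only duplication counts do —
so optima are reported both as DS settings (per-species-node
duplication/speciation counts) and as a witness reconciliation.

**The root branch.** The species root has no parent edge, so by default the
root term is omitted: duplications mapped to the root are unpenalized.
This choice matters.  Under it, raising every non-kept node to the root is
always realizable and free, the dynamic program's optimum almost always
validates, and hard instances (below) are rare — about 0.1% or fewer of
random instances, matching the regime the method was designed for.
Penalizing the root (the optional `root_length` parameter, or a root length
in the newick) makes top-level placements costly and raises the
hard-instance rate by an order of magnitude or more (internal probes: ~2.4%
at drawn root lengths, ~24% at root length 200 under the simulation
conditions below).  The worked examples in the tests pass `root_length=1`
explicitly, because their published values include a unit root factor.

**Losses.** Reported, not modelled: each gene edge (u → c) contributes the
species-edge distance from m(u) down to m(c), minus one if u is a
speciation (its first step is the event itself, not a pass-through).  A
pass-through of a species node is a speciation whose sibling copy left no
descendant — one loss.  The count agrees with an explicit embedding walk
(tested) and is zero exactly for congruent scenarios.

## Algorithms

**Dynamic program.** `M(s, kappa)` is the maximal log-likelihood of the
embedding part inside `S(s)` containing `kappa` internal gene nodes, for
`kappa = 0..phi(m*, s)` (the number of internal nodes lca-mapped into
`S(s)`).  Leaves: `M(s, kappa) = log P(|s|, kappa)`.  Internal nodes
maximize `log p(s, delta) + M(s1, k1) + M(s2, k2)` over acceptable triplets
⟨sigma, k1, k2⟩ and `delta = kappa - k1 - k2 - sigma >= 0`.  The answer is
`M(root, |L(G)|-1)`, an upper bound on the true optimum that is exact
whenever one of the settings reconstructed from the argmax tuples is
realizable.  Implementation: per-node numpy vectors, an anti-diagonal
max-plus reduction over the child tables for each sigma, and a max-plus
convolution with the duplication-count column; O(|S|·|G|) memory.  A
320-species / 400-gene-leaf instance solves in under a second.

**Acceptable triplets.** At species node s with children s1, s2, the
maximal gene subtrees lca-mapped into the child subtrees decompose into
*dual pairs* (the two child subtrees of each lca-speciation mapped to s)
and *free* trees.  Keeping sigma speciations forces the selected pairs'
internal-node counts below; everything else can be raised.  Hence
⟨sigma, k1, k2⟩ is acceptable iff `k_j` does not exceed the side total and
sigma is at most the *SeqPair* value: the longest subsequence of the dual
pairs' count pairs with coordinate sums within budgets (k1, k2).  One
knapsack-style table per node answers all budget queries; acceptable sets
are downward-closed in sigma.  On random small instances the acceptable
set at every node equals the set of triplets realized by exhaustive
reconciliation enumeration — the local constraint is exact; hardness is a
cross-level phenomenon.

**Setting validation.** A DS setting is realizable iff some choice of kept
lca-speciations matching the speciation distribution admits a duplication
allocation matching the duplication distribution.  Sigma candidates are
enumerated per species node (lexicographic combinations; the groups are
independent), pre-filtered by a sound counting test (nodes locked strictly
below a species node by kept speciations versus the setting's capacity
there), and completed by exhaustive bottom-up backtracking over duplication
placements (candidates from the lca image up to the cap imposed by the
nearest kept-speciation ancestor, low nodes first).  The filter never
changes a verdict (tested against filter-off runs); allocation gives the
final answer.

**Hard instances and branch-and-bound.** When no reconstructed setting
validates, the DP value strictly exceeds the optimum.  The solver then
branches on an undecided lca-speciation g (deepest species image first,
ties by node id): either g is *raised* (forced duplication, set F) or
*locked* (kept speciation with its lca mapping, set L).  L is closed under
three propagation rules: (i) a non-lca-speciation child of a locked
speciation whose image is a species-child of the parent's is locked (its
mapping interval is a single node); (ii) an lca-speciation child of a
locked duplication is locked; (iii) a non-lca-speciation child of a locked
duplication sharing its image is locked — rule (iii) is the same forcing
as rule (i) and is required for the constrained table's forced-duplication
minima to be consistent on chains of equal-image duplications.  Each
branch runs the constrained DP (per-node kappa/sigma/delta ranges shrunk
by blocked-node counts, constrained acceptable sets built by omitting
locked pairs, freeing raised pairs, and excluding blocked nodes) plus
constrained validation; a validated branch is exact and bounds the rest.

When every lca-speciation status is decided and validation still fails,
the remaining problem is solved exactly in polynomial time: with Σ fixed,
each duplication may sit anywhere on the species path from its lca image
to its cap, and gene-tree monotonicity does not restrict the achievable
per-node count vectors (any violating ancestor/descendant pair along a
root path can swap placements without changing counts).  Maximizing the
separable concave reward then reduces to a rectangular assignment problem
over per-node "k-th duplication" marginal-gain slots, solved with
`scipy.optimize.linear_sum_assignment`.  Branch-and-bound is therefore
exact and total; on every flagged-hard instance in the small random suite
its value matches exhaustive enumeration, and the value is invariant to
the branching order (tested under a reversed candidate order).

**Parsimony rooting.** For an unrooted gene tree, every edge is evaluated
as a root position, the lca-reconciliation duplication count is computed
for each rooting, and all co-minimal edges are reported; the returned tree
is the first minimizer in deterministic edge order.

## Synthetic instances

The generator reproduces the simulation design used to characterise the
solver: species trees with n uniquely labelled leaves, topology from random
sequential pair-joining (the Yule/coalescent shape law; a uniform/PDA
option exists for sensitivity checks), branch lengths i.i.d. uniform on
[1, 20], no root edge; gene trees with ⌈1.25·n⌉ leaves, same topology law,
labels sampled uniformly with replacement from the species set (species
coverage is not forced).  Defaults for the hard-rate experiment: n drawn
uniformly from 10..30, 5000 replicates, λ = 0.005, seeded.

What this emulates — and does not.  Random gene trees are maximally
discordant with the species tree, which stresses the validation machinery
far harder than gene families evolved by duplication and loss would; the
generator makes no attempt to model sequence-estimation error, rate
variation across branches, or realistic family-size distributions.
Passing tests therefore certify the solver's correctness and the rarity of
hard instances under these conditions, not biological realism of the
instances themselves.

## Numerical and design choices

- Log-likelihood ties are detected at relative tolerance 1e-9 (absolute
  1e-12 floor); all tying argmax tuples are kept, ordered by
  (delta, sigma, k1), so outputs are reproducible across runs.
- Setting backtrace is lazy with a deduplicating cap (default 10,000);
  exceeding it declares the instance unresolved by the DP and defers to
  branch-and-bound, which is exact regardless.
- Node identity: preorder integer ids fixed at parse time; every per-node
  structure is keyed by them.  Dual pairs and sigma candidates are ordered
  by these ids, making decompositions and searches deterministic.
- The exhaustive reconciliation enumerator (the test oracle and the
  `oracle` CLI subcommand) refuses gene trees above 9 leaves by default;
  it is exponential by nature and deliberately independent of the DP.
- Zero-length branches are legal: they force zero duplications there
  (probability one for d = 0, zero otherwise).
- Problem sizes in the shipped tests: oracle-equivalence sweeps use up to
  6 species and 8 gene leaves (500 instances in the acceptance suite);
  the hard-rate experiment uses 5000 instances at n = 10..30; one
  log-space stress instance uses 400 gene leaves.

## Known limitations

- Multifurcations are rejected, in both tree kinds; unrooted species
  trees are unsupported (gene trees can be rooted by parsimony first).
- The duplication rate λ is an input, not estimated; a one-dimensional
  outer search over `mle_solve` is easy for users to write and
  intentionally not shipped.
- Loss counting is reporting-only and validated against this package's
  own embedding semantics.
- With an explicit root edge the hard-instance rate grows sharply (see
  above); the branch-and-bound still solves such instances exactly, just
  more slowly.
- The model admits scenarios in which many duplications ride a single
  branch above a kept speciation; with the edge-less root default such
  scenarios at the root are free, which is what keeps the dynamic
  program's bound almost always attainable.
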