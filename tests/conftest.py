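import numpy as np
import pytest

from mlrecon import parse_newick
from mlrecon.simulate import random_gene_tree, random_species_tree

# the two worked example pairs used throughout: a two-species tree with a
# six-leaf and an eight-leaf gene tree exercising duplication raising
EXAMPLE_A_GENE = "((a,b),((a,(a,a)),b));"
EXAMPLE_B_GENE = "(((a,a),(b,b)),((b,b),b));"
SPECIES_AB = "(a:1,b:1);"


@pytest.fixture
def species_ab():
    return parse_newick(SPECIES_AB, kind="species")


@pytest.fixture
def example_a():
    return parse_newick(EXAMPLE_A_GENE, kind="gene")


@pytest.fixture
def example_b():
    return parse_newick(EXAMPLE_B_GENE, kind="gene")


def random_instance(rng: np.random.Generator, max_species: int = 6,
                    max_gene: int = 8):
    """A random small species/gene tree pair for oracle comparisons."""
    n = int(rng.integers(2, max_species + 1))
    S = random_species_tree(n, rng=rng)
    G = random_gene_tree(S, int(rng.integers(2, max_gene + 1)), rng=rng)
    return G, S
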