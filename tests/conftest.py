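import numpy as np
import pytest

from opermorph import Phylogeny, simulate_tree


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); with C = [[2,1,0],[1,2,0],[0,0,2]]."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    def make(n=20, length=1.0):
        return Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");"
        )

    return make


@pytest.fixture
def yule_tree():
    def make(n=20, seed=0):
        return simulate_tree(n, seed=seed)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20150913)
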