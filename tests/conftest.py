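import numpy as np
import pytest

from phylotherm import simulate
from phylotherm.tree import Phylogeny


@pytest.fixture
def cherry():
    return Phylogeny.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule20():
    return simulate.sim_yule(20, 1.0, seed=42)


@pytest.fixture
def yule50():
    return simulate.sim_yule(50, 1.0, seed=43)


def random_tree(rng: np.random.Generator, n_tips: int,
                ultrametric: bool = True) -> Phylogeny:
    """Random Yule tree, optionally with perturbed (non-ultrametric)
    branch lengths."""
    tree = simulate.sim_yule(n_tips, 1.0, seed=int(rng.integers(2 ** 31)))
    if not ultrametric:
        new = tree.lengths * rng.uniform(0.2, 2.0, tree.n_nodes)
        new[0] = 0.0
        tree = tree.with_lengths(new)
    return tree
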