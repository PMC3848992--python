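import numpy as np
import pytest

from phyloniche import treeio


@pytest.fixture
def balanced4():
    """Balanced 4-tip tree, all branches 1 (tips age 0, cherries 1, root 2)."""
    return treeio.parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def caterpillar5():
    """5-tip caterpillar, ultrametric."""
    return treeio.parse_newick(
        "(((( A:1,B:1):1,C:2):1,D:3):1,E:4):0;".replace(" ", "")
    )


@pytest.fixture
def three_species_toy():
    """3 species x 2 specimens with a clean separation gap: within-species
    nodes at age 1, species nodes at ages 6 and 10."""
    return treeio.parse_newick(
        "((a1:1,a2:1):9,((b1:1,b2:1):5,(c1:1,c2:1):5):4):0;"
    )


def random_tree(n_tips: int, seed: int) -> treeio.UltrametricTree:
    """Random ultrametric tree topology (coalescent-shaped) for property tests."""
    from phyloniche.simulate import simulate_coalescent_tree

    return simulate_coalescent_tree(n_tips, 1.0, seed=seed, label_prefix="t")
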