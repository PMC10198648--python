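import dendropy
import numpy as np
import pytest

from hiddensse.states import DEFAULT_SPACE, GeneratingMode
from hiddensse.simulate import sample_tree_set
from hiddensse.trees import CladeTree


def clade_from_newick(newick: str, tip_states: dict, crown_age: float | None = None,
                      space=DEFAULT_SPACE) -> CladeTree:
    """Build a CladeTree from a Newick string and tip -> (ex, co) map."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    return CladeTree(
        tree=tree,
        crown_age=crown_age if crown_age is not None else float(depth),
        tip_states=tip_states,
        space=space,
    )


@pytest.fixture(scope="session")
def etd_mode():
    return GeneratingMode("ETD", np.array([0.1, 0.3, 0.5]), 0.001, 0.4)


@pytest.fixture(scope="session")
def cr_mode():
    return GeneratingMode("CR", np.array([0.3]), 0.001, 0.4)


@pytest.fixture(scope="session")
def small_etd_tree(etd_mode):
    """One small ETD tree (crown age 13.4 MY, 100-250 tips)."""
    return sample_tree_set(etd_mode, 13.4, (100, 250), 1, seed=42)[0]


@pytest.fixture(scope="session")
def tiny_trees(etd_mode):
    """A handful of very small trees (fast likelihood evaluations)."""
    return sample_tree_set(etd_mode, 6.0, (4, 15), 4, seed=11)


@pytest.fixture
def balanced4():
    states = {"a": (0, 0), "b": (0, 1), "c": (1, 0), "d": (2, 2)}
    return clade_from_newick("((a:1,b:1):1,(c:1,d:1):1);", states)


@pytest.fixture
def caterpillar4():
    states = {"a": (0, 0), "b": (0, 1), "c": (1, 0), "d": (2, 2)}
    return clade_from_newick("(a:3,(b:2,(c:1,d:1):1):1);", states)
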