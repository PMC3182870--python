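import numpy as np
import pytest

import ngforest as ngf


@pytest.fixture(scope="session")
def and_not_world():
    """Planted 'A AND NOT B' benchmark: network, data, ground truth."""
    return ngf.generate(ngf.and_not_scenario(seed=11))


@pytest.fixture(scope="session")
def small_forest(and_not_world):
    """A 150-tree forest on the planted benchmark, shared across tests."""
    net, data, _truth = and_not_world
    cfg = ngf.NGFConfig(epsilon=0.01, min_root_degree=5, n_trees=150, seed=23)
    return ngf.build_forest(data, net, cfg)


@pytest.fixture()
def two_class_leaf_tree():
    """Hand-built depth-2 tree over genes A, B (Fig-style schema):
    A >= 1 -> class1; A < 1, B >= 2 -> class0; A < 1, B < 2 -> class1."""
    from ngforest.tree import TreeNode

    leaf = lambda c0, c1: TreeNode(class_counts=np.array([c0, c1]))
    return TreeNode(
        gene="A",
        threshold=1.0,
        left=TreeNode(gene="B", threshold=2.0, left=leaf(1, 6), right=leaf(7, 0)),
        right=leaf(0, 9),
    )
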