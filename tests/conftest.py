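import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from triturus_axial import tables
from triturus_axial.trees import PhyloTree, TreeNode


@pytest.fixture(scope="session")
def table1_records():
    return tables.load_table1_records()


@pytest.fixture(scope="session")
def table2_records():
    return tables.load_table2_records()


@pytest.fixture(scope="session")
def table3_records():
    return tables.load_table3_records()


@pytest.fixture(scope="session")
def fixture_tree():
    return tables.load_tree()


@pytest.fixture(scope="session")
def trait_vectors(table1_records):
    return tables.table1_trait_vectors()


def random_binary_tree(n_tips, rng, prefix="t"):
    """Random rooted binary tree with exponential branch lengths."""
    nodes = [TreeNode(label=f"{prefix}{i}", length=None) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    for node in nodes[0].children:
        pass
    root = nodes[0]

    def assign(node):
        for c in node.children:
            c.length = float(rng.exponential(1.0) + 0.05)
            assign(c)

    assign(root)
    return PhyloTree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(20150915)
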