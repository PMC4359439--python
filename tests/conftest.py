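import numpy as np
import pytest

from clonephy.genome_model import CNV
from clonephy.tssb import TreeState


@pytest.fixture
def worked_example_tree():
    """Chain tree normal A (25%) -> B (25%) -> C (50%) with a homozygous
    deletion assigned to C; the worked-example tumor."""
    tree = TreeState(n_samples=1)
    node_a = tree.root
    node_b = tree._new_node(node_a)
    node_a.children.append(node_b)
    node_c = tree._new_node(node_b)
    node_b.children.append(node_c)
    node_a.eta[0], node_b.eta[0], node_c.eta[0] = 0.25, 0.25, 0.5
    deletion = CNV(id="cnv1", chrom="1", start=0, end=1000, C=0, Cm=0, Cp=0, phi=[0.5])
    return tree, (node_a, node_b, node_c), deletion


@pytest.fixture
def rng():
    return np.random.default_rng(0)
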