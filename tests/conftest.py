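import numpy as np
import pytest

from neurotdb.swc import NeuronForest, SwcNode


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_chain(n, start=(0.0, 0.0, 0.0), step=(1.0, 0.0, 0.0), first_id=1, parent=-1,
               structure_type=3, radius=1.0):
    """Unbranched chain of n nodes as a list of SwcNode (x,y,z steps)."""
    nodes = []
    x, y, z = start
    pid = parent
    for i in range(n):
        nid = first_id + i
        nodes.append(SwcNode(nid, 1 if pid == -1 and i == 0 else structure_type,
                             x + i * step[0], y + i * step[1], z + i * step[2],
                             radius, pid))
        pid = nid
    return nodes


def make_y_tree():
    """Root, one stem node, a bifurcation, then two 2-node daughters (7 nodes)."""
    nodes = [
        SwcNode(1, 1, 0, 0, 0, 1, -1),
        SwcNode(2, 3, 1, 0, 0, 1, 1),
        SwcNode(3, 3, 2, 0, 0, 1, 2),
        SwcNode(4, 3, 3, 1, 0, 1, 3),
        SwcNode(5, 3, 4, 2, 0, 1, 4),
        SwcNode(6, 3, 3, -1, 0, 1, 3),
        SwcNode(7, 3, 4, -2, 0, 1, 6),
    ]
    return NeuronForest(nodes)


def random_tree(rng, n_nodes, spread=20.0):
    """Random tree: each node attaches to a uniformly chosen earlier node."""
    nodes = [SwcNode(1, 1, *rng.uniform(0, spread, 3), rng.uniform(0.5, 2.0), -1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes.append(SwcNode(i, 3, *rng.uniform(0, spread, 3), rng.uniform(0.5, 2.0), parent))
    return NeuronForest(nodes)


@pytest.fixture
def y_tree():
    return make_y_tree()


@pytest.fixture
def float64_nn():
    """Run NN-kernel code in float64 (gradient checks)."""
    from neurotdb.nn.core import default_dtype, set_default_dtype

    saved = default_dtype()
    set_default_dtype(np.float64)
    yield
    set_default_dtype(saved)
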