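import numpy as np
import pytest

from treescape.trees import SpanningTree, path_tree, star_tree


def prufer_to_tree(seq, n):
    """Independent decoder: Prüfer sequence -> labeled tree edge set.

    Used as the enumeration oracle for MST tests (all n^(n-2) labeled trees).
    """
    seq = list(seq)
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    for v in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            # insert keeping the list sorted
            import bisect
            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    return edges


@pytest.fixture
def star10():
    return star_tree(10)


@pytest.fixture
def path10():
    return path_tree(10)


@pytest.fixture
def bridge_tree():
    """Two degree-5 hubs joined through a degree-2 bridge node.

    h1/h2 carry four leaves each plus the bridge; the bridge routes all
    left-right traffic while being locally dominated by both hubs.
    """
    edges = [("h1", f"a{i}") for i in range(4)]
    edges += [("h2", f"b{i}") for i in range(4)]
    edges += [("h1", "bridge"), ("h2", "bridge")]
    nodes = ["h1", "h2", "bridge"] + [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    return SpanningTree(nodes, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
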