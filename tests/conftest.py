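import numpy as np
import pytest

from mstconnect.connectome import SpanningTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def prufer_to_tree(seq, n):
    """Decode a Pruefer sequence into a labelled tree edge list (oracle helper)."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((min(u, v), max(u, v)))
    return edges


def make_tree(edges, n, weights=None):
    if weights is None:
        weights = [1.0] * len(edges)
    return SpanningTree(n_nodes=n, edges=[(i, j, w) for (i, j), w in zip(edges, weights)])


@pytest.fixture
def star9():
    """Star tree on 9 nodes, centre 0."""
    return make_tree([(0, i) for i in range(1, 9)], 9)


@pytest.fixture
def path9():
    """Path tree on 9 nodes."""
    return make_tree([(i, i + 1) for i in range(8)], 9)
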