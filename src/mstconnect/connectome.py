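"""Pearson connectivity matrices and minimum-spanning-tree network metrics.

The MST here is the maximum-*weight* spanning tree of the (non-negative)
correlation matrix: the acyclic backbone that keeps the strongest
connections while avoiding loops.  Negative correlations are set to 0
before tree construction and never used as edges.

Metric conventions (all normalized metrics lie in (0, 1]):

* leaf fraction      = (#degree-1 nodes) / (N - 1); star graph -> 1
* diameter           = (edge count of the longest path) / (N - 1); path -> 1
* avg eccentricity   = mean over nodes of max hop distance, / (N - 1)
* betweenness (tree) = #unordered pairs whose unique path passes through
                       the node as an interior node, / ((N-1)(N-2)/2);
                       star centre -> 1, every leaf -> 0
* average strength   = mean of the original correlation weights of the
                       edges included in the MST (unnormalized)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "SpanningTree",
    "GlobalMetrics",
    "NodalMetrics",
    "connectivity_matrix",
    "build_mst",
    "global_metrics",
    "nodal_metrics",
    "exclusion_preset",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with unit diagonal."""

    weights: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if len(self.roi_labels) != W.shape[0]:
            raise ValueError("label count must equal matrix size")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(W), 1.0):
            raise ValueError("diagonal must be 1")
        if W.min() < -1 - 1e-12 or W.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [-1, 1]")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class SpanningTree:
    """MST backbone: unweighted acyclic connected graph + original weights.

    ``edges`` is a list of ``(i, j, weight)`` with ``i < j`` node indices
    into ``roi_labels`` and ``weight`` the original correlation of that
    edge in the source matrix.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    roi_labels: list[str] | None = None
    _adj: list[list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.n_nodes
        if len(self.edges) != n - 1:
            raise ValueError(f"a spanning tree on {n} nodes needs {n - 1} edges")
        uf = _UnionFind(n)
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j, _w in self.edges:
            if not uf.union(i, j):
                raise ValueError(f"edge ({i}, {j}) creates a cycle")
            adj[i].append(j)
            adj[j].append(i)
        if uf.n_components != 1:
            raise ValueError("edge set does not connect all nodes")
        self._adj = adj

    @property
    def adjacency(self) -> list[list[int]]:
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj])


@dataclass
class GlobalMetrics:
    avg_strength: float
    max_bc: float
    leaf_fraction: float
    diameter_norm: float
    avg_eccentricity_norm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "avg_strength": self.avg_strength,
            "max_bc": self.max_bc,
            "leaf_fraction": self.leaf_fraction,
            "diameter_norm": self.diameter_norm,
            "avg_eccentricity_norm": self.avg_eccentricity_norm,
        }


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness_centrality: np.ndarray


# ---------------------------------------------------------------------------
# Union-find
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        self.n_components -= 1
        return True


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def exclusion_preset(name: str, roi_labels: list[str]) -> set[str]:
    """Named ROI exclusion sets for the connectome analysis.

    ``occipital8`` / ``occipital16`` stand in for the 8- and 16-region
    occipital exclusion lists of a 246-region parcellation whose posterior
    field of view is incomplete; on the synthetic parcellation they map to
    the last 8 / 16 ROI labels.
    """
    if name == "none":
        return set()
    if name == "occipital8":
        return set(roi_labels[-8:])
    if name == "occipital16":
        return set(roi_labels[-16:])
    raise ValueError(f"unknown exclusion preset {name!r}")


def connectivity_matrix(
    roi_ts, exclude: set[str] | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over a subject's ROI time series.

    Parameters
    ----------
    roi_ts
        A :class:`~mstconnect.preprocess.RoiTimeSeries` (or anything with
        ``values``, ``roi_labels``).  Excluded ROIs are removed *before*
        correlation.
    exclude
        ROI labels to drop (e.g. an occipital exclusion preset).
    """
    exclude = exclude or set()
    keep = [i for i, lab in enumerate(roi_ts.roi_labels) if lab not in exclude]
    labels = [roi_ts.roi_labels[i] for i in keep]
    X = np.asarray(roi_ts.values, dtype=float)[keep]
    if X.shape[1] < 3:
        raise ValueError("need at least 3 volumes for correlation")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = labels[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance ROI {bad!r}")
    W = np.corrcoef(X)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    return ConnectivityMatrix(weights=W, roi_labels=labels)


def build_mst(W: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Maximum-weight spanning tree of a correlation matrix (Kruskal).

    Negative correlations are set to 0 and only strictly positive weights
    are candidate edges; if the positive-weight subgraph does not connect
    all nodes an error lists the components.  Edges are processed in order
    of descending weight with ties broken by (smaller first index, then
    second index), so the tree is bit-reproducible.
    """
    if isinstance(W, ConnectivityMatrix):
        weights, labels = W.weights, W.roi_labels
    else:
        weights = np.asarray(W, dtype=float)
        labels = None
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    # descending weight, then ascending (i, j) for deterministic ties
    order = np.lexsort((ju, iu, -w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        comps: dict[int, list[int]] = {}
        for v in range(n):
            comps.setdefault(uf.find(v), []).append(v)
        raise ValueError(
            "positive-weight subgraph is disconnected; components: "
            + "; ".join(str(c) for c in comps.values())
        )
    return SpanningTree(n_nodes=n, edges=edges, roi_labels=labels)


def _bfs_ecc(adj: list[list[int]], src: int) -> tuple[np.ndarray, int]:
    """Hop distances from src and the eccentricity (max distance)."""
    n = len(adj)
    dist = np.full(n, -1, dtype=int)
    dist[src] = 0
    queue = [src]
    for u in queue:
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist, int(dist.max())


def _bc_subtree(tree: SpanningTree) -> np.ndarray:
    """Raw tree betweenness via component sizes after node removal.

    For node v, the components of tree - v have sizes s_1..s_k summing to
    N - 1; the number of pairs whose unique path has v interior is
    sum_{a<b} s_a s_b = ((N-1)^2 - sum s_a^2) / 2.
    """
    n = tree.n_nodes
    adj = tree.adjacency
    # subtree sizes from a DFS rooted at 0
    parent = np.full(n, -1, dtype=int)
    order = [0]
    parent[0] = 0
    for u in order:
        for v in adj[u]:
            if parent[v] < 0:
                parent[v] = u
                order.append(v)
    size = np.ones(n, dtype=np.int64)
    for u in reversed(order[1:]):
        size[parent[u]] += size[u]
    bc_raw = np.zeros(n)
    for v in range(n):
        comp = [size[c] for c in adj[v] if parent[c] == v]
        if v != 0:
            comp.append(n - size[v])
        s = np.array(comp, dtype=float)
        bc_raw[v] = ((n - 1) ** 2 - np.sum(s**2)) / 2.0
    return bc_raw


def nodal_metrics(tree: SpanningTree) -> NodalMetrics:
    """Per-node degree and pair-normalized tree betweenness centrality."""
    n = tree.n_nodes
    bc_raw = _bc_subtree(tree)
    denom = (n - 1) * (n - 2) / 2.0
    bc = bc_raw / denom if denom > 0 else np.zeros(n)
    return NodalMetrics(degree=tree.degrees(), betweenness_centrality=bc)


def global_metrics(tree: SpanningTree) -> GlobalMetrics:
    """Global MST summary: strength, max BC, leaf fraction, diameter, eccentricity."""
    n = tree.n_nodes
    adj = tree.adjacency
    deg = tree.degrees()
    ecc = np.array([_bfs_ecc(adj, v)[1] for v in range(n)])
    return GlobalMetrics(
        avg_strength=float(np.mean([w for *_ij, w in tree.edges])),
        max_bc=float(nodal_metrics(tree).betweenness_centrality.max()),
        leaf_fraction=float(np.sum(deg == 1) / (n - 1)),
        diameter_norm=float(ecc.max() / (n - 1)),
        avg_eccentricity_norm=float(ecc.mean() / (n - 1)),
    )
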