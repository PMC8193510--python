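"""Minimum spanning tree extraction and global tree metrics.

The MST of the distance matrix (d = 1/w over positive Fisher-z weights) is the
backbone of strongest connections. Its global shape is summarised by the
standard sextet of tree metrics:

``L``     mean shortest-path length in hops over all unordered node pairs
``Lf``    leaf fraction — share of degree-1 nodes; high in star-like trees
``Th``    tree hierarchy — leaves / (2 * m * BCmax), anchored at 0.5 for a star
``Dmax``  maximum degree
``r``     degree assortativity (Newman); -1 for a star
``kappa`` degree divergence — second moment of the degree sequence over the first

``Th`` uses pair-normalized betweenness (raw pair count / ((n-1)(n-2)/2)), the
normalization under which a star of any size scores exactly 0.5 and a long path
tends to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import DistanceMatrix
from .errors import DisconnectedGraphError, InvalidSizeError, SchemaError, UndefinedMetricError


def _canon(u, v):
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class SpanningTree:
    """A tree on ``n`` labeled nodes: exactly n-1 undirected edges, connected,
    acyclic. Edges may carry the original weight ``w`` and distance ``d``."""

    nodes: list
    edges: list  # list of (u, v) pairs
    weights: dict = field(default_factory=dict)  # (u,v) canonical -> Fisher-z w
    distances: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = list(self.nodes)
        self.edges = [_canon(u, v) for u, v in self.edges]
        n = len(self.nodes)
        if n < 2:
            raise InvalidSizeError("a spanning tree needs at least 2 nodes")
        if len(self.edges) != n - 1:
            raise SchemaError(f"tree on {n} nodes must have {n - 1} edges, got {len(self.edges)}")
        g = self.to_networkx()
        if g.number_of_nodes() != n or not nx.is_connected(g):
            raise SchemaError("edge set does not form a connected tree on the given nodes")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            g.add_edge(u, v,
                       weight=self.weights.get((u, v), 1.0),
                       distance=self.distances.get((u, v), 1.0))
        return g

    def edge_set(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.edges)

    def degrees(self) -> dict:
        deg = {v: 0 for v in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def degree_sequence(self) -> np.ndarray:
        return np.array(list(self.degrees().values()), dtype=int)

    def total_distance(self) -> float:
        return sum(self.distances.get(e, np.nan) for e in self.edges)


@dataclass
class GlobalTreeMetrics:
    """The six global MST metrics for one tree."""

    L: float
    Lf: float
    Th: float
    Dmax: int
    r: float
    kappa: float

    def as_dict(self) -> dict:
        return {"L": self.L, "Lf": self.Lf, "Th": self.Th,
                "Dmax": self.Dmax, "r": self.r, "kappa": self.kappa}


def _mst_from_graph(g: nx.Graph, labels, algorithm: str) -> SpanningTree:
    if g.number_of_nodes() == 0:
        raise InvalidSizeError("empty graph")
    if not nx.is_connected(g):
        raise DisconnectedGraphError(list(nx.connected_components(g)))
    dists = [d["distance"] for _, _, d in g.edges(data=True)]
    if len(set(dists)) < len(dists):
        warnings.warn(
            "duplicate distances: MST may not be unique; ties broken by "
            "lexicographic edge order",
            RuntimeWarning,
            stacklevel=3,
        )
    mst_edges = nx.minimum_spanning_edges(g, algorithm=algorithm, weight="distance", data=True)
    edges, weights, distances = [], {}, {}
    for u, v, d in mst_edges:
        e = _canon(u, v)
        edges.append(e)
        weights[e] = d.get("weight", np.nan)
        distances[e] = d["distance"]
    return SpanningTree(list(labels), edges, weights, distances)


def kruskal_mst(dm: DistanceMatrix) -> SpanningTree:
    """Kruskal's MST of the distance matrix (minimum total d = strongest
    backbone in w). Unique when the distances are unique; with duplicate
    distances ties are broken deterministically by lexicographic edge order
    and a warning is emitted."""
    return _mst_from_graph(dm.to_graph(), dm.node_labels, "kruskal")


def prim_mst(dm: DistanceMatrix) -> SpanningTree:
    """Prim's algorithm; on unique weights returns the same edge set as
    :func:`kruskal_mst` (used as a cross-check)."""
    return _mst_from_graph(dm.to_graph(), dm.node_labels, "prim")


# ---------------------------------------------------------------------------
# global metrics


def path_length(t: SpanningTree) -> float:
    """Mean hop distance over all unordered node pairs.

    Computed in O(n) from subtree sizes: an edge splitting the tree into parts
    of size s and n-s lies on exactly s*(n-s) pairwise paths.
    """
    n = t.n
    if n == 2:
        return 1.0
    g = t.to_networkx()
    root = t.nodes[0]
    order = list(nx.dfs_postorder_nodes(g, root))
    parent = dict(nx.dfs_predecessors(g, root))
    size = {v: 1 for v in t.nodes}
    crossing = 0
    for v in order:
        if v in parent:
            size[parent[v]] += size[v]
            crossing += size[v] * (n - size[v])
    return crossing / (n * (n - 1) / 2)


def leaf_fraction(t: SpanningTree) -> float:
    deg = t.degree_sequence()
    return float((deg == 1).sum() / t.n)


def max_betweenness(t: SpanningTree) -> float:
    """Maximum pair-normalized betweenness over nodes."""
    bc = nx.betweenness_centrality(t.to_networkx(), normalized=True)
    return max(bc.values())


def tree_hierarchy(t: SpanningTree) -> float:
    """Th = leaf_count / (2 * m * BCmax); 0.5 for a star, -> 0 for a long path."""
    if t.n < 3:
        raise UndefinedMetricError("tree hierarchy requires n >= 3")
    leaves = int((t.degree_sequence() == 1).sum())
    m = t.n - 1
    bc_max = max_betweenness(t)
    return leaves / (2.0 * m * bc_max)


def max_degree(t: SpanningTree) -> int:
    return int(t.degree_sequence().max())


def assortativity(t: SpanningTree) -> float:
    """Pearson correlation of endpoint degrees over both edge orientations.

    Returns NaN when undefined (zero variance of remaining degrees, e.g. n=2);
    NaN records are excluded from group tests downstream.
    """
    deg = t.degrees()
    x, y = [], []
    for u, v in t.edges:
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    return float(r)


def degree_divergence(t: SpanningTree) -> float:
    """kappa = <k^2>/<k>, the broadness of the degree distribution."""
    k = t.degree_sequence().astype(float)
    return float((k**2).sum() / k.sum())


def global_metrics(t: SpanningTree) -> GlobalTreeMetrics:
    return GlobalTreeMetrics(
        L=path_length(t),
        Lf=leaf_fraction(t),
        Th=tree_hierarchy(t) if t.n >= 3 else float("nan"),
        Dmax=max_degree(t),
        r=assortativity(t),
        kappa=degree_divergence(t),
    )


# ---------------------------------------------------------------------------
# convenience constructors used throughout the tests and the generator


def star_tree(n: int, labels=None) -> SpanningTree:
    labels = list(labels) if labels is not None else list(range(n))
    return SpanningTree(labels, [(labels[0], labels[i]) for i in range(1, n)])


def path_tree(n: int, labels=None) -> SpanningTree:
    labels = list(labels) if labels is not None else list(range(n))
    return SpanningTree(labels, [(labels[i], labels[i + 1]) for i in range(n - 1)])
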