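"""Nodal roles in an MST: the connectivity-transitivity framework.

Two kinds of nodes carry high betweenness in a tree: hubs (high degree, the
centres of star-like sub-structures) and "bridges" — low-degree nodes that sit
between hubs and carry inter-module traffic. Degree alone cannot separate them.
The framework combines:

* local importance ``li(v) = |A|/|Adj(v)| + 1/n`` where ``A`` is the set of
  neighbours whose degree does not exceed deg(v). A node dominating its
  neighbourhood scores 1 + 1/n; a node dominated by every neighbour scores 1/n
  (the 1/n term is a baseline that shrinks with network size).
* connector index ``ci(v) = BC(v)/li(v)`` with pair-normalized betweenness:
  high for nodes that route much global traffic while being locally
  unimportant — exactly the bridge profile.

Nodes are classified on the group-representative MST (the MST of the
elementwise-averaged connectivity matrix): hubs are nodes whose degree exceeds
mean + 2 SD over all nodes, connectors those whose ci exceeds mean + 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import ConnectivityMatrix, to_distance
from .errors import SchemaError, UndefinedMetricError
from .trees import SpanningTree, kruskal_mst


@dataclass
class NodalProfile:
    node: object
    degree: int
    bc: float
    li: float
    ci: float
    role: str = "peripheral"


def betweenness(t: SpanningTree) -> dict:
    """Pair-normalized betweenness: the fraction of unordered node pairs (not
    containing v) whose unique tree path passes through v."""
    if t.n < 3:
        raise UndefinedMetricError("betweenness undefined for n < 3")
    return nx.betweenness_centrality(t.to_networkx(), normalized=True)


def local_importance(t: SpanningTree, v=None):
    """li(v) = |{u in Adj(v): deg(u) <= deg(v)}| / |Adj(v)| + 1/n.

    Equal-degree neighbours count toward the numerator (the set definition is
    inclusive). Returns a dict over all nodes, or a single value if ``v`` is
    given.
    """
    deg = t.degrees()
    g = t.to_networkx()
    n = t.n

    def one(u):
        nbrs = list(g.neighbors(u))
        a = sum(1 for w in nbrs if deg[w] <= deg[u])
        return a / len(nbrs) + 1.0 / n

    if v is not None:
        if v not in deg:
            raise SchemaError(f"unknown node {v!r}")
        return one(v)
    return {u: one(u) for u in t.nodes}


def connector_index(t: SpanningTree, v=None):
    """ci(v) = BC(v)/li(v); zero exactly for leaves, maximal for low-degree
    bridges between hubs."""
    bc = betweenness(t)
    li = local_importance(t)
    ci = {u: bc[u] / li[u] for u in t.nodes}
    if v is not None:
        if v not in ci:
            raise SchemaError(f"unknown node {v!r}")
        return ci[v]
    return ci


def group_representative_mst(cohort) -> SpanningTree:
    """MST of the elementwise mean Fisher-z matrix of a group of subjects."""
    cohort = list(cohort)
    if not cohort:
        raise SchemaError("empty cohort")
    labels = cohort[0].node_labels
    for c in cohort[1:]:
        if c.node_labels != labels:
            raise SchemaError("cohort matrices have mismatched node labels")
    mean_z = np.mean([c.z for c in cohort], axis=0)
    avg = ConnectivityMatrix("group_mean", mean_z, list(labels))
    return kruskal_mst(to_distance(avg))


def nodal_profiles(t: SpanningTree) -> list[NodalProfile]:
    deg = t.degrees()
    bc = betweenness(t)
    li = local_importance(t)
    return [
        NodalProfile(node=v, degree=deg[v], bc=bc[v], li=li[v], ci=bc[v] / li[v])
        for v in t.nodes
    ]


def classify_roles(profiles: list[NodalProfile], sd_threshold: float = 2.0) -> list[NodalProfile]:
    """Label hubs (degree > mean + sd_threshold*SD) and connectors (ci above the
    analogous threshold); population SD over the tree's nodes. A node passing
    both thresholds is labeled ``hub+connector`` and reported in a warning."""
    if len(profiles) < 3:
        raise UndefinedMetricError("role classification requires >= 3 nodes")
    degs = np.array([p.degree for p in profiles], dtype=float)
    cis = np.array([p.ci for p in profiles], dtype=float)
    if degs.std() == 0:
        warnings.warn("degree sequence has zero variance; no hubs assigned",
                      RuntimeWarning, stacklevel=2)
    deg_thr = degs.mean() + sd_threshold * degs.std()
    ci_thr = cis.mean() + sd_threshold * cis.std()
    overlap = []
    for p in profiles:
        is_hub = degs.std() > 0 and p.degree > deg_thr
        is_conn = cis.std() > 0 and p.ci > ci_thr
        if is_hub and is_conn:
            p.role = "hub+connector"
            overlap.append(p.node)
        elif is_hub:
            p.role = "hub"
        elif is_conn:
            p.role = "connector"
        else:
            p.role = "peripheral"
    if overlap:
        warnings.warn(f"nodes classified both hub and connector: {overlap}",
                      RuntimeWarning, stacklevel=2)
    return profiles
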