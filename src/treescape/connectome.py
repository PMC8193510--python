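"""Connectivity construction: ROI time series -> Fisher-z matrix -> distance matrix.

Edge weights are Fisher-z transformed Pearson correlations w_ij = arctanh(r_ij).
Because the minimum spanning tree keeps the *strongest* connections, weights are
converted to distances d_ij = 1/w_ij; non-positive weights are removed outright
(the standard convention in MST connectomics), so the distance matrix may have
absent entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DisconnectedGraphError, SchemaError, ZeroVarianceError

_R_CLAMP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """Per-subject ROI x time matrix."""

    subject_id: str
    values: np.ndarray  # nodes x timepoints
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("time series must be a 2-D nodes x timepoints array")
        n, t = self.values.shape
        if n < 2:
            raise SchemaError("need at least 2 nodes")
        if t < 3:
            raise SchemaError("need at least 3 timepoints")
        if not np.isfinite(self.values).all():
            raise SchemaError("time series contains missing/non-finite values")
        if not self.node_labels:
            self.node_labels = [f"roi{i:03d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise SchemaError("node_labels length does not match row count")


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity; the diagonal is ignored by all consumers."""

    subject_id: str
    z: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise SchemaError("connectivity must be square")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.z[off], self.z.T[off], equal_nan=True):
            raise SchemaError("connectivity must be symmetric off-diagonal")
        if not np.isfinite(self.z[off]).all():
            raise SchemaError("off-diagonal connectivity must be finite")
        if not self.node_labels:
            self.node_labels = [f"roi{i:03d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise SchemaError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class DistanceMatrix:
    """d_ij = 1/w_ij for positive weights; absent entries are NaN."""

    d: np.ndarray
    node_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]

    def to_graph(self) -> nx.Graph:
        """Undirected graph over defined entries, edges inserted in lexicographic
        index order (this fixes the MST tie-break)."""
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                dij = self.d[i, j]
                if np.isfinite(dij):
                    g.add_edge(
                        self.node_labels[i],
                        self.node_labels[j],
                        distance=float(dij),
                        weight=1.0 / float(dij),
                    )
        return g


def compute_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Fisher-z transformed Pearson correlation of ROI time series.

    Perfect off-diagonal correlations (|r| = 1, e.g. duplicated series) are
    clamped to +/-(1 - 1e-7) with a warning so that arctanh stays finite.
    """
    sd = ts.values.std(axis=1)
    dead = [lbl for lbl, s in zip(ts.node_labels, sd) if s == 0.0]
    if dead:
        raise ZeroVarianceError(dead)
    r = np.corrcoef(ts.values)
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) >= _R_CLAMP).any():
        warnings.warn(
            "perfectly correlated ROI pair(s); r clamped to +/-(1-1e-7)",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against float round-off
    return ConnectivityMatrix(ts.subject_id, z, list(ts.node_labels))


def to_distance(c: ConnectivityMatrix, repair: bool = False) -> DistanceMatrix:
    """Invert positive weights to distances; drop w <= 0.

    If the positive-weight graph is disconnected this raises
    :class:`DisconnectedGraphError` naming the components. With ``repair=True``
    the minimum number of largest-|z| non-positive edges are added back as tiny
    positive weights (large distances) to reconnect the components; they can
    only enter an MST when no positive route exists.
    """
    n = c.n_nodes
    d = np.full((n, n), np.nan)
    pos = c.z > 0
    np.fill_diagonal(pos, False)
    d[pos] = 1.0 / c.z[pos]
    np.fill_diagonal(d, np.nan)

    dm = DistanceMatrix(d, list(c.node_labels))
    g = dm.to_graph()
    if nx.number_connected_components(g) > 1:
        comps = list(nx.connected_components(g))
        if not repair:
            raise DisconnectedGraphError(comps)
        _repair_components(dm, c, comps)
    return dm


def _repair_components(dm: DistanceMatrix, c: ConnectivityMatrix, comps) -> None:
    comp_of = {}
    roots = list(range(len(comps)))

    def find(a):
        while roots[a] != a:
            roots[a] = roots[roots[a]]
            a = roots[a]
        return a

    for k, comp in enumerate(comps):
        for lbl in comp:
            comp_of[lbl] = k
    candidates = []
    labels = dm.node_labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if comp_of[labels[i]] != comp_of[labels[j]] and c.z[i, j] <= 0:
                candidates.append((abs(c.z[i, j]), i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    eps = 1e-9
    added = 0
    for _, i, j in candidates:
        ra, rb = find(comp_of[labels[i]]), find(comp_of[labels[j]])
        if ra != rb:
            roots[rb] = ra
            dm.d[i, j] = dm.d[j, i] = 1.0 / eps
            added += 1
    warnings.warn(
        f"repaired disconnected positive graph by adding {added} non-positive "
        "edge(s) with tiny positive weight",
        RuntimeWarning,
        stacklevel=3,
    )


# ---------------------------------------------------------------------------
# file I/O


def read_matrix(path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square delimited-text connectivity matrix.

    A header row of node labels is detected automatically; whitespace, comma and
    tab delimiters are accepted.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    labels = None
    if df.iloc[0].apply(lambda v: isinstance(v, str)).all():
        labels = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"cannot parse matrix file {path}: {exc}") from exc
    if mat.shape[0] != mat.shape[1]:
        raise SchemaError(f"matrix in {path} is not square: {mat.shape}")
    sid = subject_id or str(path)
    return ConnectivityMatrix(sid, mat, labels or [])


def write_matrix(c: ConnectivityMatrix, path) -> None:
    pd.DataFrame(c.z, columns=c.node_labels).to_csv(path, sep="\t", index=False)


def read_timeseries(
    path, subject_id: str | None = None, orientation: str = "nodes_x_time"
) -> RoiTimeSeries:
    """Read a delimited time-series table. ``orientation`` is ``nodes_x_time``
    (rows are ROIs) or ``time_x_nodes`` (rows are timepoints)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    labels: list[str] = []
    if df.iloc[0].apply(lambda v: isinstance(v, str)).all():
        labels = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
    mat = df.to_numpy(dtype=float)
    if orientation == "time_x_nodes":
        mat = mat.T
    elif orientation != "nodes_x_time":
        raise SchemaError(f"unknown orientation {orientation!r}")
    return RoiTimeSeries(subject_id or str(path), mat, labels)
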