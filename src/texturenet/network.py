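"""Texture similarity networks and weighted graph measures.

Each subject's network has one node per selected region. The link weight
between two regions is derived from the Euclidean distance d between their
normalized 55-component feature vectors: raw similarity s = 1/(1 + d)
(finite for identical textures; the literal inverse distance 1/d is
available with an epsilon guard), then off-diagonal min–max normalization
to [0, 1] per subject, diagonal 0.

Five weighted node measures are computed:

* strength (ST): sum of a node's link weights;
* betweenness centrality (BC): Brandes' algorithm on edge lengths l = 1/w,
  fractional counting over equal-length shortest paths, unnormalized;
* eigenvector centrality (EC): non-negative leading eigenvector of the
  weight matrix, scaled to max 1;
* clustering coefficient (CC): Onnela's weighted form on w / max(w);
* local efficiency (LE): global efficiency of the subgraph induced by the
  node's neighbours, with lengths 1/ŵ on the max-normalized weights (so LE,
  like CC and EC, is invariant to a global rescaling of the weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .haralick import FeatureMatrix

METRIC_NAMES = ["ST", "BC", "EC", "CC", "LE"]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region link-weight matrix in [0, 1], zero diagonal."""

    w: np.ndarray
    region_labels: list[int]
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if w.shape[0] != len(self.region_labels):
            raise ValueError("label count does not match matrix size")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("duplicate region labels")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.w = w

    @property
    def n_regions(self) -> int:
        return self.w.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.w, index=self.region_labels, columns=self.region_labels)
        df.to_csv(path, sep="\t", index_label="label_id", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str = "") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="label_id")
        labels = [int(x) for x in df.index]
        return cls(w=df.to_numpy(dtype=np.float64), region_labels=labels, subject_id=subject_id)


def similarity_matrix(
    features: FeatureMatrix, variant: str = "bounded", eps: float = 1e-12
) -> ConnectivityMatrix:
    """Build the subject's texture-similarity network from feature vectors.

    ``variant="bounded"`` uses s = 1/(1 + d); ``variant="inverse"`` uses the
    literal inverse distance 1/max(d, eps). Off-diagonal entries are then
    min–max normalized to [0, 1]. If all pairwise similarities are equal
    (e.g. identical feature rows) the network is degenerate: all weights are
    set to 0 with a warning.
    """
    if len(features.values) < 3:
        raise ValueError("need at least 3 regions to build a network")
    X = features.values.to_numpy(dtype=np.float64)
    d = pdist(X, metric="euclidean")
    if variant == "bounded":
        s = 1.0 / (1.0 + d)
    elif variant == "inverse":
        s = 1.0 / np.maximum(d, eps)
    else:
        raise ValueError(f"unknown similarity variant: {variant}")
    lo, hi = s.min(), s.max()
    if hi == lo:
        warnings.warn("degenerate constant similarity; all weights set to 0")
        s = np.zeros_like(s)
    else:
        s = (s - lo) / (hi - lo)
    w = squareform(s)
    return ConnectivityMatrix(
        w=w, region_labels=features.region_labels, subject_id=features.subject_id
    )


def _graph(w: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    ii, jj = np.nonzero(np.triu(w, 1))
    for i, j in zip(ii, jj):
        g.add_edge(int(i), int(j), weight=float(w[i, j]), length=1.0 / float(w[i, j]))
    return g


def strength(conn: ConnectivityMatrix) -> np.ndarray:
    """ST(i) = sum_j w(i, j)."""
    return conn.w.sum(axis=1)


def betweenness(conn: ConnectivityMatrix) -> np.ndarray:
    """Weighted betweenness centrality with edge lengths 1/w, unnormalized."""
    g = _graph(conn.w)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(conn.n_regions)])


def eigenvector_centrality(
    conn: ConnectivityMatrix, tol: float = 1e-10, max_iter: int = 10000
) -> np.ndarray:
    """Non-negative leading eigenvector of w, scaled so the max entry is 1.

    Computed by power iteration on w + a small diagonal shift that makes the
    iteration converge on bipartite-like spectra without changing the
    eigenvectors' ordering.
    """
    w = conn.w
    if not w.any():
        raise ValueError("zero matrix has no eigenvector centrality")
    n = w.shape[0]
    # shift makes the dominant eigenvalue simple-signed (Perron root of w + I)
    a = w + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        v_new = a @ v
        v_new /= np.linalg.norm(v_new)
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    v = np.abs(v)
    return v / v.max()


def clustering(conn: ConnectivityMatrix) -> np.ndarray:
    """Onnela weighted clustering coefficient on w / max(w); 0 when degree < 2."""
    g = _graph(conn.w)
    cc = nx.clustering(g, weight="weight")
    return np.array([cc[i] for i in range(conn.n_regions)])


def _efficiency(w_sub: np.ndarray) -> float:
    """Global efficiency of a weighted graph: mean of 1/shortest-path-length."""
    k = w_sub.shape[0]
    if k < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w_sub > 0, 1.0 / w_sub, np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = dijkstra(lengths, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (k * (k - 1)))


def local_efficiency(conn: ConnectivityMatrix) -> np.ndarray:
    """LE(i) = global efficiency of the subgraph induced by i's neighbours.

    Weights are first normalized by the network maximum; shortest paths use
    lengths 1/ŵ. LE(i) = 0 for nodes with fewer than 2 neighbours.
    """
    w = conn.w
    wmax = w.max()
    w_hat = w / wmax if wmax > 0 else w
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(w_hat[i])[0]
        if len(nbrs) < 2:
            continue
        out[i] = _efficiency(w_hat[np.ix_(nbrs, nbrs)])
    return out


@dataclass
class NodeMetricTable:
    """Per-region ST, BC, EC, CC, LE values for one subject."""

    table: pd.DataFrame  # columns: label_id + METRIC_NAMES
    subject_id: str = ""

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.insert(0, "subject", self.subject_id)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def node_metrics(conn: ConnectivityMatrix) -> NodeMetricTable:
    """All five weighted node measures for one subject's network."""
    df = pd.DataFrame({"label_id": conn.region_labels})
    df["ST"] = strength(conn)
    df["BC"] = betweenness(conn)
    if conn.w.any():
        df["EC"] = eigenvector_centrality(conn)
    else:
        df["EC"] = 0.0
    df["CC"] = clustering(conn)
    df["LE"] = local_efficiency(conn)
    return NodeMetricTable(table=df, subject_id=conn.subject_id)
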