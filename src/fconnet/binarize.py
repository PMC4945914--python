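"""Binarization of weighted connectivity matrices.

Four methods: uniform threshold, fixed density, minimum spanning tree (MST)
and minimum connected component (MCC).  Weights are bounded dependencies in
[0, 1]; for MST they are converted to distances d = 1 - w so that the tree
retains the *strongest* connections, the convention of MST brain-network
analysis.  Tie-breaking everywhere is descending weight then lexicographic
(i, j), which makes every method deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from fconnet.connectivity import ConnectivityMatrix
from fconnet.preproc import ValidationError

BINARIZERS = ("threshold", "density", "mst", "mcc")


class DisconnectedGraphError(ValueError):
    """The weighted graph on nonzero entries is not connected."""


@dataclass
class BinaryNetwork:
    """Undirected 0/1 adjacency produced by one binarizer."""

    adjacency: np.ndarray
    method: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency: must be square")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency: must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency: entries must be 0/1")
        if np.diag(a).any():
            raise ValidationError("adjacency: self-loops are not allowed")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g


def _weights_of(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = W.weights if isinstance(W, ConnectivityMatrix) else np.asarray(W, dtype=float)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    if (w < 0).any():
        raise ValidationError("weights: must be non-negative for binarization")
    return w


def _sorted_edges(w: np.ndarray) -> list[tuple[float, int, int]]:
    """Upper-triangle edges sorted by descending weight, then (i, j)."""
    n = w.shape[0]
    i, j = np.triu_indices(n, 1)
    order = sorted(range(i.size), key=lambda k: (-w[i[k], j[k]], i[k], j[k]))
    return [(float(w[i[k], j[k]]), int(i[k]), int(j[k])) for k in order]


def threshold_binarize(W: ConnectivityMatrix | np.ndarray, th: float) -> BinaryNetwork:
    """Keep links with weight strictly greater than ``th``; may disconnect."""
    if th < 0:
        raise ValidationError("th: must be >= 0")
    w = _weights_of(W)
    return BinaryNetwork((w > th).astype(np.int8), "threshold", float(th))


def density_binarize(
    W: ConnectivityMatrix | np.ndarray, kappa: float
) -> BinaryNetwork:
    """Keep the round(kappa * N(N-1)/2) strongest links.

    Every subject binarized at the same kappa yields the same edge count
    regardless of individual weight scale.  Ties at the cut are resolved by
    lexicographic (i, j) order.
    """
    if not (0 < kappa <= 1):
        raise ValidationError("kappa: must lie in (0, 1]")
    w = _weights_of(W)
    n = w.shape[0]
    m = int(round(kappa * n * (n - 1) / 2))
    if m < 1:
        raise ValidationError(f"kappa={kappa} yields 0 edges for N={n}")
    adj = np.zeros_like(w, dtype=np.int8)
    for _, i, j in _sorted_edges(w)[:m]:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, "density", float(kappa))


def mst_binarize(
    W: ConnectivityMatrix | np.ndarray, transform: str = "one_minus"
) -> BinaryNetwork:
    """Maximum-dependency spanning tree: MST of distances d = 1 - w.

    ``transform="inverse"`` uses d = 1/w instead; any strictly decreasing
    weight-to-distance map yields the same tree when weights are distinct.
    Exactly N-1 edges, connected, acyclic.
    """
    w = _weights_of(W)
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for wt, i, j in _sorted_edges(w):
        if wt <= 0:
            continue
        if transform == "one_minus":
            d = 1.0 - wt
        elif transform == "inverse":
            d = 1.0 / wt
        else:
            raise ValidationError("transform: must be 'one_minus' or 'inverse'")
        g.add_edge(i, j, weight=d)
    if g.number_of_nodes() != n or not nx.is_connected(g):
        raise DisconnectedGraphError(
            "weighted graph on nonzero entries is disconnected; MST undefined"
        )
    tree = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in tree.edges():
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, "mst")


def mcc_binarize(W: ConnectivityMatrix | np.ndarray) -> BinaryNetwork:
    """Minimum connected component: add links in descending weight order
    (including links internal to an existing component) until the graph is
    connected.

    Equivalent to thresholding at the percolation-critical weight w_c — the
    largest weight at which the thresholded graph is connected — including the
    whole tie group at w_c.  At least N-1 edges.
    """
    w = _weights_of(W)
    n = w.shape[0]
    edges = [e for e in _sorted_edges(w) if e[0] > 0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj = np.zeros((n, n), dtype=np.int8)
    n_components = n
    k = 0
    while k < len(edges) and n_components > 1:
        wt = edges[k][0]
        # admit the whole tie group at this weight level
        while k < len(edges) and edges[k][0] == wt:
            _, i, j = edges[k]
            adj[i, j] = adj[j, i] = 1
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                n_components -= 1
            k += 1
    if n_components > 1:
        raise DisconnectedGraphError(
            "weighted graph on nonzero entries is disconnected; MCC undefined"
        )
    return BinaryNetwork(adj, "mcc")


def binarize(
    W: ConnectivityMatrix | np.ndarray,
    method: str,
    parameter: float | None = None,
) -> BinaryNetwork:
    """Dispatch by binarizer name; ``parameter`` is th for threshold, kappa
    for density, ignored for mst/mcc."""
    if method == "threshold":
        if parameter is None:
            raise ValidationError("threshold binarization needs a th parameter")
        return threshold_binarize(W, parameter)
    if method == "density":
        if parameter is None:
            raise ValidationError("density binarization needs a kappa parameter")
        return density_binarize(W, parameter)
    if method == "mst":
        return mst_binarize(W)
    if method == "mcc":
        return mcc_binarize(W)
    raise ValidationError(
        f"unknown binarizer {method!r}; valid: {', '.join(BINARIZERS)}"
    )
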