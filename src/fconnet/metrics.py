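"""Graph-theory metrics on binary brain networks.

Six metrics: global efficiency, node betweenness centrality, edge betweenness
centrality, local efficiency, modularity index, and assortativity.
Betweenness values are unnormalized counts over unordered node pairs.
Disconnected pairs contribute 1/inf = 0 to both efficiencies.  Modularity
Q = sum_m (q_mm - a_m^2) is maximized over partitions with a seeded,
restarted Louvain optimizer followed by greedy single-node refinement.
Assortativity (the Pearson correlation of the degrees at the two ends of each
edge) is undefined on degree-regular graphs and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from fconnet.binarize import BinaryNetwork
from fconnet.preproc import ValidationError

METRIC_NAMES = (
    "global_efficiency",
    "node_betweenness",
    "edge_betweenness",
    "local_efficiency",
    "modularity",
    "assortativity",
)


@dataclass
class MetricValue:
    """One network-level metric value plus optional per-element detail."""

    name: str
    value: float | None
    aggregation: str = "network-level"
    per_node: dict | None = None
    per_edge: dict | None = None
    partition: list[set] | None = None
    undefined_reason: str | None = None

    @property
    def is_defined(self) -> bool:
        return self.value is not None


def _graph(G: BinaryNetwork | nx.Graph) -> nx.Graph:
    return G.to_networkx() if isinstance(G, BinaryNetwork) else G


def global_efficiency(G: BinaryNetwork | nx.Graph) -> MetricValue:
    """GE = (1/(N(N-1))) sum_{i != j} 1/l_ij, with 1/l = 0 for unreachable
    pairs; 1 for the complete graph, 0 for the empty graph."""
    g = _graph(G)
    if g.number_of_nodes() < 2:
        raise ValidationError("global efficiency needs >= 2 nodes")
    return MetricValue("global_efficiency", float(nx.global_efficiency(g)))


def node_betweenness(G: BinaryNetwork | nx.Graph) -> MetricValue:
    """Unnormalized node betweenness (Brandes accumulation over unordered
    pairs, endpoints excluded); network value is the mean over nodes."""
    g = _graph(G)
    if g.number_of_nodes() < 3:
        raise ValidationError("node betweenness needs >= 3 nodes")
    bc = nx.betweenness_centrality(g, normalized=False)
    return MetricValue(
        "node_betweenness",
        float(np.mean(list(bc.values()))),
        aggregation="mean-over-nodes",
        per_node=dict(bc),
    )


def edge_betweenness(G: BinaryNetwork | nx.Graph) -> MetricValue:
    """Unnormalized edge betweenness over unordered pairs (endpoint pairs
    included: the edge (i, j) itself serves the pair (i, j)); network value is
    the mean over edges."""
    g = _graph(G)
    if g.number_of_edges() < 1:
        raise ValidationError("edge betweenness needs >= 1 edge")
    ebc = nx.edge_betweenness_centrality(g, normalized=False)
    return MetricValue(
        "edge_betweenness",
        float(np.mean(list(ebc.values()))),
        aggregation="mean-over-edges",
        per_edge=dict(ebc),
    )


def local_efficiency(G: BinaryNetwork | nx.Graph) -> MetricValue:
    """Mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (0 for degree < 2); exactly 0 on any tree."""
    g = _graph(G)
    if g.number_of_nodes() < 1:
        raise ValidationError("local efficiency needs >= 1 node")
    per_node = {
        v: (
            float(nx.global_efficiency(g.subgraph(g[v])))
            if g.degree[v] >= 2
            else 0.0
        )
        for v in g
    }
    return MetricValue(
        "local_efficiency",
        float(np.mean(list(per_node.values()))),
        aggregation="mean-over-nodes",
        per_node=per_node,
    )


def partition_modularity(G: BinaryNetwork | nx.Graph, partition) -> float:
    """Q = sum_m (q_mm - a_m^2) for a given partition into modules, where
    q_mm is the fraction of links inside module m and a_m the fraction of
    link ends attached to m."""
    return float(nx.community.modularity(_graph(G), partition))


def _refine_partition(g: nx.Graph, comms: list[set]) -> list[set]:
    """Greedy single-node moves (including to a fresh singleton module) until
    Q stops improving."""
    comms = [set(c) for c in comms if c]
    best_q = nx.community.modularity(g, comms)
    improved = True
    while improved:
        improved = False
        for v in sorted(g.nodes()):
            home = next(k for k, c in enumerate(comms) if v in c)
            for k in range(len(comms) + 1):
                if k == home:
                    continue
                trial = [set(c) for c in comms]
                trial[home].discard(v)
                if k == len(comms):
                    trial.append({v})
                else:
                    trial[k].add(v)
                trial = [c for c in trial if c]
                q = nx.community.modularity(g, trial)
                if q > best_q + 1e-12:
                    best_q, comms, improved = q, trial, True
                    break
    return comms


def modularity(
    G: BinaryNetwork | nx.Graph, n_restarts: int = 10, seed: int = 0
) -> MetricValue:
    """Maximized modularity index Q and the optimal partition found.

    Restarted seeded Louvain, each restart refined by greedy single-node
    moves; the best partition over restarts (and over the agglomerative CNM
    candidate) is returned.  Deterministic for a fixed seed.
    """
    g = _graph(G)
    if g.number_of_edges() < 1:
        raise ValidationError("modularity needs >= 1 edge")
    candidates = []
    for k in range(n_restarts):
        candidates.append(nx.community.louvain_communities(g, seed=seed + k))
    candidates.append(nx.community.greedy_modularity_communities(g))
    best_q, best_part = -np.inf, None
    for cand in candidates:
        part = _refine_partition(g, [set(c) for c in cand])
        q = nx.community.modularity(g, part)
        if q > best_q:
            best_q, best_part = q, part
    return MetricValue(
        "modularity", float(best_q), partition=[set(c) for c in best_part]
    )


def assortativity(G: BinaryNetwork | nx.Graph) -> MetricValue:
    """Degree assortativity r in [-1, 1]: Pearson correlation of the degrees
    at the two ends of each edge (Newman).  Undefined (value None) when the
    end degrees have zero variance, e.g. on regular graphs; such subjects are
    excluded from group statistics with an explicit reason."""
    g = _graph(G)
    if g.number_of_edges() < 2:
        raise ValidationError("assortativity needs >= 2 edges")
    degrees = dict(g.degree())
    ends = np.array([(degrees[u], degrees[v]) for u, v in g.edges()], dtype=float)
    both = np.concatenate([ends, ends[:, ::-1]])  # each edge seen from both ends
    if np.var(both[:, 0]) == 0 or np.var(both[:, 1]) == 0:
        return MetricValue(
            "assortativity", None, undefined_reason="zero degree variance at edge ends"
        )
    r = np.corrcoef(both[:, 0], both[:, 1])[0, 1]
    return MetricValue("assortativity", float(r))


_DISPATCH = {
    "global_efficiency": global_efficiency,
    "node_betweenness": node_betweenness,
    "edge_betweenness": edge_betweenness,
    "local_efficiency": local_efficiency,
    "modularity": modularity,
    "assortativity": assortativity,
}


def compute_metric(G: BinaryNetwork | nx.Graph, name: str, **kwargs) -> MetricValue:
    """Compute one metric by name."""
    if name not in _DISPATCH:
        raise ValidationError(
            f"unknown metric {name!r}; valid: {', '.join(METRIC_NAMES)}"
        )
    return _DISPATCH[name](G, **kwargs)
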