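"""Weighted node and whole-network metrics.

Three node-level metrics summarise individual sociality:

* **weighted degree (strength)** -- the sum of a bird's edge weights,
  strength_i = sum_j a_ij;
* **weighted clustering coefficient** (Barrat et al. 2004) -- the
  weight-aware proportion of a bird's neighbour pairs that are themselves
  connected,

      c_i = 1 / (s_i (k_i - 1)) * sum_{j,h} (a_ij + a_ih) / 2 * x_ij x_ih x_jh,

  where x is the binary adjacency, k_i the binary degree and s_i the
  strength; undefined (NaN) for nodes with fewer than two neighbours;
* **weighted betweenness** -- the number of shortest paths between other
  pairs that pass through the focal node, with edge length taken as the
  inverse edge weight (strong associations = short distances).  Raw path
  counts, no pair normalisation; ties between equal-length paths split
  contributions equally.

Node metrics are z-scored within each network so they are comparable across
networks of different size and density.  Four global measures (density,
average path length on inverse-weight distances, average edge weight, and
modularity of a greedy weighted partition) describe overall structure; they
are purely descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InputError
from .network_builder import SocialNetwork

__all__ = [
    "NODE_METRICS",
    "weighted_degree",
    "weighted_clustering",
    "weighted_betweenness",
    "node_metrics",
    "standardize_within_network",
    "global_metrics",
    "GlobalMetricRecord",
]

NODE_METRICS = ("weighted_clustering", "weighted_degree", "weighted_betweenness")


def weighted_degree(net: SocialNetwork) -> np.ndarray:
    """strength_i = sum_j a_ij."""
    return net.weights.sum(axis=1)


def weighted_clustering(net: SocialNetwork) -> np.ndarray:
    """Barrat weighted clustering; NaN for nodes with binary degree < 2."""
    a = net.weights
    x = (a > 0).astype(float)
    k = x.sum(axis=1)
    s = a.sum(axis=1)
    # sum over ordered neighbour pairs (j, h): (a_ij + a_ih)/2 x_ij x_ih x_jh
    # collapses to sum_j a_ij (X @ X)_ij because the half-weights symmetrise.
    paths2 = x @ x
    numerator = (a * paths2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = numerator / (s * (k - 1))
    c[k < 2] = np.nan
    return c


def _as_graph(net: SocialNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.size))
    iu, ju = np.nonzero(np.triu(net.weights, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        w = net.weights[i, j]
        g.add_edge(i, j, weight=w, distance=1.0 / w)
    return g


def weighted_betweenness(net: SocialNetwork) -> np.ndarray:
    """Shortest-path betweenness with edge length 1/a_ij, raw pair counts."""
    g = _as_graph(net)
    bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return np.array([bc[i] for i in range(net.size)])


def node_metrics(net: SocialNetwork, standardized: bool = True) -> pd.DataFrame:
    """Per-individual metric table, raw and (optionally) z-scored.

    Undefined clustering values (binary degree < 2) are treated as 0 for
    standardization so that every individual remains rankable; the raw
    column keeps the NaN for auditing.
    """
    table = pd.DataFrame(
        {
            "weighted_clustering": weighted_clustering(net),
            "weighted_degree": weighted_degree(net),
            "weighted_betweenness": weighted_betweenness(net),
        },
        index=pd.Index(net.nodes, name="individual_id"),
    )
    table.insert(0, "network_id", net.network_id)
    if standardized:
        table = standardize_within_network(table)
    return table


def standardize_within_network(table: pd.DataFrame) -> pd.DataFrame:
    """Append within-network z-scored columns (sample sd, ddof=1).

    Zero-variance metrics get a z-score of 0 everywhere and are recorded in
    ``table.attrs['zero_variance']`` -- such networks are dropped upstream.
    """
    if len(table) < 2:
        raise InputError("standardize_within_network: need at least 2 nodes")
    out = table.copy()
    flat = []
    for name in NODE_METRICS:
        values = out[name].to_numpy(dtype=float)
        values = np.nan_to_num(values, nan=0.0)
        sd = values.std(ddof=1)
        if sd == 0:
            flat.append(name)
            out[name + "_z"] = 0.0
        else:
            out[name + "_z"] = (values - values.mean()) / sd
    out.attrs["zero_variance"] = flat
    return out


@dataclass(frozen=True)
class GlobalMetricRecord:
    network_id: str
    density: float
    average_path_length: float
    average_edge_weight: float
    modularity: float


def global_metrics(net: SocialNetwork) -> GlobalMetricRecord:
    """Descriptive whole-network measures.

    Density counts present (nonzero) edges over N(N-1)/2; average path
    length is the mean inverse-weight shortest-path distance over connected
    pairs; modularity scores the partition found by greedy weighted
    modularity optimisation.  Networks without edges return NaN for the
    edge-dependent measures.
    """
    n = net.size
    g = _as_graph(net)
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    if m == 0:
        return GlobalMetricRecord(net.network_id, density, np.nan, np.nan, np.nan)

    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    avg_weight = float(np.mean(weights))

    total, pairs = 0.0, 0
    for source, dists in nx.all_pairs_dijkstra_path_length(g, weight="distance"):
        for target, d in dists.items():
            if target != source:
                total += d
                pairs += 1
    apl = total / pairs if pairs else np.nan

    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    modularity = nx.community.modularity(g, communities, weight="weight")
    return GlobalMetricRecord(net.network_id, density, apl, avg_weight, modularity)


def global_metrics_frame(networks) -> pd.DataFrame:
    records = [global_metrics(net) for net in networks]
    return pd.DataFrame([r.__dict__ for r in records])
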