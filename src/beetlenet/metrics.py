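"""Graph-topology metrics for species co-occurrence networks.

Conventions follow the NetworkAnalyzer family of tools: all metrics are
computed on the simple unweighted graph (edge weights only influence
layout), closeness and betweenness are normalised within each connected
component, shortest-path counts and edge betweenness use ordered-pair
counting (so the lone edge of an isolated species pair has EBC = 2), and
network centralization is the Freeman degree-centralization index.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree (NDC), closeness (NCC), betweenness (NBC) and clustering.

    NCC is (number of reachable nodes) / (sum of distances to them), i.e.
    the reciprocal mean shortest-path distance within the node's component;
    NBC is normalised by (n-1)(n-2)/2 with n the component size. Isolated
    nodes score 0 on both. Local clustering of degree-<2 nodes is 0.
    """
    rows = {
        v: {"ndc": int(net.degree(v)), "ncc": 0.0, "nbc": 0.0, "local_clustering": 0.0}
        for v in net.nodes
    }
    clustering = nx.clustering(net)
    for v, c in clustering.items():
        rows[v]["local_clustering"] = float(c)
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        n = len(comp)
        if n < 2:
            continue
        for v, c in nx.closeness_centrality(sub, wf_improved=False).items():
            rows[v]["ncc"] = float(c)
        # betweenness normalised by the component's (n-1)(n-2)/2
        for v, b in nx.betweenness_centrality(sub, normalized=(n > 2)).items():
            rows[v]["nbc"] = float(b)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species_id"
    return df.sort_index()


def edge_betweenness(net: nx.Graph) -> pd.DataFrame:
    """Edge betweenness centrality with ordered-pair counting.

    EBC(e) = sum over ordered pairs (s, t) of the fraction of s-t shortest
    paths crossing e; equal-length paths split the count evenly. Twice the
    unordered-pair value, so a two-node component's edge scores exactly 2.
    """
    ebc = nx.edge_betweenness_centrality(net, normalized=False)
    rows = [
        {"source": u, "target": v, "ebc": 2.0 * val} for (u, v), val in ebc.items()
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "ebc"])
    return df.sort_values("ebc", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class NetworkAttributes:
    """Whole-network topology summary (a general-attributes table row)."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    centralization: float | None
    shortest_paths: int
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def network_attributes(net: nx.Graph) -> NetworkAttributes:
    """Density, centralization, heterogeneity, mean clustering and path statistics.

    density = 2E / (N (N-1)); avg_neighbors = 2E / N; shortest_paths counts
    ordered reachable pairs; characteristic path length averages distance
    over those pairs; heterogeneity is the coefficient of variation of the
    degree sequence (population variance); centralization is
    [N / (N-2)] [max_deg / (N-1) - density], undefined (None) for N < 3.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_neighbors = 2.0 * e / n if n else 0.0
    clustering = float(np.mean(list(nx.clustering(net).values()))) if n else 0.0
    if n >= 3:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    else:
        centralization = None
    total_pairs = 0
    total_dist = 0.0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        for _, dists in nx.shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total_pairs += 1
                    total_dist += d
    cpl = total_dist / total_pairs if total_pairs else 0.0
    mean_deg = degrees.mean() if n else 0.0
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    return NetworkAttributes(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=clustering,
        centralization=centralization,
        shortest_paths=total_pairs,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        density=density,
        heterogeneity=heterogeneity,
    )


def annotate_network(net: nx.Graph) -> nx.Graph:
    """Attach node metrics and EBC as graph attributes (in place) and return it."""
    nm = node_metrics(net)
    for v in net.nodes:
        net.nodes[v]["ndc"] = int(nm.at[v, "ndc"])
        net.nodes[v]["ncc"] = float(nm.at[v, "ncc"])
        net.nodes[v]["nbc"] = float(nm.at[v, "nbc"])
        net.nodes[v]["local_clustering"] = float(nm.at[v, "local_clustering"])
    for (u, v), val in nx.edge_betweenness_centrality(net, normalized=False).items():
        net.edges[u, v]["ebc"] = 2.0 * val
    return net
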