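"""Per-node centrality measures and global network statistics.

Four centralities characterize each vertex of a directed regulatory
network:

* **in-degree** — number of incoming edges;
* **out-degree** — number of outgoing edges;
* **betweenness** — fraction of directed shortest paths between other
  ordered vertex pairs that pass through the vertex, normalized by
  (n-1)(n-2); pairs with no path contribute nothing;
* **cluster coefficient** — fraction of the vertex's neighbor pairs
  (neighborhood taken as the union of in- and out-neighbors, direction
  ignored) that are themselves connected by an edge in either direction.

The undirected reading of the cluster coefficient is deliberate: the
mixed-direction neighborhoods of miRNAs (miRNA -> target plus
TF -> miRNA) only close into triangles when direction is ignored, which
is the configuration of interest for miRNA/TF co-regulation.

Isolated vertices carry betweenness 0 and cluster coefficient 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import RegulatoryNetwork

__all__ = [
    "MEASURES",
    "GlobalStats",
    "degree_profile",
    "betweenness",
    "cluster_coefficient",
    "centrality_profile",
    "characteristic_path_length",
    "global_stats",
]

#: Column names of the centrality profile, in canonical order.
MEASURES = ("in_degree", "out_degree", "betweenness", "cluster_coefficient")


def degree_profile(net: RegulatoryNetwork) -> pd.DataFrame:
    """In- and out-degree per node, indexed by node id (sorted)."""
    ids = net.node_ids
    return pd.DataFrame(
        {
            "in_degree": [len(net.in_neighbors(i)) for i in ids],
            "out_degree": [len(net.out_neighbors(i)) for i in ids],
        },
        index=pd.Index(ids, name="node_id"),
    )


def betweenness(
    net: RegulatoryNetwork, normalized: bool = True
) -> dict[str, float]:
    """Directed shortest-path betweenness per node.

    With ``normalized=True`` the raw pair-sum is divided by
    (n-1)(n-2), the number of ordered pairs excluding the vertex, so
    values lie in [0, 1].  The unnormalized count is exposed for
    oracle-style cross-checks.
    """
    g = net.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=normalized))


def cluster_coefficient(net: RegulatoryNetwork) -> dict[str, float]:
    """Undirected-neighborhood clustering coefficient per node.

    For a vertex with k >= 2 neighbors this is the number of unordered
    neighbor pairs joined by at least one edge (either direction),
    divided by C(k, 2); vertices with fewer than two neighbors score 0.
    """
    und = net.to_networkx().to_undirected()
    return dict(nx.clustering(und))


def centrality_profile(
    net: RegulatoryNetwork, measures: tuple[str, ...] = MEASURES
) -> pd.DataFrame:
    """Table of the requested centralities, one row per node (sorted).

    Restricting ``measures`` to the degree columns skips the costlier
    shortest-path computation when only degrees are compared.
    """
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    profile = degree_profile(net)
    if "betweenness" in measures:
        btw = betweenness(net)
        profile["betweenness"] = [btw[i] for i in profile.index]
    if "cluster_coefficient" in measures:
        cc = cluster_coefficient(net)
        profile["cluster_coefficient"] = [cc[i] for i in profile.index]
    return profile[list(measures)]


@dataclass(frozen=True)
class GlobalStats:
    """Whole-network summary statistics.

    ``characteristic_path_length`` is NaN when the network has no
    reachable ordered pair (undefined, not zero).  Mean in-degree and
    mean out-degree are equal by construction (each edge contributes one
    of each).
    """

    characteristic_path_length: float
    mean_in_degree: float
    mean_out_degree: float
    mean_betweenness: float
    mean_cluster_coefficient: float


def characteristic_path_length(net: RegulatoryNetwork) -> float:
    """Mean finite directed shortest-path length over reachable ordered
    pairs (s != t); NaN when no pair is reachable."""
    g = net.to_networkx()
    total = 0
    count = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target != source:
                total += dist
                count += 1
    return total / count if count else math.nan


def global_stats(net: RegulatoryNetwork) -> GlobalStats:
    profile = centrality_profile(net)
    means = profile.mean()
    return GlobalStats(
        characteristic_path_length=characteristic_path_length(net),
        mean_in_degree=float(means["in_degree"]),
        mean_out_degree=float(means["out_degree"]),
        mean_betweenness=float(means["betweenness"]),
        mean_cluster_coefficient=float(means["cluster_coefficient"]),
    )
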