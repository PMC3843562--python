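"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths (and, for betweenness, the
algorithm) used by the implementation: betweenness comes from per-pair
BFS path counting rather than Brandes accumulation, the clustering
coefficient from direct neighbor-pair enumeration, and the TCR from
explicit union-target counting over externally supplied target sets.
"""

from __future__ import annotations

from collections import deque

from regnetopo import RegulatoryNetwork


def _bfs_counts(adj: dict, source: str) -> tuple[dict, dict]:
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def bf_betweenness(
    net: RegulatoryNetwork, normalized: bool = True
) -> dict[str, float]:
    """Betweenness by per-ordered-pair shortest-path counting.

    The number of shortest s->t paths through v is
    sigma(s, v) * sigma(v, t) when d(s, v) + d(v, t) = d(s, t).
    """
    ids = net.node_ids
    adj = {nid: sorted(net.out_neighbors(nid)) for nid in ids}
    dist = {}
    sigma = {}
    for s in ids:
        dist[s], sigma[s] = _bfs_counts(adj, s)
    score = {nid: 0.0 for nid in ids}
    for s in ids:
        for t in ids:
            if s == t or t not in dist[s]:
                continue
            d_st = dist[s][t]
            n_st = sigma[s][t]
            for v in ids:
                if v in (s, t):
                    continue
                if (
                    v in dist[s]
                    and t in dist[v]
                    and dist[s][v] + dist[v][t] == d_st
                ):
                    score[v] += sigma[s][v] * sigma[v][t] / n_st
    n = len(ids)
    if normalized and n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        score = {k: v * scale for k, v in score.items()}
    return score


def bf_cluster_coefficient(net: RegulatoryNetwork) -> dict[str, float]:
    """Clustering by direct enumeration of unordered neighbor pairs."""
    out = {}
    edge_set = set(net.edges)
    for nid in net.node_ids:
        nbrs = sorted(net.neighbors(nid))
        k = len(nbrs)
        if k < 2:
            out[nid] = 0.0
            continue
        connected = 0
        pairs = 0
        for i in range(k):
            for j in range(i + 1, k):
                pairs += 1
                a, b = nbrs[i], nbrs[j]
                if (a, b) in edge_set or (b, a) in edge_set:
                    connected += 1
        out[nid] = connected / pairs
    return out


def tcr_from_target_sets(target_sets: list[set]) -> float:
    """TCR by explicit union-target enumeration of raw target sets."""
    n = len(target_sets)
    total_out = sum(len(s) for s in target_sets)
    union = set().union(*target_sets)
    mean_out = total_out / n
    mean_targ = len(union) / n
    return (mean_targ / mean_out - 1.0 / n) / (1.0 - 1.0 / n)
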