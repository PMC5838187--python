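"""Degree and betweenness centrality.

Betweenness is computed natively with Brandes' dependency-accumulation
algorithm (O(|V||E|) for unweighted graphs), using the raw unordered-pair
convention: for node v, the sum over pairs {s, t} with s != v != t of the
fraction of shortest s-t paths passing through v.  Endpoints are excluded,
disconnected pairs contribute zero and no normalization is applied by
default — only the rank order feeds the downstream top-fraction bottleneck
rule, so any monotone normalization is equivalent.  A normalized column
(division by (n-1)(n-2)/2) is provided for comparability with Cytoscape's
NetworkAnalyzer output.

A brute-force all-shortest-path enumeration oracle is included for small
graphs; it shares no code with the Brandes implementation.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import networkx as nx
import pandas as pd

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "brute_force_betweenness",
    "centrality_table",
]

#: absolute tolerance for betweenness comparisons
BETWEENNESS_ATOL = 1e-9


def _as_table(net: nx.Graph, columns: dict[str, dict]) -> pd.DataFrame:
    nodes = sorted(net.nodes)
    df = pd.DataFrame({name: [vals[v] for v in nodes] for name, vals in columns.items()},
                      index=pd.Index(nodes, name="gene"))
    df.attrs["label"] = net.graph.get("label", "network")
    return df


def degree_centrality(net: nx.Graph) -> pd.DataFrame:
    """Per-gene degree (number of distinct neighbors; isolated nodes get 0)."""
    return _as_table(net, {"degree": dict(net.degree())})


def betweenness_centrality(net: nx.Graph) -> pd.DataFrame:
    """Brandes betweenness, raw unordered-pair convention.

    Returns a DataFrame indexed by gene with ``betweenness`` and, for
    n >= 3, ``normalized_betweenness`` = betweenness / ((n-1)(n-2)/2).
    """
    bc = dict.fromkeys(net.nodes, 0.0)
    for s in net.nodes:
        # single-source shortest-path counts (BFS, unweighted)
        stack: list = []
        preds: dict = {v: [] for v in net.nodes}
        sigma = dict.fromkeys(net.nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(net.nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = dict.fromkeys(net.nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was counted from both endpoints
    for v in bc:
        bc[v] /= 2.0
    table = _as_table(net, {"betweenness": bc})
    n = net.number_of_nodes()
    if n >= 3:
        table["normalized_betweenness"] = table["betweenness"] / ((n - 1) * (n - 2) / 2.0)
    return table


def _all_shortest_paths(net: nx.Graph, s, t) -> list[tuple]:
    """Enumerate every shortest s-t path explicitly (BFS layering + DFS expansion)."""
    dist = {s: 0}
    preds: dict = {s: []}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in net[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                preds[w] = [v]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                preds[w].append(v)
    if t not in dist:
        return []
    paths: list[tuple] = []

    def walk(v, suffix):
        if v == s:
            paths.append((s, *suffix))
            return
        for p in preds[v]:
            walk(p, (v, *suffix))

    walk(t, ())
    return paths


def brute_force_betweenness(net: nx.Graph, max_nodes: int = 15) -> pd.DataFrame:
    """Betweenness by exhaustive enumeration of all shortest paths per pair.

    Independent oracle for :func:`betweenness_centrality`; guarded to small
    graphs because path counts can explode combinatorially.
    """
    if net.number_of_nodes() > max_nodes:
        raise ValueError(
            f"brute-force betweenness limited to {max_nodes} nodes, "
            f"got {net.number_of_nodes()}"
        )
    bc = dict.fromkeys(net.nodes, 0.0)
    for s, t in combinations(sorted(net.nodes), 2):
        paths = _all_shortest_paths(net, s, t)
        if not paths:
            continue
        total = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / total
    return _as_table(net, {"betweenness": bc})


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """Combined per-gene centrality table: degree, betweenness and, when
    defined, normalized betweenness.  Every network node appears exactly once.
    """
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    table = deg.join(btw)
    table.attrs["label"] = net.graph.get("label", "network")
    return table
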