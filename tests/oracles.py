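"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, closed-form
combinatorics, min-plus matrix distances — and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

INF = float("inf")


def floyd_warshall(nodes: list, edges: list[tuple]) -> dict:
    """All-pairs shortest-path distances by min-plus relaxation."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for u, v in edges:
        d[idx[u], idx[v]] = 1.0
        d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return {(a, b): d[idx[a], idx[b]] for a in nodes for b in nodes}


def enumerate_shortest_paths(adj: dict, dist: dict, s, t) -> list[tuple]:
    """All shortest s-t paths by depth-bounded exhaustive DFS."""
    target_len = dist[(s, t)]
    if target_len == INF:
        return []
    paths = []

    def dfs(path, budget):
        head = path[-1]
        if head == t:
            paths.append(tuple(path))
            return
        if budget == 0:
            return
        for nb in adj[head]:
            if nb not in path and dist[(nb, t)] <= budget - 1:
                dfs(path + [nb], budget - 1)

    dfs([s], int(target_len))
    return paths


def brute_centralities(nodes: list, edges: list[tuple]) -> dict:
    """degree / closeness / betweenness by exhaustive shortest-path
    enumeration (closeness uses the per-component (n_c-1)/(n-1) scaling)."""
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = floyd_warshall(nodes, edges)
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}
    closeness = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and dist[(v, u)] < INF]
        if not reach or n == 1:
            closeness[v] = 0.0
            continue
        total = sum(dist[(v, u)] for u in reach)
        closeness[v] = (len(reach) / total) * (len(reach) / (n - 1))
    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                betweenness[v] += 1.0 / sigma
    return {"degree": degree, "closeness": closeness, "betweenness": betweenness}


def brute_global_stats(nodes: list, edges: list[tuple]) -> tuple[float, float, int]:
    """(average path length over reachable pairs, transitivity, pair count)
    by pair/triple enumeration."""
    nodes = sorted(nodes)
    dist = floyd_warshall(nodes, edges)
    finite = [dist[(a, b)] for a, b in itertools.combinations(nodes, 2)
              if dist[(a, b)] < INF]
    apl = sum(finite) / len(finite) if finite else float("nan")
    eset = {frozenset(e) for e in edges}
    triangles = sum(1 for trio in itertools.combinations(nodes, 3)
                    if all(frozenset(p) in eset for p in itertools.combinations(trio, 2)))
    triples = sum(1 for trio in itertools.combinations(nodes, 3)
                  for centre in trio
                  if all(frozenset((centre, o)) in eset for o in trio if o != centre))
    transitivity = 3.0 * triangles / triples if triples else 0.0
    return apl, transitivity, len(finite)


def brute_ecc(nodes: list, edges: list[tuple], u, v) -> float:
    """Edge clustering coefficient by triangle enumeration."""
    eset = {frozenset(e) for e in edges}
    deg = {n: sum(1 for e in eset if n in e) for n in nodes}
    z = sum(1 for w in nodes if w not in (u, v)
            and frozenset((u, w)) in eset and frozenset((v, w)) in eset)
    denom = min(deg[u] - 1, deg[v] - 1)
    return z / denom if denom > 0 else 0.0


def hypergeom_enumeration(universe_size: int, set_size: int, query_size: int,
                          overlap: int) -> float:
    """P(X >= overlap) by enumerating every possible query subset."""
    success = (1 << set_size) - 1  # first set_size elements form the gene set
    count = 0
    total = 0
    for comb_idx in itertools.combinations(range(universe_size), query_size):
        mask = 0
        for i in comb_idx:
            mask |= 1 << i
        total += 1
        if (mask & success).bit_count() >= overlap:
            count += 1
    return count / total


def mw_exact(x, y) -> float:
    """Two-sided exact Mann-Whitney p by relabeling enumeration."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def ustat(ix):
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in range(n1 + n2) if i not in set(ix)]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = ustat(tuple(range(n1)))
    dev = abs(u_obs - mu) - 1e-12
    hits = total = 0
    for ix in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(ustat(ix) - mu) >= dev:
            hits += 1
    return hits / total


def topk_sort_intersect(values: dict[str, dict], k: int,
                        risk: set[str] | None) -> list[str]:
    """Brute-force sort-and-intersect candidate list."""
    tops = []
    for feature, d in values.items():
        ranked = sorted(d, key=lambda n: (-d[n], n))[:k]
        tops.append(set(ranked))
    inter = set.intersection(*tops)
    if risk:
        inter &= risk
    return sorted(inter)
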