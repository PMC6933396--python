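"""Dense-module detection by agglomeration on edge clustering coefficients.

The edge clustering coefficient of an edge (u, v) is

    ECC(u, v) = z(u, v) / min(deg(u) - 1, deg(v) - 1)

where z is the number of triangles containing the edge; a degenerate
denominator (a degree-1 endpoint) gives ECC = 0.  Detection is a fast
agglomerative procedure: starting from singleton clusters, edges are
processed in descending ECC order (ties: larger triangle count first, then
lexicographic edge id) and each edge merges its two clusters unless both are
already locked modules.  A cluster locks when its internal edge count
reaches ``lambda`` times its boundary edge count and its size reaches
``min_size``.  Edges with ECC = 0 carry no triangle evidence and do not
trigger merges, so tree-like regions never agglomerate; this is what keeps
bridges from pulling unrelated nodes into a dense module.  The procedure is
fully deterministic.

Each module's drivers are its highest within-module-degree members: every
node wired to at least half of the other members, and always at least the
top-ranked node (ties reported together).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .datatypes import ValidationError, canonical_edge


def _triangles_on_edge(adj: dict[str, set[str]], u: str, v: str) -> int:
    return len(adj[u] & adj[v])


def edge_clustering_coefficient(net: nx.Graph, edge: tuple[str, str]) -> float:
    """ECC of a single edge; raises if the edge is not in the network."""
    u, v = edge
    if not net.has_edge(u, v):
        raise ValidationError(f"edge {edge!r} not in network")
    adj = {n: set(net.neighbors(n)) for n in (u, v)}
    adj[u].discard(u)
    adj[v].discard(v)
    denom = min(net.degree(u) - 1, net.degree(v) - 1)
    if denom <= 0:
        return 0.0
    return len(adj[u] & adj[v]) / denom


@dataclass
class Module:
    id: int
    members: frozenset[str]
    internal_edges: int
    boundary_edges: int
    drivers: list[str]


@dataclass
class ModuleResult:
    modules: list[Module]
    lam: float
    min_size: int

    def member_sets(self) -> list[set[str]]:
        return [set(m.members) for m in self.modules]


class _Clusters:
    """Union-find over nodes with per-cluster internal edge and degree sums."""

    def __init__(self, net: nx.Graph):
        self.parent = {n: n for n in net.nodes()}
        self.members = {n: {n} for n in net.nodes()}
        self.internal = {n: 0 for n in net.nodes()}
        self.degsum = {n: net.degree(n) for n in net.nodes()}
        self.locked = {n: False for n in net.nodes()}
        self.adj = {n: set(net.neighbors(n)) for n in net.nodes()}

    def find(self, n: str) -> str:
        while self.parent[n] != n:
            self.parent[n] = self.parent[self.parent[n]]
            n = self.parent[n]
        return n

    def merge(self, a: str, b: str) -> str:
        if len(self.members[a]) < len(self.members[b]):
            a, b = b, a
        cross = sum(1 for n in self.members[b] for nb in self.adj[n]
                    if self.find(nb) == a)
        self.parent[b] = a
        self.members[a] |= self.members[b]
        self.internal[a] += self.internal[b] + cross
        self.degsum[a] += self.degsum[b]
        self.locked[a] = self.locked[a] or self.locked[b]
        del self.members[b], self.internal[b], self.degsum[b]
        return a

    def boundary(self, root: str) -> int:
        return self.degsum[root] - 2 * self.internal[root]


def detect_modules(net: nx.Graph, lam: float = 1.0, min_size: int = 3
                   ) -> ModuleResult:
    """Detect locked dense modules (see module docstring for the procedure).

    Emitted modules are disjoint, each satisfying
    ``internal_edges >= lam * boundary_edges`` and ``size >= min_size``
    recomputable from the network.  A network with no qualifying cluster
    yields an empty module list.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("module detection on an empty network")
    if lam <= 0:
        raise ValidationError(f"lambda must be positive, got {lam}")
    if min_size < 2:
        raise ValidationError(f"min_size must be >= 2, got {min_size}")

    adj = {n: set(net.neighbors(n)) for n in net.nodes()}
    scored = []
    for u, v in net.edges():
        u, v = canonical_edge(u, v)
        z = _triangles_on_edge(adj, u, v)
        denom = min(net.degree(u) - 1, net.degree(v) - 1)
        ecc = z / denom if denom > 0 else 0.0
        if ecc > 0:
            scored.append((-ecc, -z, u, v))
    scored.sort()

    cl = _Clusters(net)
    for _, _, u, v in scored:
        ru, rv = cl.find(u), cl.find(v)
        if ru == rv:
            continue
        if cl.locked[ru] and cl.locked[rv]:
            continue
        root = cl.merge(ru, rv)
        if (len(cl.members[root]) >= min_size
                and cl.internal[root] >= lam * cl.boundary(root)):
            cl.locked[root] = True

    emitted = []
    for root, mem in cl.members.items():
        if not cl.locked[root]:
            continue
        internal = cl.internal[root]
        boundary = cl.boundary(root)
        if len(mem) >= min_size and internal >= lam * boundary:
            emitted.append((mem, internal, boundary))
    emitted.sort(key=lambda t: (-len(t[0]), min(t[0])))
    modules = []
    for i, (mem, internal, boundary) in enumerate(emitted, start=1):
        modules.append(Module(id=i, members=frozenset(mem),
                              internal_edges=internal, boundary_edges=boundary,
                              drivers=module_drivers(net, mem)))
    return ModuleResult(modules=modules, lam=lam, min_size=min_size)


def module_drivers(net: nx.Graph, module: Sequence[str] | set[str]) -> list[str]:
    """Driver nodes of a module, ranked by within-module degree.

    Drivers are members wired to at least half of the other members
    (within-module degree >= 0.5 * (size - 1)); at least the top-ranked node
    is always reported, with ties kept together.
    """
    module = set(module)
    if not module:
        raise ValidationError("module is empty")
    wdeg = {n: sum(1 for nb in net.neighbors(n) if nb in module) if n in net else 0
            for n in module}
    ranked = sorted(module, key=lambda n: (-wdeg[n], n))
    threshold = 0.5 * (len(module) - 1)
    drivers = [n for n in ranked if wdeg[n] >= threshold]
    if not drivers:
        top = wdeg[ranked[0]]
        drivers = [n for n in ranked if wdeg[n] == top]
    return drivers
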