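"""Network topology statistics against a degree-preserving rewiring null.

Per-node centralities (degree; Brandes betweenness, unnormalized; closeness
per connected component with the (n_c - 1)/(n - 1) cross-component scaling),
global statistics (average path length over reachable pairs; global
transitivity), a degree-conserved double-edge-swap null ensemble with
empirical p-values, a log-log least-squares power-law fit of the degree
distribution, Mann-Whitney comparison of risk vs background centralities,
and the top-k-per-feature intersection used to nominate candidate genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .datatypes import ValidationError, canonical_edge, risk_nodes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, closeness and betweenness.

    Betweenness is exact (Brandes) and unnormalized, each unordered pair
    counted once.  Closeness of node v in a component of size n_c is
    ((n_c - 1) / sum of distances) * ((n_c - 1) / (n - 1)), which makes
    values comparable across components; isolated nodes get 0.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("centralities of an empty network are undefined")
    deg = dict(net.degree())
    clo = nx.closeness_centrality(net, wf_improved=True)
    bet = nx.betweenness_centrality(net, normalized=False)
    nodes = sorted(net.nodes())
    return pd.DataFrame({
        "node": nodes,
        "degree": [deg[n] for n in nodes],
        "closeness": [clo[n] for n in nodes],
        "betweenness": [bet[n] for n in nodes],
        "is_risk": [bool(net.nodes[n].get("is_risk", False)) for n in nodes],
    }).set_index("node")


# ---------------------------------------------------------------------------
# Global statistics
# ---------------------------------------------------------------------------

@dataclass
class GlobalStats:
    average_path_length: float      # NaN when undefined (flagged below)
    clustering_coefficient: float   # global transitivity
    apl_defined: bool
    n_reachable_pairs: int


def _adjacency(net: nx.Graph) -> csr_array:
    nodes = sorted(net.nodes())
    return csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=np.int8))


def _apl_transitivity(adj: csr_array, need_apl: bool = True
                      ) -> tuple[float, float, int]:
    """(average path length, transitivity, reachable pair count) from a
    0/1 adjacency matrix."""
    deg = np.asarray(adj.sum(axis=1)).ravel()
    triples2 = float((deg * (deg - 1)).sum())          # 2 * connected triples
    if triples2 > 0:
        a2 = adj @ adj
        tri6 = float((a2.multiply(adj)).sum())         # trace(A^3) = 6 * triangles
        transitivity = tri6 / triples2
    else:
        transitivity = 0.0
    if not need_apl:
        return math.nan, transitivity, 0
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    finite = np.isfinite(dist) & (dist > 0)
    n_pairs = int(finite.sum() // 2)
    apl = float(dist[finite].sum() / (2 * n_pairs)) if n_pairs else math.nan
    return apl, transitivity, n_pairs


def global_stats(net: nx.Graph) -> GlobalStats:
    """Average shortest-path length over reachable unordered pairs, and
    global transitivity (3 x triangles / connected triples).

    A network with no connected pair has an undefined average path length:
    the value is NaN and ``apl_defined`` is False (flagged, never silent).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("global statistics of an empty network are undefined")
    apl, transitivity, n_pairs = _apl_transitivity(_adjacency(net))
    return GlobalStats(average_path_length=apl,
                       clustering_coefficient=transitivity,
                       apl_defined=n_pairs > 0,
                       n_reachable_pairs=n_pairs)


# ---------------------------------------------------------------------------
# Degree-preserving rewiring null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullEnsembleConfig:
    n_random: int = 1000
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValidationError(f"n_random must be >= 1, got {self.n_random}")
        if self.swaps_per_edge < 1:
            raise ValidationError(f"swaps_per_edge must be >= 1, got {self.swaps_per_edge}")
        if self.seed < 0:
            raise ValidationError(f"seed must be non-negative, got {self.seed}")


def _swap_edges(edges: list[tuple], n_attempts: int,
                rng: np.random.Generator) -> tuple[list[tuple], int]:
    """Attempt ``n_attempts`` double-edge swaps; returns (edges, accepted).

    A swap picks two distinct edges (a,b),(c,d) and proposes (a,d),(c,b) or
    (a,c),(b,d); proposals creating self-loops or duplicate edges are
    rejected.  The degree sequence is conserved exactly.
    """
    edges = list(edges)
    m = len(edges)
    edge_set = set(edges)
    ii = rng.integers(0, m, size=n_attempts)
    jj = rng.integers(0, m, size=n_attempts)
    ff = rng.integers(0, 2, size=n_attempts)
    accepted = 0
    for k in range(n_attempts):
        i, j = int(ii[k]), int(jj[k])
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if ff[k]:
            p, q = (a, d), (c, b)
        else:
            p, q = (a, c), (b, d)
        if p[0] == p[1] or q[0] == q[1]:
            continue
        p = p if p[0] <= p[1] else (p[1], p[0])
        q = q if q[0] <= q[1] else (q[1], q[0])
        if p == q or p in edge_set or q in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(p)
        edge_set.add(q)
        edges[i] = p
        edges[j] = q
        accepted += 1
    return edges, accepted


def _canonical_edges(net: nx.Graph) -> list[tuple]:
    return sorted(canonical_edge(u, v) for u, v in net.edges())


def rewire_once(net: nx.Graph, seed: int, replicate: int,
                swaps_per_edge: int = 10) -> tuple[list[tuple], int]:
    """Edge list of replicate ``replicate``: a deterministic function of
    (seed, replicate).  Returns (edge list, accepted swap count)."""
    edges = _canonical_edges(net)
    if len(edges) < 2:
        raise ValidationError("rewiring requires a network with >= 2 edges")
    rng = np.random.default_rng([seed, replicate])
    return _swap_edges(edges, swaps_per_edge * len(edges), rng)


def degree_preserving_null(net: nx.Graph, config: NullEnsembleConfig
                           ) -> Iterator[nx.Graph]:
    """Stream of degree-conserved rewired replicates of ``net``.

    Replicate i is a deterministic function of (config.seed, i).  Node
    attributes are carried over unchanged.  If no legal swap exists the
    replicate equals the input and a warning is logged.
    """
    attrs = {n: dict(d) for n, d in net.nodes(data=True)}
    nodes = list(net.nodes())
    for i in range(config.n_random):
        edges, accepted = rewire_once(net, config.seed, i, config.swaps_per_edge)
        if accepted == 0:
            logger.warning("replicate %d: zero accepted swaps (no legal swap found)", i)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        nx.set_node_attributes(g, attrs)
        yield g


def null_global_stats(net: nx.Graph, config: NullEnsembleConfig,
                      need_apl: bool = True) -> pd.DataFrame:
    """Average path length and transitivity across the null ensemble.

    Equivalent to mapping :func:`global_stats` over
    :func:`degree_preserving_null`, but computed on adjacency arrays
    directly so large ensembles stay cheap.
    """
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows = []
    for i in range(config.n_random):
        edges, _ = rewire_once(net, config.seed, i, config.swaps_per_edge)
        r = np.fromiter((index[u] for u, v in edges), dtype=np.int64, count=len(edges))
        c = np.fromiter((index[v] for u, v in edges), dtype=np.int64, count=len(edges))
        data = np.ones(2 * len(edges), dtype=np.int8)
        adj = csr_array((data, (np.concatenate([r, c]), np.concatenate([c, r]))),
                        shape=(n, n))
        apl, cc, _ = _apl_transitivity(adj, need_apl=need_apl)
        rows.append({"replicate": i, "average_path_length": apl,
                     "clustering_coefficient": cc})
    return pd.DataFrame(rows)


def empirical_p(observed: float, null_values: Sequence[float],
                tail: str = "greater", smoothed: bool = False) -> float:
    """Empirical p-value of an observed statistic against null draws.

    Default (strict) rule: p = #{null > observed} / N for ``tail="greater"``
    (symmetric for "less").  ``smoothed=True`` uses the estimator
    (1 + #{null >= observed}) / (N + 1), which never returns 0.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise ValidationError("empirical p-value needs a non-empty null ensemble")
    if tail not in ("greater", "less"):
        raise ValidationError(f"tail must be 'greater' or 'less', got {tail!r}")
    if tail == "greater":
        strict, weak = null_values > observed, null_values >= observed
    else:
        strict, weak = null_values < observed, null_values <= observed
    if smoothed:
        return float((1 + weak.sum()) / (null_values.size + 1))
    return float(strict.sum() / null_values.size)


# ---------------------------------------------------------------------------
# Power-law fit
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float


def fit_power_law(degrees: Sequence[int]) -> PowerLawFit:
    """Least-squares fit of log10 P(k) versus log10 k over observed degrees
    k >= 1 (degrees with zero probability do not appear).  At least three
    distinct positive degree values are required."""
    degrees = np.asarray(list(degrees), dtype=int)
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if ks.size < 3:
        raise ValidationError(
            f"power-law fit needs >= 3 distinct positive degrees, got {ks.size}")
    pk = counts / len(degrees)
    res = stats.linregress(np.log10(ks), np.log10(pk))
    return PowerLawFit(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2))


# ---------------------------------------------------------------------------
# Mann-Whitney U (risk vs background)
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of group x versus y: wins + half-ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of group labelings.

    p = P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|) under random assignment of
    the pooled values to groups; ties enter through midranks, which make the
    rank-sum route identical to win + half-tie counting."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n2 = len(y)
    ranks = stats.rankdata(pooled)           # midranks
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu) - 1e-12            # guard float jitter on ties
    rlist = ranks.tolist()
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = sum(rlist[i] for i in comb) - offset
        total += 1
        if abs(u - mu) >= dev:
            count += 1
    return u_obs, count / total


def _asymptotic_mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided normal-approximation p with tie correction and continuity
    correction."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = ((t ** 3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * stats.norm.sf(z)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of x versus y.

    ``method="auto"`` enumerates exactly when the labeling space is small
    enough to enumerate outright (both groups <= 8, or C(n1+n2, n1) below
    ~20k) and uses the tie- and continuity-corrected normal approximation
    otherwise.  Returns (U of x, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("Mann-Whitney requires non-empty groups")
    if method == "auto":
        method = ("exact" if math.comb(len(x) + len(y), len(x)) <= 20000
                  else "asymptotic")
    if method == "exact":
        return _exact_mw_p(x, y)
    if method == "asymptotic":
        return _asymptotic_mw_p(x, y)
    raise ValidationError(f"unknown method {method!r}")


def compare_risk_vs_background(report: pd.DataFrame, net: nx.Graph,
                               features: Iterable[str] = ("degree", "closeness",
                                                          "betweenness")
                               ) -> pd.DataFrame:
    """Mann-Whitney comparison of each centrality between risk-flagged nodes
    and all remaining nodes."""
    risky = risk_nodes(net)
    if not risky:
        raise ValidationError("no risk-flagged nodes in the network")
    bg = [n for n in report.index if n not in risky]
    rk = [n for n in report.index if n in risky]
    if not bg:
        raise ValidationError("no background (non-risk) nodes in the network")
    rows = []
    for f in features:
        u, p = mann_whitney_u(report.loc[rk, f].to_numpy(),
                              report.loc[bg, f].to_numpy())
        rows.append({"feature": f, "u_statistic": u, "p_value": p,
                     "n_risk": len(rk), "n_background": len(bg)})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Top-k intersection prioritization
# ---------------------------------------------------------------------------

@dataclass
class TopKResult:
    candidates: list[str]
    top_lists: dict[str, list[str]]
    boundary_ties: dict[str, bool]
    k: int


def top_k_intersection(report: pd.DataFrame, k: int = 20,
                       restrict_to_risk: bool = True,
                       features: Sequence[str] = ("degree", "closeness",
                                                  "betweenness")) -> TopKResult:
    """Intersection of the per-feature top-k node lists.

    Per feature, nodes are ranked by descending value with lexicographic node
    id breaking ties; a flag records whether the value at rank k ties with
    rank k+1 (boundary ties are decided lexicographically, never dropped
    silently).  Candidates are the intersection of the three lists,
    restricted to risk-flagged nodes when any exist and
    ``restrict_to_risk=True``.
    """
    n = len(report)
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    top_lists: dict[str, list[str]] = {}
    ties: dict[str, bool] = {}
    for f in features:
        ranked = sorted(report.index, key=lambda node: (-report.loc[node, f], node))
        top_lists[f] = ranked[:k]
        ties[f] = (k < n and
                   report.loc[ranked[k - 1], f] == report.loc[ranked[k], f])
    inter = set(top_lists[features[0]])
    for f in features[1:]:
        inter &= set(top_lists[f])
    if restrict_to_risk and "is_risk" in report.columns and report["is_risk"].any():
        inter &= set(report.index[report["is_risk"]])
    return TopKResult(candidates=sorted(inter), top_lists=top_lists,
                      boundary_ties=ties, k=k)


# ---------------------------------------------------------------------------
# Full topology report
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    per_node: pd.DataFrame
    global_stats: GlobalStats
    null_summary: Optional[dict] = None
    powerlaw: Optional[PowerLawFit] = None
    risk_comparison: Optional[pd.DataFrame] = None


def topology_report(net: nx.Graph, null_config: Optional[NullEnsembleConfig] = None,
                    smoothed: bool = False) -> TopologyReport:
    """Centralities, global statistics and (optionally) empirical p-values of
    average path length and clustering coefficient against the rewiring null."""
    per_node = centralities(net)
    gs = global_stats(net)
    try:
        pl = fit_power_law(per_node["degree"].to_numpy())
    except ValidationError:
        pl = None
    null_summary = None
    if null_config is not None and net.number_of_edges() >= 2:
        null_df = null_global_stats(net, null_config, need_apl=gs.apl_defined)
        null_summary = {
            "n_random": null_config.n_random,
            "swaps_per_edge": null_config.swaps_per_edge,
            "seed": null_config.seed,
            "p_apl": empirical_p(gs.average_path_length,
                                 null_df["average_path_length"].dropna(),
                                 tail="greater", smoothed=smoothed)
            if gs.apl_defined else None,
            "p_cc": empirical_p(gs.clustering_coefficient,
                                null_df["clustering_coefficient"],
                                tail="greater", smoothed=smoothed),
        }
    risk_cmp = None
    if risk_nodes(net) and len(risk_nodes(net)) < net.number_of_nodes():
        risk_cmp = compare_risk_vs_background(per_node, net)
    return TopologyReport(per_node=per_node, global_stats=gs,
                          null_summary=null_summary, powerlaw=pl,
                          risk_comparison=risk_cmp)
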