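"""Synthetic multi-omics study generator with planted, recoverable signal.

Emulates a two-condition cell-line comparison (3 replicates per condition by
default): negative-binomial RNA counts, log-normal protein abundances, a
scale-free protein-protein interaction network with planted dense modules
anchored on planted risk genes, and a GMT gene-set collection containing one
set enriched for the planted genes.  Every generator is a pure function of
its configuration (including the seed), and a machine-readable truth table
records the planted signal for evaluation.

Conditions are labelled ``control`` (reference) and ``glaucoma`` (test);
a planted "up" gene is higher in the test condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, OmicsMatrix, ValidationError, new_network

CONTROL = "control"
TEST = "glaucoma"

# fixed sub-stream tags so each generator is independently reproducible
_STREAM_RNA = 1
_STREAM_PROTEIN = 2
_STREAM_PPI = 3
_STREAM_GENESETS = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data.

    The defaults are the conditions every planted-recovery check runs at:
    2 x 3 design, NB(mean=100, dispersion=0.1) counts with per-sample size
    factors log-uniform in [0.7, 1.4], 4-fold RNA / 2-fold protein planted
    shifts, log-normal protein noise at cv 0.1, a preferential-attachment
    interactome (m=2) and two planted 8-cliques each tied to the rest of the
    graph by a single bridge edge.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    planted_de_genes: tuple[str, ...] = ()
    planted_directions: Optional[Mapping[str, str]] = None  # gene -> up|down; default half/half
    rna_fold: float = 4.0
    protein_fold: float = 2.0
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 0.0   # gene-level dynamic range (0 = flat baselines)
    dispersion: float = 0.1
    protein_cv: float = 0.1
    protein_baseline: float = 1024.0
    protein_dropout: float = 0.0
    network_nodes: int = 1000
    attachment_m: int = 2
    planted_modules: tuple[tuple[int, int], ...] = ((8, 1), (8, 1))
    n_hub_genes: int = 8
    gene_set_count: int = 50
    gene_set_size: int = 40
    enrichment_odds: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_replicates", "network_nodes", "attachment_m"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive integer, got {getattr(self, name)}")
        for name in ("rna_fold", "protein_fold", "baseline_mean", "dispersion",
                     "protein_cv", "protein_baseline", "enrichment_odds"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.baseline_log2_sd < 0:
            raise ValidationError(
                f"baseline_log2_sd must be >= 0, got {self.baseline_log2_sd}")
        if not (0 <= self.protein_dropout < 1):
            raise ValidationError(f"protein_dropout must be in [0, 1), got {self.protein_dropout}")
        if self.seed < 0:
            raise ValidationError(f"seed must be non-negative, got {self.seed}")
        if self.network_nodes <= self.attachment_m:
            raise ValidationError("network_nodes must exceed attachment_m")
        universe = set(self.gene_ids())
        unknown = [g for g in self.planted_de_genes if g not in universe]
        if unknown:
            raise ValidationError(f"planted_de_genes outside the gene universe: {unknown[:5]}")
        for size, bridges in self.planted_modules:
            if size < 2:
                raise ValidationError(f"planted module size must be >= 2, got {size}")
            if size > self.network_nodes:
                raise ValidationError(
                    f"planted module size {size} exceeds network_nodes {self.network_nodes}")
            if bridges < 1:
                raise ValidationError(f"bridge_count must be >= 1, got {bridges}")
        if self.gene_set_size > self.n_genes:
            raise ValidationError(
                f"gene_set_size {self.gene_set_size} exceeds universe size {self.n_genes}")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def directions(self) -> dict[str, str]:
        """Planted direction per gene; default alternates up/down."""
        if self.planted_directions is not None:
            out = dict(self.planted_directions)
            bad = {g: d for g, d in out.items() if d not in ("up", "down")}
            if bad:
                raise ValidationError(f"planted directions must be 'up'/'down': {bad}")
            missing = [g for g in self.planted_de_genes if g not in out]
            if missing:
                raise ValidationError(f"planted genes without a direction: {missing[:5]}")
            return {g: out[g] for g in self.planted_de_genes}
        return {g: ("up" if i % 2 == 0 else "down")
                for i, g in enumerate(self.planted_de_genes)}


def default_config(seed: int = 0, n_planted: int = 100, **overrides) -> SimulationConfig:
    """Standard study conditions with ``n_planted`` genes planted evenly
    through the universe (deterministic placement, independent of seed)."""
    n_genes = int(overrides.pop("n_genes", 2000))
    step = max(1, n_genes // max(1, n_planted))
    planted = tuple(f"G{i:05d}" for i in range(0, step * n_planted, step))[:n_planted]
    return SimulationConfig(n_genes=n_genes, planted_de_genes=planted, seed=seed, **overrides)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _size_factors(rng: np.random.Generator, n: int) -> np.ndarray:
    # log-uniform depth variation so normalization is actually exercised
    return np.exp(rng.uniform(math.log(0.7), math.log(1.4), size=n))


def _sample_ids(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    ids, conds = [], {}
    for cond in (CONTROL, TEST):
        for r in range(1, config.n_replicates + 1):
            s = f"{cond}_{r}"
            ids.append(s)
            conds[s] = cond
    return ids, conds


def simulate_rna_counts(config: SimulationConfig) -> OmicsMatrix:
    """Negative-binomial RNA counts, genes x (2 * n_replicates).

    Planted genes have NB mean ``baseline_mean * rna_fold`` (direction "up")
    or ``baseline_mean / rna_fold`` ("down") in the test condition; variance
    follows the mean/dispersion parameterization var = mu + dispersion*mu^2.
    """
    rng = _rng(config, _STREAM_RNA)
    genes = config.gene_ids()
    sample_ids, conds = _sample_ids(config)
    sf = _size_factors(rng, len(sample_ids))
    directions = config.directions()

    fold = np.ones(len(genes))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, d in directions.items():
        fold[gene_index[g]] = config.rna_fold if d == "up" else 1.0 / config.rna_fold

    # optional gene-level dynamic range (median baseline stays baseline_mean)
    baseline = config.baseline_mean * np.exp2(
        rng.normal(0.0, config.baseline_log2_sd, size=len(genes)))

    mu = np.empty((len(genes), len(sample_ids)))
    for j, s in enumerate(sample_ids):
        per_gene = baseline * (fold if conds[s] == TEST else 1.0)
        mu[:, j] = per_gene * sf[j]

    r = 1.0 / config.dispersion           # NB size parameter
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    values = pd.DataFrame(counts, index=genes, columns=sample_ids)
    return OmicsMatrix(values=values, conditions=conds, kind="counts")


def simulate_protein_abundances(config: SimulationConfig) -> OmicsMatrix:
    """Log-normal protein abundances, proteins x samples.

    log2 abundances are Gaussian with sd ``sqrt(ln(1 + cv^2)) / ln 2``;
    planted proteins are shifted by ``log2(protein_fold)`` in the test
    condition, in the same direction as their RNA counterpart.  A configured
    detection-dropout fraction removes proteins from the observed universe.
    """
    rng = _rng(config, _STREAM_PROTEIN)
    genes = np.array(config.gene_ids())
    if config.protein_dropout > 0:
        n_drop = int(math.floor(config.protein_dropout * len(genes)))
        drop = set(rng.choice(len(genes), size=n_drop, replace=False).tolist())
        keep = [i for i in range(len(genes)) if i not in drop]
        proteins = genes[keep].tolist()
    else:
        proteins = genes.tolist()
    sample_ids, conds = _sample_ids(config)
    directions = config.directions()

    base = math.log2(config.protein_baseline)
    sd = math.sqrt(math.log1p(config.protein_cv ** 2)) / math.log(2)
    shift = math.log2(config.protein_fold)

    per_protein = base + rng.normal(0.0, config.baseline_log2_sd, size=len(proteins))
    mean = np.tile(per_protein[:, None], (1, len(sample_ids)))
    p_index = {g: i for i, g in enumerate(proteins)}
    test_cols = [j for j, s in enumerate(sample_ids) if conds[s] == TEST]
    for g, d in directions.items():
        if g in p_index:
            mean[p_index[g], test_cols] += shift if d == "up" else -shift

    log2_vals = rng.normal(mean, sd)
    values = pd.DataFrame(np.exp2(log2_vals), index=proteins, columns=sample_ids)
    return OmicsMatrix(values=values, conditions=conds, kind="abundance")


def _name_allocation(config: SimulationConfig) -> dict:
    """Deterministic assignment of gene names to network positions.

    Planted genes are placed where the downstream analysis should find them:
    the first ``len(planted_modules)`` planted genes anchor the planted
    cliques, the next ``n_hub_genes`` sit on the highest-degree base nodes,
    and the remainder scatter over the base graph.
    """
    planted = list(config.planted_de_genes)
    k_mod = len(config.planted_modules)
    anchors = planted[:k_mod]
    hubs = planted[k_mod:k_mod + config.n_hub_genes]
    scattered = planted[k_mod + config.n_hub_genes:]
    module_extra = sum(size - 1 for size, _ in config.planted_modules)
    n_base_names = config.network_nodes - len(hubs) - len(scattered)
    if n_base_names < 0:
        raise ValidationError(
            "more planted genes than network nodes to place them on")
    pool = [g for g in config.gene_ids() if g not in set(planted)]
    if len(pool) < n_base_names + module_extra:
        raise ValidationError(
            "gene universe too small for the configured network and planted modules")
    return {
        "anchors": anchors,
        "hubs": hubs,
        "scattered": scattered,
        "pool": pool,
        "module_extra": module_extra,
    }


def simulate_ppi(config: SimulationConfig) -> tuple[nx.Graph, pd.DataFrame]:
    """Scale-free PPI with planted dense modules.

    The base graph is Barabasi-Albert preferential attachment (so the degree
    distribution is power-law-shaped); each planted module is a clique of new
    nodes anchored on a planted gene and attached to the base graph by
    exactly ``bridge_count`` edges from the anchor.

    Returns the graph and a node-role table (columns ``node``, ``role``,
    ``module_id``) used for truth bookkeeping.
    """
    rng = _rng(config, _STREAM_PPI)
    alloc = _name_allocation(config)

    base = nx.barabasi_albert_graph(config.network_nodes, config.attachment_m, seed=rng)
    degree_order = sorted(base.nodes(), key=lambda n: (-base.degree(n), n))

    # name assignment: hubs on top-degree nodes, scattered planted genes on
    # evenly spaced mid-ranked nodes, the rest from the pool in rank order
    names: dict[int, str] = {}
    for node, gene in zip(degree_order, alloc["hubs"]):
        names[node] = gene
    remaining_nodes = [n for n in degree_order if n not in names]
    if alloc["scattered"]:
        step = max(1, len(remaining_nodes) // len(alloc["scattered"]))
        taken = []
        for i, gene in enumerate(alloc["scattered"]):
            node = remaining_nodes[min(i * step, len(remaining_nodes) - 1)]
            names[node] = gene
            taken.append(node)
        remaining_nodes = [n for n in remaining_nodes if n not in set(taken)]
    pool = iter(alloc["pool"])
    for node in remaining_nodes:
        names[node] = next(pool)

    g = new_network(
        edges=((names[u], names[v]) for u, v in base.edges()),
        nodes=(names[n] for n in base.nodes()),
    )
    roles = {names[n]: "hub" if names[n] in set(alloc["hubs"]) else
             ("planted_base" if names[n] in set(alloc["scattered"]) else "background")
             for n in base.nodes()}
    module_id = {n: -1 for n in g.nodes()}

    base_nodes = list(g.nodes())
    for mod_i, ((size, bridges), anchor) in enumerate(
            zip(config.planted_modules, alloc["anchors"])):
        members = [anchor] + [next(pool) for _ in range(size - 1)]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(*sorted((members[i], members[j])))
        targets = rng.choice(len(base_nodes), size=bridges, replace=False)
        for t in targets:
            g.add_edge(*sorted((anchor, base_nodes[int(t)])))
        for m in members:
            roles[m] = "module_anchor" if m == anchor else "module_member"
            module_id[m] = mod_i
    role_table = pd.DataFrame(
        {"node": list(g.nodes()),
         "role": [roles[n] for n in g.nodes()],
         "module_id": [module_id[n] for n in g.nodes()]}
    ).sort_values("node").reset_index(drop=True)
    return g, role_table


def simulate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """GMT-style collection: one set enriched for planted genes, the rest uniform.

    The "true" set draws members without replacement with selection weight
    ``enrichment_odds`` for planted genes versus 1 for background genes, so
    odds = 1 reduces exactly to a uniform draw.
    """
    rng = _rng(config, _STREAM_GENESETS)
    genes = config.gene_ids()
    if not genes:
        raise ValidationError("gene universe is empty")
    planted = set(config.planted_de_genes)
    weights = np.array([config.enrichment_odds if g in planted else 1.0 for g in genes])
    weights = weights / weights.sum()

    coll = GeneSetCollection()
    true_members = rng.choice(len(genes), size=config.gene_set_size,
                              replace=False, p=weights)
    coll.add("planted_pathway", "synthetic set enriched for planted genes",
             sorted(genes[i] for i in true_members))
    for k in range(config.gene_set_count - 1):
        members = rng.choice(len(genes), size=config.gene_set_size, replace=False)
        coll.add(f"random_pathway_{k:03d}", "synthetic background set",
                 sorted(genes[i] for i in members))
    return coll


def simulate_truth(config: SimulationConfig, role_table: Optional[pd.DataFrame] = None
                   ) -> pd.DataFrame:
    """Planted-truth table: gene, planted flag, true direction, network role,
    module membership.  Consumed by evaluation code and tests only."""
    directions = config.directions()
    if role_table is None:
        _, role_table = simulate_ppi(config)
    roles = dict(zip(role_table["node"], role_table["role"]))
    modules = dict(zip(role_table["node"], role_table["module_id"]))
    rows = []
    for g in config.gene_ids():
        rows.append({
            "gene": g,
            "is_planted": g in directions,
            "true_direction": directions.get(g, "none"),
            "network_role": roles.get(g, "absent"),
            "module_id": modules.get(g, -1),
        })
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input plus the truth table."""
    ppi, role_table = simulate_ppi(config)
    return {
        "rna": simulate_rna_counts(config),
        "protein": simulate_protein_abundances(config),
        "ppi": ppi,
        "gene_sets": simulate_gene_sets(config),
        "truth": simulate_truth(config, role_table),
    }
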