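"""End-to-end orchestration: QC -> differential calls on both layers ->
direction-consistent intersection -> subnetwork construction -> topology and
rewiring null -> top-k prioritization -> module detection -> enrichment.

A run is fully reproducible from (config, inputs): one global seed fans out
to per-stage seeds through a fixed derivation, every stage parameter is
recorded verbatim in the run report, and floats are serialized at 12
significant digits so repeated runs are byte-identical.  Empty intermediate
results (e.g. an empty risk set) degrade gracefully into empty-but-valid
downstream reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import io as onio
from .datatypes import OmicsMatrix, RiskGeneSet, ValidationError, conditions_from_prefix
from .diffexpr import de_protein, de_rna, intersect_risk, replicate_correlation
from .enrich import enrich
from .modules import detect_modules
from .netbuild import extract_subnetwork
from .simulate import CONTROL, TEST, SimulationConfig, simulate_all
from .topology import NullEnsembleConfig, top_k_intersection, topology_report

logger = logging.getLogger(__name__)

# fixed per-stage seed derivation offsets
_SEED_SIM = 11
_SEED_NULL = 13


@dataclass
class PipelineConfig:
    """All knobs of a full run; see the CLI ``run-all`` verb."""

    outdir: str = "omicsnet_run"
    seed: int = 0
    # inputs: either a simulate block or file paths
    simulate: Optional[SimulationConfig] = None
    rna_path: Optional[str] = None
    protein_path: Optional[str] = None
    ppi_path: Optional[str] = None
    gmt_path: Optional[str] = None
    mapping_path: Optional[str] = None
    conditions: Optional[tuple[str, str]] = None   # (reference, test)
    # thresholds
    rna_p: float = 0.05
    rna_fc_up: float = 2.0
    rna_fc_down: float = 0.5
    protein_p: float = 0.05
    protein_fc_up: float = 1.5
    protein_fc_down: float = 2.0 / 3.0
    rna_qc_floor: float = 0.9
    protein_qc_floor: float = 0.5
    # network / topology
    induced: str = "edge"
    n_random: int = 1000
    swaps_per_edge: int = 10
    smoothed_p: bool = False
    top_k: int = 20
    # modules / enrichment
    module_lambda: float = 1.0
    module_min_size: int = 3
    enrichment_universe: str = "rna"   # "rna" | "network" | path to a gene list
    enrichment_q_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "planted_de_genes" in sim:
                sim["planted_de_genes"] = tuple(sim["planted_de_genes"])
            if "planted_modules" in sim:
                sim["planted_modules"] = tuple(tuple(x) for x in sim["planted_modules"])
            cfg.simulate = SimulationConfig(**sim)
        if cfg.conditions is not None:
            cfg.conditions = tuple(cfg.conditions)
        return cfg


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _jsonify(obj):
    """Deterministic JSON-ready structure (12 significant digits on floats)."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonify(v) for v in items]
    if isinstance(obj, float):
        return None if math.isnan(obj) else _round_sig(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonify(obj.item())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_inputs(config: PipelineConfig, outdir: Path) -> dict:
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(
            config.simulate, seed=int(np_seed(config.seed, _SEED_SIM)))
        data = simulate_all(sim_cfg)
        onio.write_matrix(data["rna"], outdir / "rna_counts.tsv")
        onio.write_matrix(data["protein"], outdir / "protein_abundance.tsv")
        onio.write_edge_list(data["ppi"], outdir / "ppi_edges.tsv")
        onio.write_gmt(data["gene_sets"], outdir / "gene_sets.gmt")
        data["truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)
        data["conditions"] = (CONTROL, TEST)
        data["mapping"] = None
        data["sim_config"] = sim_cfg
        return data
    for name in ("rna_path", "protein_path", "ppi_path"):
        if getattr(config, name) is None:
            raise ValidationError(f"config needs either a simulate block or {name}")
    rna = onio.read_matrix(config.rna_path, kind="counts")
    protein = onio.read_matrix(config.protein_path, kind="abundance")
    rna.conditions = conditions_from_prefix(rna.sample_ids)
    protein.conditions = conditions_from_prefix(protein.sample_ids)
    return {
        "rna": rna,
        "protein": protein,
        "ppi": onio.read_edge_list(config.ppi_path),
        "gene_sets": onio.read_gmt(config.gmt_path) if config.gmt_path else None,
        "mapping": onio.read_mapping(config.mapping_path) if config.mapping_path else None,
        "truth": None,
        "conditions": config.conditions,
        "sim_config": None,
    }


def np_seed(seed: int, offset: int) -> int:
    """Fixed per-stage seed derivation (stays below 2**31)."""
    return (seed * 1000003 + offset) % (2 ** 31 - 1)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``<outdir>/report.json`` along with every intermediate artifact)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _jsonify(dataclasses.asdict(config)),
                    "stages": {}}

    data = _load_inputs(config, outdir)
    conditions = data["conditions"]

    # --- QC ---------------------------------------------------------------
    qc = {}
    for layer, floor in (("rna", config.rna_qc_floor), ("protein", config.protein_qc_floor)):
        rep = replicate_correlation(data[layer], floor=floor)
        qc[layer] = {
            "min_within_condition": rep.min_within_condition,
            "flagged_conditions": rep.flagged_conditions,
            "undefined_samples": rep.undefined_samples,
            "floor": rep.floor,
        }
        rep.matrix.to_csv(outdir / f"qc_correlation_{layer}.tsv", sep="\t")
    report["stages"]["qc"] = qc

    # --- differential expression ------------------------------------------
    rna_de = de_rna(data["rna"], p_threshold=config.rna_p,
                    fc_up=config.rna_fc_up, fc_down=config.rna_fc_down,
                    conditions=conditions)
    prot_de = de_protein(data["protein"], p_threshold=config.protein_p,
                         fc_up=config.protein_fc_up, fc_down=config.protein_fc_down,
                         conditions=conditions)
    rna_de.to_csv(outdir / "de_rna.tsv", sep="\t", index=False)
    prot_de.to_csv(outdir / "de_protein.tsv", sep="\t", index=False)
    report["stages"]["de"] = {
        "rna": {"up": int((rna_de["direction"] == "up").sum()),
                "down": int((rna_de["direction"] == "down").sum()),
                "tested": len(rna_de)},
        "protein": {"up": int((prot_de["direction"] == "up").sum()),
                    "down": int((prot_de["direction"] == "down").sum()),
                    "tested": len(prot_de)},
    }

    # --- intersection ------------------------------------------------------
    risk, venn = intersect_risk(rna_de, prot_de, mapping=data["mapping"])
    with open(outdir / "risk_genes.tsv", "w") as fh:
        fh.write("gene\tdirection\n")
        for g in sorted(risk.members):
            fh.write(f"{g}\t{risk.members[g]}\n")
    write_json(venn.counts, outdir / "venn.json")
    report["stages"]["risk"] = {
        "up": len(risk.up), "down": len(risk.down), "total": len(risk),
        "venn": venn.counts,
    }

    # --- subnetwork ---------------------------------------------------------
    sub, sub_report = extract_subnetwork(data["ppi"], risk, induced=config.induced)
    onio.write_edge_list(sub, outdir / "subnetwork_edges.tsv")
    onio.write_sif(sub, outdir / "subnetwork.sif")
    report["stages"]["subnetwork"] = {
        "nodes": sub_report.n_nodes, "edges": sub_report.n_edges,
        "risk_in_network": sub_report.n_risk_in_network,
        "unmapped": sub_report.unmapped, "isolated": sub_report.isolated,
    }

    # --- topology + null ----------------------------------------------------
    candidates: list[str] = []
    if sub.number_of_nodes() == 0:
        report["stages"]["topology"] = {"empty": True}
        report["stages"]["candidates"] = {"empty": True, "genes": []}
    else:
        null_cfg = NullEnsembleConfig(
            n_random=config.n_random, swaps_per_edge=config.swaps_per_edge,
            seed=np_seed(config.seed, _SEED_NULL))
        topo = topology_report(
            sub, null_config=null_cfg if sub.number_of_edges() >= 2 else None,
            smoothed=config.smoothed_p)
        topo.per_node.to_csv(outdir / "topology_nodes.tsv", sep="\t")
        topo_json = {
            "global": dataclasses.asdict(topo.global_stats),
            "null": topo.null_summary,
            "powerlaw": dataclasses.asdict(topo.powerlaw) if topo.powerlaw else None,
            "risk_comparison": topo.risk_comparison.reset_index().to_dict("records")
            if topo.risk_comparison is not None else None,
        }
        write_json(topo_json, outdir / "topology.json")
        report["stages"]["topology"] = topo_json
        k = min(config.top_k, len(topo.per_node))
        topk = top_k_intersection(topo.per_node, k=k)
        candidates = topk.candidates
        report["stages"]["candidates"] = {
            "k": k, "genes": candidates,
            "boundary_ties": topk.boundary_ties,
            "top_lists": topk.top_lists,
        }

    # --- modules ------------------------------------------------------------
    if sub.number_of_nodes() == 0:
        report["stages"]["modules"] = {"count": 0, "modules": []}
    else:
        mods = detect_modules(sub, lam=config.module_lambda,
                              min_size=config.module_min_size)
        with open(outdir / "modules.tsv", "w") as fh:
            fh.write("module_id\tmember\twithin_module_degree\tis_driver\n")
            for m in mods.modules:
                for node in sorted(m.members):
                    wd = sum(1 for nb in sub.neighbors(node) if nb in m.members)
                    fh.write(f"{m.id}\t{node}\t{wd}\t{int(node in m.drivers)}\n")
        report["stages"]["modules"] = {
            "count": len(mods.modules),
            "lambda": mods.lam, "min_size": mods.min_size,
            "modules": [{"id": m.id, "size": len(m.members),
                         "internal_edges": m.internal_edges,
                         "boundary_edges": m.boundary_edges,
                         "drivers": m.drivers,
                         "members": sorted(m.members)} for m in mods.modules],
        }

    # --- enrichment ---------------------------------------------------------
    if data["gene_sets"] is None or len(risk) == 0:
        report["stages"]["enrichment"] = {"tested": 0, "significant": 0}
    else:
        if config.enrichment_universe == "rna":
            universe = set(data["rna"].feature_ids)
        elif config.enrichment_universe == "network":
            universe = set(data["ppi"].nodes())
        else:
            with open(config.enrichment_universe) as fh:
                universe = {line.strip() for line in fh if line.strip()}
        query = set(risk.members) & universe
        if not query:
            report["stages"]["enrichment"] = {"tested": 0, "significant": 0}
        else:
            enr = enrich(query, data["gene_sets"], universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["stages"]["enrichment"] = {
                "tested": len(enr),
                "significant": int((enr["q_value"] < config.enrichment_q_threshold).sum()),
                "top_set": enr.iloc[0]["set_name"] if len(enr) else None,
                "top_q": float(enr.iloc[0]["q_value"]) if len(enr) else None,
            }

    report["seed"] = config.seed
    write_json(report, outdir / "report.json")
    return report
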