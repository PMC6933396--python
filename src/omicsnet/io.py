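"""Readers and writers for every external format the pipeline touches.

Formats: tab-separated expression matrices (first column feature id, header
row of sample ids), two-column tab-separated edge lists (HPRD-style exports;
extra columns ignored), GMT gene-set files, SIF network export for viewer
compatibility, and small tab-separated mapping tables.  All readers validate
strictly and fail loudly; nothing is silently coerced.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (FormatError, GeneSetCollection, OmicsMatrix,
                        canonical_edge, new_network)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path: PathLike, kind: str,
                conditions: Optional[dict[str, str]] = None) -> OmicsMatrix:
    """Read a features x samples TSV matrix.

    ``kind="counts"`` rejects negative and non-integer entries;
    ``kind="abundance"`` rejects non-positive entries.  Ragged rows and
    duplicated ids are reported with the offending line number / id.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        sample_ids = [c.strip() for c in header[1:]]
        if not sample_ids:
            raise FormatError(f"{path}: header has no sample columns")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(row)}")
            fid = row[0].strip()
            if fid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            try:
                vals = [float(x) for x in row[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry ({exc})")
            if kind == "counts":
                for x in vals:
                    if x < 0:
                        raise FormatError(f"{path}:{lineno}: negative count {x:g}")
                    if x != int(x):
                        raise FormatError(f"{path}:{lineno}: non-integer count {x:g}")
            elif kind == "abundance":
                for x in vals:
                    if x <= 0:
                        raise FormatError(f"{path}:{lineno}: non-positive abundance {x:g}")
            else:
                raise FormatError(f"kind must be 'counts' or 'abundance', got {kind!r}")
            feature_ids.append(fid)
            rows.append(vals)
    dtype = np.int64 if kind == "counts" else float
    values = pd.DataFrame(np.asarray(rows, dtype=dtype),
                          index=feature_ids, columns=sample_ids)
    return OmicsMatrix(values=values, conditions=conditions, kind=kind)


def write_matrix(matrix: OmicsMatrix, path: PathLike) -> None:
    path = Path(path)
    df = matrix.values
    if matrix.kind == "counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Edge lists / networks
# ---------------------------------------------------------------------------

def read_edge_list(path: PathLike) -> nx.Graph:
    """Read a two-column tab-separated symbol edge list into a simple graph.

    Self-loops are dropped and duplicate pairs (in either order) collapsed,
    each with a logged count; the counts are also stored on the graph as
    ``g.graph["n_self_loops_dropped"]`` and ``g.graph["n_duplicates_dropped"]``.
    Extra columns beyond the first two are ignored (subsumes HPRD exports).
    """
    path = Path(path)
    g = new_network()
    n_loops = 0
    n_dups = 0
    n_edges = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: fewer than 2 columns")
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise FormatError(f"{path}:{lineno}: empty gene symbol")
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            e = canonical_edge(u, v)
            if g.has_edge(*e):
                n_dups += 1
            else:
                g.add_edge(*e)
            n_edges += 1
    if n_edges == 0 and n_loops == 0:
        raise FormatError(f"{path}: empty edge list")
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.info("%s: collapsed %d duplicate pair(s)", path, n_dups)
    g.graph["n_self_loops_dropped"] = n_loops
    g.graph["n_duplicates_dropped"] = n_dups
    return g


def write_edge_list(g: nx.Graph, path: PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(canonical_edge(u, v) for u, v in g.edges()):
            fh.write(f"{u}\t{v}\n")


def write_sif(g: nx.Graph, path: PathLike, relation: str = "pp") -> None:
    """SIF export (``nodeA\tpp\tnodeB``) for network viewers; isolated nodes
    are written as bare single-column lines per the SIF convention."""
    with open(path, "w") as fh:
        for u, v in sorted(canonical_edge(u, v) for u, v in g.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in sorted(n for n in g.nodes() if g.degree(n) == 0):
            fh.write(f"{n}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> GeneSetCollection:
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                name = parts[0] if parts else f"line {lineno}"
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            name, description = parts[0].strip(), parts[1].strip()
            members = [p.strip() for p in parts[2:] if p.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in coll.sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            coll.add(name, description, members)
    if not coll.sets:
        raise FormatError(f"{path}: empty GMT file")
    return coll


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            gs = collection[name]
            fh.write("\t".join([name, gs.description] + sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

def read_mapping(path: PathLike) -> dict[str, str]:
    """Two-column protein -> gene translation table."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: fewer than 2 columns")
            src, dst = parts[0].strip(), parts[1].strip()
            if src in mapping and mapping[src] != dst:
                raise FormatError(f"{path}:{lineno}: conflicting mapping for {src!r}")
            mapping[src] = dst
    return mapping
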