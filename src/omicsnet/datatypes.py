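"""Shared data carriers for the pipeline.

The in-memory containers are deliberately thin wrappers around the field's
standard objects: expression matrices are pandas DataFrames (features x
samples), networks are undirected ``networkx.Graph`` instances over gene
symbols, and gene sets are plain named sets.  Validation lives here so that
every stage can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A value or configuration violates a documented precondition."""


class FormatError(ValueError):
    """An external file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with per-sample condition labels.

    Parameters
    ----------
    values:
        DataFrame indexed by feature id with one column per sample.
        For ``kind="counts"`` entries must be non-negative integers; for
        ``kind="abundance"`` entries must be strictly positive reals.
    conditions:
        Mapping sample id -> condition name.  Two distinct conditions are
        required by the differential stages, not at construction time.
    kind:
        ``"counts"`` (RNA) or ``"abundance"`` (protein).
    """

    values: pd.DataFrame
    conditions: Optional[dict[str, str]] = None
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "abundance"):
            raise ValidationError(f"kind must be 'counts' or 'abundance', got {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError("matrix contains non-numeric entries")
            if self.kind == "counts":
                if np.any(arr < 0):
                    raise FormatError("counts matrix contains negative entries")
                if not np.allclose(arr, np.round(arr)):
                    raise FormatError("counts matrix contains non-integer entries")
            else:
                if np.any(arr <= 0):
                    raise FormatError("abundance matrix contains non-positive entries")
        if self.conditions is not None:
            missing = [s for s in cols if s not in self.conditions]
            if missing:
                raise ValidationError(f"samples without condition label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_pair(self, conditions: Optional[tuple[str, str]] = None) -> tuple[str, str]:
        """Return the (reference, test) condition pair.

        Defaults to the two distinct labels in sorted order; raise if the
        matrix does not carry exactly two conditions.
        """
        if self.conditions is None:
            raise ValidationError("matrix carries no condition labels")
        present = sorted(set(self.conditions[s] for s in self.sample_ids))
        if conditions is None:
            if len(present) != 2:
                raise ValidationError(f"expected exactly two conditions, found {present}")
            return (present[0], present[1])
        ref, test = conditions
        for c in (ref, test):
            if c not in present:
                raise ValidationError(f"condition {c!r} not present in matrix (has {present})")
        return (ref, test)

    def samples_of(self, condition: str) -> list[str]:
        if self.conditions is None:
            raise ValidationError("matrix carries no condition labels")
        return [s for s in self.sample_ids if self.conditions[s] == condition]


def conditions_from_prefix(sample_ids: Iterable[str], sep: str = "_") -> dict[str, str]:
    """Infer condition labels from sample names of the form ``<cond>_<rep>``."""
    out = {}
    for s in sample_ids:
        if sep not in s:
            raise ValidationError(f"sample id {s!r} has no {sep!r} separator to infer a condition")
        out[s] = s.rsplit(sep, 1)[0]
    return out


# ---------------------------------------------------------------------------
# Differential expression results and the risk-gene set
# ---------------------------------------------------------------------------

DE_COLUMNS = ["feature_id", "fold_change", "statistic", "p_value", "q_value", "direction"]


@dataclass
class RiskGeneSet:
    """Genes called in the same direction at both the RNA and protein level."""

    members: dict[str, str] = field(default_factory=dict)  # gene -> "up" | "down"

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.members.items() if d not in ("up", "down")}
        if bad:
            raise ValidationError(f"risk directions must be 'up' or 'down': {bad}")

    @property
    def up(self) -> set[str]:
        return {g for g, d in self.members.items() if d == "up"}

    @property
    def down(self) -> set[str]:
        return {g for g, d in self.members.items() if d == "down"}

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical stored form of an unordered pair (lexicographic)."""
    return (u, v) if u <= v else (v, u)


def new_network(edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()) -> nx.Graph:
    """Build a validated simple undirected graph over gene symbols."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u == v:
            raise ValidationError(f"self-loop on {u!r} not allowed")
        g.add_edge(*canonical_edge(u, v))
    return g


def validate_network(g: nx.Graph) -> nx.Graph:
    if g.is_directed() or g.is_multigraph():
        raise ValidationError("network must be a simple undirected graph")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValidationError(f"network contains self-loops: {loops[:3]}")
    return g


def risk_nodes(g: nx.Graph) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("is_risk", False)}


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.sets.items():
            if not s.members:
                raise ValidationError(f"gene set {name!r} has no members")

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene set name {name!r}")
        gs = GeneSet(description=description, members=frozenset(members))
        if not gs.members:
            raise ValidationError(f"gene set {name!r} has no members")
        self.sets[name] = gs

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]
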