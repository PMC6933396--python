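"""Hypergeometric over-representation analysis with BH correction.

A local, deterministic replacement for web enrichment services: for each
gene set S (intersected with an explicit universe U) and query list Q, the
p-value is the upper tail P(X >= |Q ∩ S|) of the hypergeometric distribution
with population |U|, successes |S ∩ U| and draws |Q|.  Only
over-representation is tested.  Benjamini-Hochberg q-values are computed
across all tested sets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, ValidationError

ENRICH_COLUMNS = ["set_name", "universe_size", "set_size", "query_size",
                  "overlap", "p_value", "q_value", "overlap_members"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper(overlap: int, universe_size: int, set_size: int,
                    query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def enrich(query: Iterable[str], collection: GeneSetCollection,
           universe: Iterable[str]) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``collection``.

    Requires query ⊆ universe; every set is intersected with the universe
    before testing.  Rows are sorted by p-value ascending then set name.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("universe is empty")
    if not query:
        raise ValidationError("query is empty")
    outside = query - universe
    if outside:
        raise ValidationError(
            f"query genes outside the universe: {sorted(outside)[:5]}")

    rows = []
    for name in collection.names():
        members = set(collection[name].members) & universe
        overlap = query & members
        p = hypergeom_upper(len(overlap), len(universe), len(members), len(query))
        rows.append({
            "set_name": name,
            "universe_size": len(universe),
            "set_size": len(members),
            "query_size": len(query),
            "overlap": len(overlap),
            "p_value": p,
            "overlap_members": ",".join(sorted(overlap)),
        })
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return df[ENRICH_COLUMNS]
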