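"""Differential calling on each omics layer and the dual-omics intersection.

RNA counts are normalized by median-of-ratios size factors and tested with a
Welch two-sample t-test on log2(normalized count + 1); the fold change is the
ratio of condition means of normalized counts with a pseudocount of 0.5.
Protein abundances are tested with a Welch t-test on log2 abundances; the
fold change is the ratio of condition geometric means.  A feature is called
"up" when it passes both the upper fold-change gate and the p-value gate
(symmetrically "down"); features passing neither are "none".  Raw p-values
gate the calls (BH q-values are reported alongside).

The high-risk gene set is the direction-consistent intersection: a gene is a
member iff it is called in the same direction at both the RNA and the
protein level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DE_COLUMNS, OmicsMatrix, RiskGeneSet, ValidationError
from .enrich import bh_adjust

PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Replicate-correlation QC
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    matrix: pd.DataFrame                    # sample x sample Pearson r
    min_within_condition: dict[str, float]  # condition -> min off-diagonal r
    flagged_conditions: list[str]
    undefined_samples: list[str]            # zero-variance samples
    floor: float


def replicate_correlation(matrix: OmicsMatrix, floor: Optional[float] = None
                          ) -> CorrelationReport:
    """Sample-sample Pearson correlations with a within-condition QC floor.

    Counts are correlated on the log2(count + 1) scale, abundances on log2
    abundance.  Default floors: 0.9 for counts, 0.5 for abundances.  A
    zero-variance sample yields undefined correlations: it is flagged and its
    entries reported as NaN, never silently dropped.
    """
    if floor is None:
        floor = 0.9 if matrix.kind == "counts" else 0.5
    conds = matrix.conditions
    if conds is None:
        raise ValidationError("matrix carries no condition labels")
    for c in sorted(set(conds.values())):
        if len(matrix.samples_of(c)) < 2:
            raise ValidationError(f"condition {c!r} has fewer than 2 samples")

    x = matrix.values.to_numpy(dtype=float)
    x = np.log2(x + 1.0) if matrix.kind == "counts" else np.log2(x)
    samples = matrix.sample_ids
    sd = x.std(axis=0)
    undefined = [s for s, v in zip(samples, sd) if v == 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    for s in undefined:
        j = samples.index(s)
        corr[j, :] = np.nan
        corr[:, j] = np.nan
        corr[j, j] = 1.0
    cm = pd.DataFrame(corr, index=samples, columns=samples)

    min_within: dict[str, float] = {}
    flagged: list[str] = []
    for c in sorted(set(conds.values())):
        ss = matrix.samples_of(c)
        vals = [cm.loc[a, b] for i, a in enumerate(ss) for b in ss[i + 1:]]
        m = float(np.nanmin(vals)) if vals and not all(np.isnan(vals)) else float("nan")
        min_within[c] = m
        if np.isnan(m) or m < floor:
            flagged.append(c)
    return CorrelationReport(matrix=cm, min_within_condition=min_within,
                             flagged_conditions=flagged,
                             undefined_samples=undefined, floor=floor)


# ---------------------------------------------------------------------------
# Size factors and the Welch test
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (per sample).

    Ratios are taken against the per-gene geometric mean over genes with all
    counts positive; if no such gene exists all factors are 1.
    """
    arr = counts.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        return pd.Series(1.0, index=counts.columns)
    log_ref = np.log(arr[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(arr[positive]) - log_ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value (test - reference).

    Zero pooled variance (both groups constant): returns (0, 1) when the
    means are equal, otherwise the difference is deterministic and p -> 0 is
    avoided by the fold-change gate carrying the call; we still return p = 1
    and statistic 0 because a constant feature carries no t-test evidence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch test requires >= 2 replicates per condition")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 0.0, 1.0
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (vx ** 2 / (len(x) ** 2 * (len(x) - 1))
                     + vy ** 2 / (len(y) ** 2 * (len(y) - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def _call_direction(fc: float, p: float, p_threshold: float,
                    fc_up: float, fc_down: float) -> str:
    if p <= p_threshold and fc >= fc_up:
        return "up"
    if p <= p_threshold and fc <= fc_down:
        return "down"
    return "none"


def _de_table(log2_vals: np.ndarray, fold: np.ndarray, features: list[str],
              p_threshold: float, fc_up: float, fc_down: float,
              ref_cols: list[int], test_cols: list[int]) -> pd.DataFrame:
    stats_p = np.empty((len(features), 2))
    for i in range(len(features)):
        stats_p[i] = welch_t(log2_vals[i, test_cols], log2_vals[i, ref_cols])
    q = bh_adjust(stats_p[:, 1])
    direction = [_call_direction(f, p, p_threshold, fc_up, fc_down)
                 for f, p in zip(fold, stats_p[:, 1])]
    return pd.DataFrame({
        "feature_id": features,
        "fold_change": fold,
        "statistic": stats_p[:, 0],
        "p_value": stats_p[:, 1],
        "q_value": q,
        "direction": direction,
    })[DE_COLUMNS]


def _split_columns(matrix: OmicsMatrix, conditions: Optional[tuple[str, str]]
                   ) -> tuple[list[int], list[int]]:
    ref, test = matrix.condition_pair(conditions)
    samples = matrix.sample_ids
    ref_cols = [samples.index(s) for s in matrix.samples_of(ref)]
    test_cols = [samples.index(s) for s in matrix.samples_of(test)]
    if len(ref_cols) < 2 or len(test_cols) < 2:
        raise ValidationError("each condition needs >= 2 replicates for the t-test")
    return ref_cols, test_cols


def de_rna(matrix: OmicsMatrix, p_threshold: float = 0.05,
           fc_up: float = 2.0, fc_down: float = 0.5,
           conditions: Optional[tuple[str, str]] = None) -> pd.DataFrame:
    """Per-gene differential expression on RNA counts.

    Fold change = (mean normalized count in test + 0.5) / (same in reference
    + 0.5); Welch t on log2(normalized count + 1).  Default gates follow the
    conventional RNA thresholds: p <= 0.05 and fold >= 2 or <= 1/2.
    """
    if matrix.kind != "counts":
        raise ValidationError(f"de_rna expects a counts matrix, got kind={matrix.kind!r}")
    ref_cols, test_cols = _split_columns(matrix, conditions)
    sf = size_factors(matrix.values).to_numpy()
    norm = matrix.values.to_numpy(dtype=float) / sf[None, :]
    fold = ((norm[:, test_cols].mean(axis=1) + PSEUDOCOUNT)
            / (norm[:, ref_cols].mean(axis=1) + PSEUDOCOUNT))
    log2n = np.log2(norm + 1.0)
    return _de_table(log2n, fold, matrix.feature_ids,
                     p_threshold, fc_up, fc_down, ref_cols, test_cols)


def de_protein(matrix: OmicsMatrix, p_threshold: float = 0.05,
               fc_up: float = 1.5, fc_down: float = 2.0 / 3.0,
               conditions: Optional[tuple[str, str]] = None) -> pd.DataFrame:
    """Per-protein differential expression on abundances.

    Welch t on log2 abundances; fold change = ratio of condition geometric
    means.  Default gates: p <= 0.05 and fold >= 3/2 or <= 2/3.
    """
    if matrix.kind != "abundance":
        raise ValidationError(f"de_protein expects an abundance matrix, got kind={matrix.kind!r}")
    ref_cols, test_cols = _split_columns(matrix, conditions)
    log2a = np.log2(matrix.values.to_numpy(dtype=float))
    fold = np.exp2(log2a[:, test_cols].mean(axis=1) - log2a[:, ref_cols].mean(axis=1))
    return _de_table(log2a, fold, matrix.feature_ids,
                     p_threshold, fc_up, fc_down, ref_cols, test_cols)


# ---------------------------------------------------------------------------
# Dual-omics intersection
# ---------------------------------------------------------------------------

@dataclass
class IntersectionReport:
    """Venn bookkeeping for the direction-consistent intersection."""
    counts: dict = field(default_factory=dict)


def intersect_risk(rna: pd.DataFrame, protein: pd.DataFrame,
                   mapping: Optional[dict[str, str]] = None
                   ) -> tuple[RiskGeneSet, IntersectionReport]:
    """Direction-consistent intersection of the two DE tables.

    A gene enters the risk set iff its RNA call and its (optionally mapped)
    protein call are both "up" or both "down".  The report carries, per
    direction, the sizes of the RNA-only / protein-only / intersection
    partitions plus discordant calls.
    """
    rna_dir = dict(zip(rna["feature_id"], rna["direction"]))
    prot_dir: dict[str, str] = {}
    for pid, d in zip(protein["feature_id"], protein["direction"]):
        gene = mapping.get(pid, pid) if mapping else pid
        prot_dir[gene] = d

    members = {g: d for g, d in rna_dir.items()
               if d != "none" and prot_dir.get(g) == d}
    counts: dict = {}
    for d in ("up", "down"):
        rna_set = {g for g, x in rna_dir.items() if x == d}
        prot_set = {g for g, x in prot_dir.items() if x == d}
        counts[d] = {
            "rna": len(rna_set),
            "protein": len(prot_set),
            "both": len(rna_set & prot_set),
            "rna_only": len(rna_set - prot_set),
            "protein_only": len(prot_set - rna_set),
        }
    counts["discordant"] = sum(
        1 for g, d in rna_dir.items()
        if d != "none" and prot_dir.get(g, "none") != "none" and prot_dir[g] != d)
    return RiskGeneSet(members=members), IntersectionReport(counts=counts)
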