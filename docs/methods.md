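# Methods

## Overview

`omicsnet` implements a two-condition multi-omics prioritization workflow:
differential calls on RNA counts and protein abundances are intersected
into a direction-consistent "high-risk" gene set, that set's interaction
neighbourhood is cut out of a global PPI, and genes are prioritized by
network topology against a degree-conserved random-graph null, with
edge-clustering module detection and hypergeometric gene-set enrichment
downstream.  Everything is deterministic given a seed.

## Differential expression

RNA counts are normalized by median-of-ratios size factors (the reference
is the per-gene geometric mean over genes with all counts positive; all
factors are 1 when no such gene exists).  The per-gene test is a Welch
two-sample *t* on log2(normalized count + 1) — a deliberate choice of a
closed-form, oracle-testable engine over a shrinkage-based count model: the
workflow's substance is in its thresholds and the intersection rule, not in
the DE engine, and a formula-level test lets the suite verify p-values to
1e-10.  The fold change is (mean normalized count in test + ½) / (same in
reference + ½); the pseudocount keeps folds finite on dropout genes.
Proteins use the same Welch test on log2 abundance with the fold as the
ratio of geometric means.  Gates: RNA *p* ≤ 0.05 with fold ≥ 2 or ≤ 1/2;
protein *p* ≤ 0.05 with fold ≥ 3/2 or ≤ 2/3.  Gates act on raw p-values;
BH q-values are reported alongside but do not gate by default.  All gates
are configurable.  Features whose two groups are both constant get
*p* = 1, statistic 0 and direction `none`: a constant feature carries no
*t*-test evidence.  Condition order is always explicit
(reference, test); fold = test / reference.

The high-risk set is the intersection: a gene is a member iff RNA and
(optionally id-mapped) protein calls are equal and not `none`.  The report
keeps the per-direction Venn partitions and the count of discordant calls.

## Replicate QC

Sample-sample Pearson correlations are computed on log2(count + 1) (RNA) or
log2 abundance (protein), with configurable within-condition floors
(defaults 0.9 / 0.5).  A zero-variance sample yields NaN correlations and
is flagged, never dropped.  Note that informative replicate correlations
require gene-level dynamic range: with the generator's default flat
baselines the correlation across genes is pure noise, so QC demonstrations
should set `baseline_log2_sd` > 0 (see below).

## Subnetwork construction

The risk subnetwork is **edge-induced**: it keeps every PPI edge with at
least one risk endpoint; partner-partner edges are excluded.  This is the
single most consequential interpretation in the pipeline, so a
node-induced alternative (`induced="node"`: risk genes + partners with all
edges among them) is provided for sensitivity analysis.  Risk genes with
no PPI partner are excluded from the graph (a degree-0 node breaks
closeness conventions) but always listed in the report, as are risk genes
absent from the PPI.

## Topology statistics and the null ensemble

Per node: degree; exact Brandes betweenness, unnormalized, each unordered
pair counted once (only ranks feed the top-k step, and normalization is
rank-invariant); closeness per connected component scaled by
(n_c − 1)/(n − 1) so values are comparable across components of the
typically disconnected subnetwork (isolated nodes get 0).

Global: average path length over reachable unordered pairs only (flagged
undefined when no pair is reachable) and global transitivity
3 × triangles / connected triples.

The null ensemble holds the degree sequence fixed: each replicate applies
`swaps_per_edge × |E|` attempted double-edge swaps
((a,b),(c,d) → (a,d),(c,b) or (a,c),(b,d)), rejecting proposals that
create self-loops or duplicate edges.  `swaps_per_edge` defaults to 10, a
common mixing heuristic for swap chains.  Replicate *i* is a deterministic
function of (seed, *i*), so ensembles can be regenerated piecewise.  On
graphs with no legal swap (e.g. a triangle) the replicate equals the input
and a warning is logged.  The empirical p-value follows the strict
convention p = #{null > observed}/N; because p = 0 is statistically
improper, a smoothed estimator (1 + #{null ≥ observed})/(N + 1) is
available and is the one whose null distribution is uniform by
construction (verified in the acceptance suite).  The default ensemble
size is N = 1000.

The scale-free check is a least-squares fit of log₁₀ P(k) against log₁₀ k
over observed degrees ≥ 1; it is a fit-shaped diagnostic, not a rigorous
maximum-likelihood power-law test (out of scope by design).

Risk-vs-background comparisons use a two-sided Mann–Whitney *U* per
centrality against **all** non-risk nodes.  The p-value is computed by
full enumeration of group labelings when the labeling space is enumerable
(C(n1+n2, n1) ≤ 20 000, i.e. both groups ≲ 8) and otherwise by the normal
approximation with midrank tie correction and continuity correction.  At
group sizes below ~5 the normal approximation deviates from the exact tail
by more than 0.02 regardless of implementation, which is why those sizes
are always enumerated.

Candidates are the intersection of the top-k (default 20) lists for
degree, closeness and betweenness, restricted to risk-flagged nodes when
any exist.  Ranking ties at the k-boundary are flagged and resolved
lexicographically — silent tie-dropping would make results seed-dependent.

## Module detection

The edge clustering coefficient of (u,v) is z/min(deg u − 1, deg v − 1)
with z the number of triangles on the edge; a degree-1 endpoint gives
ECC = 0, which keeps pendant edges from seeding modules.  Detection is
agglomerative: edges sorted by descending ECC (ties: larger z, then
lexicographic edge id) merge their clusters unless both are already locked
modules; a cluster locks once internal edges ≥ λ × boundary edges
(λ = 1) and size ≥ `min_size` (3).  Edges with ECC = 0 never trigger
merges: they carry no triangle evidence, and allowing them would
eventually glue every connected component into one trivially "dense"
cluster with zero boundary — with the zero-ECC exclusion a tree yields no
modules at all, and a planted clique attached by triangle-free bridges is
recovered exactly.  The emitted module list is deterministic, its modules
are disjoint, and each satisfies its lock criterion as recomputable from
the input graph.  Drivers are members with within-module degree
≥ ½(size − 1), at least the top-ranked member, ties kept together — the
simplest rule consistent with hub-centred module drawings; it is a
package convention, not a community standard.

## Synthetic data generator

The generator emulates the study design end-to-end so each stage can be
scored against planted truth:

- **Design**: two conditions ("control", "glaucoma") × 3 replicates.
- **RNA**: negative binomial with var = μ + φμ², baseline mean 100,
  dispersion φ = 0.1; per-sample size factors log-uniform in [0.7, 1.4] so
  normalization is actually exercised.  Planted genes shift the test
  condition mean by ×4 (up) or ÷4 (down).
- **Protein**: log-normal; log2 values Gaussian with
  σ = sqrt(ln(1 + cv²))/ln 2 at cv = 0.1, planted shift ±log2(2).
  A detection-dropout fraction (default 0) can remove proteins from the
  observed universe.
- **Baselines**: flat by default (every feature at the same baseline), the
  simplest condition under which planted folds are interpretable.
  `baseline_log2_sd` adds gene-level dynamic range (log-normal) for
  demonstrations that need realistic between-gene spread, e.g. replicate
  QC.
- **PPI**: Barabási–Albert preferential attachment (m = 2, 1000 nodes) —
  chosen solely to give the scale-free degree distribution the topology
  stage checks — plus two planted 8-cliques, each a set of new nodes
  anchored on a planted gene and tied to the base graph by exactly one
  bridge edge.  Eight planted genes sit on the highest-degree base nodes
  ("hubs"), the rest scatter over mid-ranked nodes.
- **Gene sets**: one set drawn with 9:1 selection odds for planted genes
  (odds 1 reduces exactly to uniform) plus 49 uniform background sets,
  GMT-serializable.
- **Truth table**: gene → planted flag, true direction, network role,
  module id; consumed only by evaluation code and tests.

What the generator does **not** model: read-level or spectrum-level data,
isoform structure, batch effects beyond size factors, correlated
expression between interacting genes, and identifier ambiguity.  Passing
tests therefore demonstrate the pipeline's correctness and calibration
under a clean planted-signal model, not robustness to real-data artefacts.

Determinism: every generator output is a pure function of its config; each
generator draws from its own fixed sub-stream of the seed, so e.g. the PPI
is unchanged when only protein parameters change.

## Problem sizes

The shipped verification suite runs the study conditions at: 2 000 genes /
100 planted for DE-recovery checks; 1 000-node interactomes for module
recovery (50 seeds) and 500-node interactomes for hub recall (20 seeds);
1 000 rewired replicates of a 500-node graph for null invariants; 200
trials × 99 null draws on a 60-node graph for empirical-p calibration; and
N = 200 nulls in the end-to-end script's empirical p-values.  These sizes
make each property measurable with comfortable margins while keeping a
full run on one core in minutes; all of them scale up by config.

## Known limitations

- The Welch-on-log2 engine is not a negative-binomial test: at 3 vs 3 its
  null p-values are only approximately uniform (Welch–Satterthwaite df
  estimation), measured KS ≈ 0.03 at 5 000 features.
- With heavy ties the Mann–Whitney exact two-sided p uses the symmetric
  deviation convention P(|U − μ| ≥ |u_obs − μ|), which can differ from
  doubling the smaller tail.
- The edge-induced subnetwork contains triangles only where risk genes are
  adjacent, so module detection on it is conservative; planted-module
  recovery is assessed on the full interactome.
- Gene symbols are matched case-sensitively after whitespace trimming;
  silent case-folding can merge distinct identifiers.  Protein-to-gene
  translation is by identity unless a two-column mapping file is given.
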