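# Methods

This note records the models and procedures the package implements, the
conventions and defaults it fixes where the underlying methods admit
choices, what the synthetic-data generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Normalization

**Median-of-ratios with a tunable inclusion criterion.** The classic
median-of-ratios estimator divides each sample's counts by a pseudo-sample
reference (the per-gene geometric mean across samples) and takes the
per-sample median of those ratios. It is undefined whenever every gene has
at least one zero — the usual situation in single-cell data. The
implementation generalizes it with one parameter, `min_detect_frac`
*f* ∈ (0, 1]:

- gene *i* is included iff it has positive counts in ≥ ⌈*f·m*⌉ of *m*
  samples;
- its reference *rᵢ* is the geometric mean of its **positive** counts only;
- sample *j*'s raw factor is the median of *k_{ij}/rᵢ* over included genes
  with *k_{ij}* > 0;
- raw factors are rescaled to geometric mean 1.

With *f* = 1 and a zero-free matrix every branch reduces to the classic
formula (verified against an independent implementation in the tests).
Geometric means over positive counts only, per-sample medians over positive
ratios only, and the ceiling in the threshold are deliberate: they keep the
estimator defined on sparse matrices, which is its reason to exist. An
alternative convention (geometric mean over all samples, zeros included)
would zero out every reference; requiring ratios for all samples would
reintroduce the classic estimator's failure mode.

Errors are actionable: if no gene passes inclusion the message suggests
lowering *f*; if a sample has no positive count among included genes the
sample is named.

**TMM.** The reference sample is the one whose upper quartile of positive
counts is closest to the mean upper quartile. For sample *g* against
reference *r*, over genes positive in both: M = log₂ of the ratio of
library-size-scaled proportions, A = the mean log abundance, and weights
are the inverse delta-method variances
1/((N_g−k_g)/(N_g k_g) + (N_r−k_r)/(N_r k_r)). Genes in the top or bottom
`trim_m` = 0.30 fraction by M-rank or `trim_a` = 0.05 fraction by A-rank
(average ranks; both tails) are dropped; the TMM component is
2^(Σ wM / Σ w) over survivors; the raw size factor is the component times
the library size. If fewer than 10 genes survive trimming the function
warns and uses the untrimmed weighted mean. Trim fractions follow the
method's customary defaults; the component is exposed in
`SizeFactors.params["tmm_component"]` because "component = 1 under pure
library scaling" is the method's defining sanity check.

**Upper quartile, spike-in, per-value, quantile.** Upper-quartile raw
factors are the 75th percentile of each sample's positive counts, with
linear (type-7) interpolation — stated because Q75 conventions differ.
Spike-in factors are median-of-ratios (*f* = 1) on the spike submatrix
only (≥ 2 spike features required), then applied to the whole matrix:
spike-ins are present at nominally equal amounts everywhere, so their
ratios isolate technical depth. CPM/RPKM/TPM use the standard formulas
(TPM normalizes length-corrected rates to a 10⁶ column sum). Quantile
normalization is the classic rank-mean procedure; within-column ties
receive the mean of their rank-means, so the "identical sorted columns"
and idempotence identities are exact on tie-free data and approximate in
the presence of ties.

**Scale convention.** All size factors are rescaled to geometric mean 1 so
methods are comparable. A consequence worth stating: multiplying one of
*m* columns by *c* moves every geometric-mean-based reference by *c*^(1/m),
so the *exact* invariant for median-of-ratios and spike-in factors is on
ratios — the scaled sample gains a factor *c* relative to every other
sample (for two samples: factors (1/√c̄, √c̄) given equal start). The
literal "raw factor scales by *c*, others untouched" holds for the
upper-quartile estimator, whose reference is internal to each column.

## The data map

Nodes are derived datasets; edges carry `OperationRecord`s (operation name,
JSON-serializable parameters, timestamp). The graph is a tree except at
merge nodes, which take one parent per merged dataset. Supported recorded
operations — normalize, filter_features, filter_samples, subset, merge —
are all deterministic functions of their parameters, so any node replays
exactly from the root (`DataMap.replay`); this is asserted matrix-for-matrix
in the tests. Choices the design left open:

- **Eager re-analysis.** Switching the active node re-runs every registered
  recipe immediately and attaches fresh reports to that node. Eager
  execution costs time on switch but guarantees reports are never stale;
  recipes are global to the map, without per-node parameter overrides.
- **Failure reports.** A recipe whose preconditions fail on the new node
  (for example, the DE groups reduced to one condition by a sample filter)
  produces a report with `ok=False` and the reason, never an exception —
  node switching must not abort a session.
- **Cascade deletion.** Deleting a node removes its whole descendant
  closure: a child is defined only relative to its parent's data. The
  closure is cross-checked against an independent breadth-first
  reachability search in the tests. The root is undeletable; if the active
  node is deleted, the root becomes active.
- **Deterministic node IDs** ("n0", "n1", …) keep lineage tables and
  archives reproducible across runs.
- **Merges of colliding sample IDs are rejected**, not auto-suffixed:
  silent renaming would corrupt the sample ↔ design correspondence.

## Session archives

A session saves to one zip file: a JSON manifest (format version, graph
structure, operation records, recipes) plus one TSV payload per node
matrix and the markdown/TSV payloads of each report. Payloads are
SHA-256-checksummed and verified on load; the format version is checked.
Matrices are written with 17-significant-digit formatting and parsed with
correctly-rounded float conversion, so float64 values survive exactly;
zip member timestamps are frozen and members are written in sorted order.
Consequently save → load → save is byte-identical (given a frozen clock
for the map's own timestamps, which is injectable) and every report
number is recomputable from the archive alone via replay.

## Differential expression

Per-gene two-sided Mann-Whitney U between two groups (each ≥ 2 samples),
run on normalized values — rank tests are invariant to monotone
transforms, so normalized vs log-normalized input is cosmetic. Conventions
fixed for reproducibility:

- exact null enumeration when both groups have ≤ 8 samples and the gene's
  values are tie-free; otherwise the normal approximation with tie
  correction and continuity correction;
- U is reported for the first (lexicographically) group; genes constant
  across all samples get p = 1 and U = n_A·n_B/2;
- log₂ fold change uses pseudocount 1 on the group means;
- multiplicity is controlled with Benjamini-Hochberg (recorded in every
  report), the standard FDR choice for exploratory gene ranking.

**Calibration at small n.** The U statistic is discrete: at 5 vs 5 the
two-sided rejection region at α = 0.05 is U ≤ 2 or U ≥ 23, with exact null
mass 8/252 ≈ 0.032. The raw rejection rate therefore sits *below* the
nominal level at such sizes — the test is conservative, never inflated —
and no implementation of an exact rank test can place that rate inside a
tight two-sided band around 0.05. Ties and zeros (the asymptotic
tie-corrected path) push the rate lower still. The suite asserts
one-sided control (never exceeding nominal) plus realized FDR ≤ 0.10 on
mixed fixtures.

**Power fixture.** The sensitivity regression guard (planted |log₂FC| = 2,
10 vs 10, BH 0.05, sensitivity > 0.8) runs on a well-expressed, dropout-free
configuration (`mean_log_mu=4`, `dropout=False`, `effect_sigma=0`). Its
purpose is to catch regressions in the test/adjustment/ranking pipeline,
which requires a fixture where a correct rank test actually has that
power; under the sparse single-cell default most planted genes are below
detectability at n = 10 and no rank test recovers 80% of them. The sparse
default remains the fixture for the conservatism and FDR checks, where it
is the harder case.

## TF influence scoring

Gene scores combine effect size and significance:
G = |log₂FC| · (−log₁₀ max(p_adj, p_floor)) by default (options: either
factor alone), with p_floor = 1e-300 keeping scores finite. The score
formulas and the three influence options are this package's codification
of "score by p-value and fold change, then aggregate over the direct
neighborhood" — the aggregation family is standard, but the exact
formulas are conventions fixed here. Influence uses **direct (1-step)
neighborhoods** only — out-neighbors in a directed regulatory network, all
neighbors in an undirected association network; multi-level neighborhoods
are a possible extension hook. `degree_normalized` divides each neighbor's
score by its (in-)degree so that a gene regulated by many TFs does not
credit each of them fully; the resulting credit conservation (Σ_t(S_t −
G_t) equals the in-degree-fraction-weighted score mass) is verified by a
brute-force double loop in the tests. Ranks break ties by center score,
then gene name. Gene symbols match case-sensitively; DE genes absent from
the network are ignored with a logged count. Self-loops are dropped on
load; duplicate edges collapse.

## Synthetic data generator

`simulate_counts` draws counts k_{ij} ~ ZINB with mean s_j·µ_i·2^{β_i·x_j}
and NB dispersion φ (var = m + φm²; φ = 0 gives Poisson), where µ_i is
log-normal(`mean_log_mu`=2.0, `mean_log_sigma`=1.5), s_j is
log-normal(0, `sigma_s`=0.5) rescaled to geometric mean 1, x_j ∈ {0,1} is
the condition, and a fraction `de_frac`=0.1 of genes carries signed
log₂ effects ~ ±N(`effect_mu`=2.0, `effect_sigma`=0.5). Zero-inflation is
logistic in log mean, P(drop) = logistic(a − b·log m) with a = 1.5,
b = 1.0 — low-expressed genes drop out most, mimicking single-cell
capture. Spike-in rows (optional) have fixed known concentrations spanning
~2⁷, scale with s_j only, and receive neither DE nor dropout. Defaults
describe a modest sparse single-cell experiment (2000 genes × 20 cells,
two balanced conditions, ~40% zeros at the median gene).

What the generator does **not** emulate — hence what passing tests do not
show about real data: batch effects and other structured unwanted
variation, gene–gene correlation (counts are independent across genes
given the factors), amplification noise beyond the NB, UMI saturation,
multimodal expression within a condition, and any specific published
dataset. Parameter-recovery and FDR results on this generator demonstrate
correctness of the estimators under their own model assumptions, not
robustness to violations of them.

`simulate_network` builds a directed TF→target graph (each TF regulates 5
random targets by default). With `planted_tf`, the first TF's targets
receive dominant scores and the TF the highest center score, making rank 1
under every influence option the unique correct answer — the recovery
fixture for the scoring module.

## Problem sizes and tolerances

The test-suite and acceptance-script problem sizes (50×4 oracle matrices,
2000×20 recovery and calibration fixtures, 10 FDR seeds, 200 enumeration
instances, 1000 BH vectors, 100 monotonicity perturbations) were chosen as
the smallest sizes at which each property is statistically meaningful;
the whole suite runs in a few seconds. Exact-arithmetic comparisons use
1e-9–1e-12 tolerances; statistical assertions state their bounds inline
(binomial 99% bands, FDR ≤ 0.10, r ≥ 0.95, sensitivity > 0.8).

## Known limitations

- Cook's-distance sample filtering requires fitted per-gene GLMs and is
  out of scope; quality filters cover totals, detected genes, dropout and
  size-factor ranges plus explicit lists.
- Only the Mann-Whitney DE path is implemented; count-model DE (DESeq2,
  edgeR and kin), multi-factorial designs, and external normalizations
  (RUVg, Census, spike-in regression) are deliberately not wrapped.
- The data map holds all node matrices in memory; very large sessions
  should prune with `delete_node`.
- Quantile normalization's defining identities are exact only on tie-free
  data (see above).
- Networks are user-supplied edge lists; no online database retrieval.
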