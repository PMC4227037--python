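# Methods

## The model

The package implements a depth-1 causal-reasoning model.  A knowledge graph
holds typed nodes (protein abundance, transcriptional/kinase/phosphatase/
catalytic/GTP-bound activity, RNA expression, phosphorylated forms,
biological processes) connected by signed, directed causal edges
(increases / decreases / ambiguous), each optionally backed by literature
evidence (citation id, species, tissue/cell-context keywords).

A hypothesis (HYP) is one upstream node together with its direct causal
edges to RNA-expression nodes whose gene symbols were measured in the
dataset.  There is no transitive closure: HYP scoring is deliberately
depth-1, so the only graph structure that matters downstream of a
controller is the multiset of (gene, expected sign) pairs.  A node is a
*possible HYP* when at least `min_downstream` (default 4) of its downstream
RNA nodes were measured; the set of possible HYPs is the universe for all
evaluation statistics.

Dataset input is a differential-expression table discretized into State
Changes: direction = sign(log2 fold change) when the adjusted p-value is
below `adj_p_cut` (default 0.05) and |log2FC| clears an optional floor
(default 0), else 0.  Non-significant genes are retained with direction 0
because the richness population is the measured universe, not the changed
subset.

## Scoring

For a HYP with k measured downstreams, x of which changed, in a universe of
N measured genes with n changed:

* richness = exact hypergeometric upper tail P(X ≥ x | N, n, k);
* concordance = exact binomial upper tail P(X ≥ c | m, p₀) where m counts
  changed downstreams with an unambiguous edge sign and c those whose
  direction matches the orientation under test.  p₀ defaults to 0.5 and is
  configurable for datasets with a strong global up/down imbalance.

Both controller orientations are scored; the direction call is the
orientation with the smaller concordance tail, a tie is reported as
ambiguous.  Changed downstreams on ambiguous-sign edges count toward
richness (they are changed measured downstreams) but not concordance.
Significance requires both raw p-values < `p_cut` (default 0.05); a
Benjamini–Hochberg variant is available behind a flag but off by default,
matching the uncorrected-cutoff convention of the evaluation this package
reproduces.

A structural consequence of the defaults worth knowing: a HYP with exactly
4 informative changed downstreams can never pass the 0.05 concordance
cutoff even with perfect agreement (0.5⁴ = 0.0625), so at
`min_downstream=4` richness is the binding test for the smallest HYPs.
Tests and benchmarks account for this floor.

## Evaluation statistics

Per (dataset, subnetwork) pair, the 2×2 table over the possible-HYP
universe yields coverage a/(a+c), odds ratio ad/bc, and a Pearson
chi-square p (1 df, no Yates correction by default; correction and a
Haldane–Anscombe +0.5 OR correction are flags).  Degenerate tables are
signalled rather than silently patched: an empty subnetwork-possible set
makes coverage undefined, b·c = 0 with a·d > 0 reports an infinite OR, the
0/0 case raises, and a zero marginal makes the chi-square undefined (rows
remain in the evaluation matrix, flagged).  Stars are fixed at
0.05/0.01/0.001.

The universe is an explicit argument everywhere, either one shared set or a
per-dataset mapping.  Published mouse-dataset odds ratios for the model
this package emulates are reproduced with species-matched subnetwork
possible-HYP counts inside the shared human-oriented 2,410-HYP universe;
both conventions are computable by passing the universe explicitly.

Report rounding follows the source material's printing: coverage as integer
percent, whole-model OR to two decimals, subnetwork OR to one.

Cross-dataset overlap patterns (`dataset_overlap_patterns`) partition the
universe by presence/absence across datasets and count each pattern overall
and per subnetwork, with percentages of the subnetwork-possible counts.

## Graph semantics and I/O

Node identity is the canonical label (activity tag + symbol + optional
phospho site), case-sensitive.  Cross-species unification is explicit via
`make_chimeric` with an ortholog symbol map; unified nodes are tagged
chimeric, the operation is idempotent, and chained renames (a map value
that is itself a key with a different target) are rejected because they
would break idempotence.  A genuine activity-tag collision cannot arise
since unification preserves tags inside labels.

Normalization on graph construction: self-loops are dropped with a warning
(meaningless in a depth-1 bipartite hypothesis model), duplicate
(source, target) edges merge with concatenated evidences, and *any* sign
disagreement collapses to ambiguous.  The last rule is stronger than only
collapsing +1 vs −1 conflicts, but it is what keeps merging associative and
order-insensitive — a once-conflicted edge can then never be resurrected to
a definite sign by a later assertion.

XGMML I/O uses the node `label` attribute for canonical labels, an edge
`relationship` att in {increases, decreases, ambiguous}, `evidence` atts
serialized as `citation|species|kw;kw`, and round-trips all other atts
opaquely; unmappable relationship strings are rejected by default or mapped
to ambiguous on request.  The edge-table dialect is 6 tab-separated columns
(source, relationship, target, citation, species, ;-joined keywords), one
line per evidence, `#` comments.

Edge context proportions (`context_edge_proportion`) count edges with at
least `min_evidence` (default 1) evidences whose context keywords contain a
query keyword as a case-insensitive substring.  The default of 1 follows
the prose definition of the statistic ("proportion of vascular-specific
evidence"); the printed reference proportions are only reproducible under
≥1-evidence counting, and the threshold is configurable.

## Synthetic benchmark generator

The generator emulates the statistical shape of a knowledgebase-backed
evaluation, not its biological content:

* `generate_kb` — a bipartite controller → exp(gene) graph.  Defaults:
  2,400 controllers (knowledgebase-scale possible-HYP count), 10,000
  measured genes (microarray-scale universe; together with the default
  noise rates this yields a few hundred to a few thousand changed genes,
  the range real datasets show), Poisson out-degree with mean 25 truncated
  at ≥ 1, negative edge-sign probability 0.3 (curated causal content is
  increase-dominated).
* A planted perturbation: `n_active` controllers (default 300, matching the
  few-hundred significant HYPs real datasets yield) with uniform ±1
  directions.  `simulate_experiment` changes each downstream of an active
  controller to its implied direction (edge sign × controller direction)
  with probability 1 − ε − silence, flips it with probability ε
  (default 0.05), silences it otherwise (default 0.10); genes with several
  active parents resolve by sign majority with ties unchanged — the
  simplest rule consistent with discrete calls; all other genes change at
  background rate β = 0.01 with uniform direction.
* `assign_subnetworks` — six subnetworks of 60 controllers by default
  (within the 27–155 possible-HYP range of the emulated model).  The
  number of active members is drawn from Fisher's noncentral hypergeometric
  distribution with odds ρ (default 4), the sampling law whose enrichment
  odds ratio is exactly ρ; members are then uniform within each stratum.
  ρ = 1 reduces to the central hypergeometric null.

All randomness derives from one integer seed through spawned NumPy
`SeedSequence` streams (one per stage), so knowledgebase, experiment and
subnetwork draws are independently reproducible.

### What the generator does and does not emulate

It reproduces the quantities the pipeline's statistics consume: universe
sizes, signed depth-1 neighbourhoods, realistic changed-gene counts, and
controlled subnetwork enrichment.  It does not emulate correlated gene
regulation, controller–controller edges, hub degree distributions,
measurement batch structure, or biologically meaningful node identities.
Passing benchmarks therefore demonstrates correctness and statistical
calibration of the method under its own model assumptions — not that any
particular biological network is right.

## Benchmark problem sizes

The recovery benchmark runs 20 seeds at the full default scale
(2,400 controllers × 10,000 genes, 20 active controllers, ε = 0.05,
silence = 0.10, β = 0.01) and checks sensitivity ≥ 0.9, empirical FDR
≤ 0.1 and all recovered directions correct.  The enrichment benchmark is
run at the set level — the planted active set stands in for the
significant set — so it isolates the calibration of the evaluation
statistic from RCR recovery (which the first benchmark measures): 100
seeds at ρ = 4 for detection and 400 seeds at ρ = 1 for the null
rejection rate (400 brings the Monte-Carlo standard error of the rate
near 1%, small against the ±3-point tolerance).  The exact null rejection
probability of the uncorrected chi-square under these margins is 4.5%,
computed by summing the hypergeometric null over all tables.  A separate
single-seed test runs the full pipeline (generate → simulate → score →
evaluate) against a planted ρ = 4 subnetwork.

## Known limitations

* Depth-1 only; no path reasoning, feedbacks, or dynamics.
* Uncorrected per-HYP significance by design; with ~2,400 HYPs the
  expected false-positive count at joint 0.05 cutoffs is nonzero (the
  benchmarks quantify it as empirical FDR ≲ 0.1 at the default panel).
* The chi-square is asymptotic; very small subnetworks or significant sets
  can make it undefined or poorly calibrated (flagged, and the Yates
  correction is available).
* Ambiguous-sign edges dilute concordance information; a graph dominated by
  ambiguous edges will score richness-only.
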