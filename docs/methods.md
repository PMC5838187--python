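# Methods

## Model and procedure

The pipeline screens undirected, unweighted PPI networks for *central genes*
using two distribution-based criteria and their intersection:

* **Hub rule.** A gene is a hub when its degree strictly exceeds
  `mean + hub_sd_multiplier × SD` of the network's degree distribution.
  Defaults: multiplier 2, population SD (ddof = 0). Population SD was chosen
  because it is deterministic for the observed distribution and matches the
  usual "mean + 2 SD" screening idiom; sample SD is available via
  `ScreenParameters(sd_kind="sample")`. The inequality is strict, so a
  zero-spread network (every degree equal, e.g. a cycle) yields no hubs.
* **Bottleneck rule.** The top `bottleneck_fraction` of genes by betweenness
  centrality, with the count rounded up (`⌈fraction × n⌉`, default 5%) and
  ties broken by ascending symbol so the selection is deterministic.
* **Hub–bottleneck genes** are the intersection of the two panels.

Betweenness uses the raw unordered-pair convention (endpoints excluded, no
normalization, disconnected pairs contribute zero), computed with Brandes'
dependency accumulation in O(|V||E|) for unweighted graphs. Only the rank
order feeds the top-fraction rule, so any monotone normalization would give
identical bottleneck panels; the raw convention was chosen because its small
closed forms (path interior = 1, star center = C(leaves, 2), 4-cycle = 1/2
everywhere) make the implementation testable by hand. A normalized column
(`betweenness / ((n−1)(n−2)/2)`) is emitted for comparability with
Cytoscape's NetworkAnalyzer.

### Component-aware screening

Degree statistics are not comparable across connected components of very
different sizes: pooling deflates the mean and SD relative to the large
component, so the pooled cutoff both admits spurious small-component genes
and misses the large component's top genes. The component-aware screen
therefore applies the rules inside each component with at least
`min_component_size` nodes (default 20 — a size floor generalizing "screen
only the main components"; smaller fragments are skipped and logged), also
screens the pooled network for audit, and merges the per-component
hub–bottleneck panels by deduplicated union ordered by first appearance.
Union is the only merge rule consistent with the published per-component and
final panels (the final 20-gene panel equals the 18-gene ∪ 4-gene component
panels). It is associative and order-insensitive as a set.

## Enrichment stage

Term over-representation follows the ClueGO protocol: a one-sided
(upper-tail) hypergeometric test per term — `P(X ≥ k)` for `X ~
Hypergeom(N, K, n)` with universe size N, term size K, query size n, overlap
k — filtered by `k ≥ 2`, `100·k/K ≥ 4%` and `p ≤ 0.01`. Raw p-values are
thresholded by default, matching the source protocol; Bonferroni and
Benjamini–Hochberg corrections are optional switches. The percent filter is
the fraction of the *term's* genes recovered in the query (ClueGO's
"% genes/term" semantics), not the fraction of the query annotated.

Surviving terms are grouped by Cohen's kappa on the 2×2 contingency of gene
membership over the universe (observed vs chance agreement of the two
membership indicators; kappa = 1 exactly when the member sets are
identical). Terms with pairwise kappa ≥ 0.4 (ClueGO's conventional
threshold) are linked and clusters are the connected components of that term
graph — a deterministic simplification of ClueGO's iterative kappa merge
that is identical on well-separated term blocks, which is the regime the
generator plants; on overlapping blocks connected components can chain
clusters that the iterative merge would split.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, with
the study's reported sizes as the named `study_scale` preset:

* `gen_preferential_attachment(n, m, seed)` — Barabási–Albert growth from an
  m-clique (exactly `(n−m)·m + C(m,2)` edges), giving the heavy-tailed
  degree distribution typical of PPI networks.
* `gen_two_component(sizes, m, seed)` — disjoint union of independent PA
  graphs; `study_scale` sizes [3581, 809], desk default [300, 60].
* `gen_disease_pair(n_a, n_b, n_common, seed)` — two symbol panels with an
  exact (not expected) overlap; defaults 843, 376 and 65, the reported
  UC/COAC gene-set sizes.
* `gen_planted_hubs(n, m, n_hubs, hub_extra_degree, seed)` — PA background
  plus designated nodes wired to `hub_extra_degree` extra random partners.
  The validation setting (n = 500, m = 3, 5 hubs, 80 extra edges) puts
  planted degrees ≥ 6 background SDs above the background mean, so recovery
  failures indicate screening defects, not borderline draws.
* `gen_annotations(universe_size, n_terms, planted, seed)` — annotation
  tables whose planted terms have an exact requested overlap with a
  designated query panel; background terms draw members uniformly. The
  simulation default plants overlaps of 8 on terms of size 20–25 against a
  20-gene query in a 200-gene universe (upper-tail p ≈ 1e−4), decisively
  inside the p ≤ 0.01 filter rather than at its margin.

Each generator call consumes a single seeded `random.Random` stream, so
output is bit-reproducible for a fixed seed and the `simulate` CLI writes
the seed and ground truth (planted hubs, planted terms, overlap list) in a
YAML sidecar.

What the generators do **not** emulate: real PPI degree–betweenness
correlation structure beyond what preferential attachment induces,
confidence-score distributions, gene-symbol aliasing, or annotation term
hierarchies (terms are flat sets, no ontology propagation). Passing the
synthetic suites therefore shows the *rules* are implemented correctly and
recover planted structure under scale-free assumptions; it does not certify
behavior on any particular curated interactome.

## Reference tables

The six curated panels (T1, T2_comp1, T2_comp2, T3, T4, T5) were transcribed
by hand from the published tables, whose symbol columns were concatenated
single-cell runs; each fixture file preserves the raw run alongside the
per-row curation. T1 lists CDKN2A twice (rows 15 and 28) — the duplicate is
collapsed with a logged warning, leaving 28 unique symbols. The published
cross-disease table ("Table 6") was referenced but never printed; it is
reconstructed as `intersect_panels(T3, T4)` and labeled `reconstructed-T6`.

## Numerical and design choices

* Symbol normalization is uppercase + strip only; no alias resolution.
* Edge-list third columns parse as confidence scores; values > 1 are treated
  as STRING-style 0–1000 scores and divided by 1000. Confidence is carried
  but ignored by all centrality math (the screening rules are unweighted).
* Betweenness comparisons use an absolute tolerance of 1e−9; the observed
  disagreement between Brandes and the exhaustive path-enumeration oracle is
  at the 1e−14 level (floating-point accumulation order only).
* Components are ordered by size descending, ties by smallest member
  symbol, so "component-1" labels are deterministic.
* "Related genes" expansion around a seed panel defaults to depth-1 closed
  neighborhoods (seeds plus direct interactors), with depth configurable.
* Degenerate inputs: screening requires ≥ 3 nodes; empty hub panels are
  valid results; an empty enrichment result and an empty consensus panel are
  valid results, not errors.

## Problem sizes used in validation

The test suite and the acceptance script use desk-scale problem sizes chosen
to exercise every rule with comfortable margins: 200 random graphs of 4–12
nodes for the betweenness oracle suite, 50 planted-hub networks of 500 nodes
for recovery, exhaustive hypergeometric enumeration for universes up to 12
genes, and annotation universes of 100–200 genes. The full suite runs in
well under a minute per stage on one CPU.
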