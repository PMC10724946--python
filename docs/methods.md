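# Methods

`pancanet` implements a multi-cohort proteomic co-expression network
analysis: per-cohort differential protein calling, planar-filtered
co-expression networks with multiscale modules and hubs, cross-cohort
module preservation, pan-cancer protein interaction communities
(PCPICs) with a signed cross-talk network, and network-neighborhood
key-regulator ranking.  This note records the model assumptions, the
concrete numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Differential protein expression

Tumor vs matched-normal differences are tested per gene with Welch's
two-sample t-test on log-scale abundances (no equal-variance
assumption, no moderation/shrinkage) and corrected by
Benjamini–Hochberg FDR across tested genes.  Genes with fewer than
three finite values in either group are dropped and counted.  A gene
is called up (down) when FDR < `q_dep` (default 0.05) with a positive
(negative) mean difference.  A cohort without normal samples returns
an explicit empty result rather than an error, and is excluded
downstream from signature-dependent stages only.

Degenerate rows are resolved deterministically: a gene constant and
equal in both groups gets t = 0, p = 1; constant but different groups
get p = 0 with the sign of the difference.

**Proteome-specific DEPs** are proteins with protein-level FDR <
`q_dep` whose matched transcript has FDR ≥ `q_rna` (default 0.05),
evaluated per direction on the intersection of the two gene universes.
Both thresholds are config-exposed; the criterion is deliberately
symmetric and threshold-based because nothing finer is identifiable
from two marginal tests.

**Cross-cohort recurrence** of gene sets is scored with an exact
multi-set intersection test: under the null, each cohort's set is an
independent uniform subset of fixed size from the common universe.
The running intersection is then a Markov chain — given the first
k−1 sets share j elements, the overlap with the k-th set of size n_k is
hypergeometric — so the exact distribution of the m-way intersection
size follows by chaining hypergeometric transitions, and the reported
p-value is the upper tail at the observed overlap.  Expected overlap
is n·∏(nᵢ/n).  For problems with universe > 10⁴ and more than five
sets the summation is replaced by a seeded Monte-Carlo estimate
(reported as such in the result).

## Co-expression networks

**Screening.** All-pairs Spearman correlation on tumor samples.
Significance is calibrated by permutation: each gene's values are
shuffled across samples independently, `n_perm` times (default 50),
and the FDR at threshold t = |rho| is the ratio of the mean null to
the observed count of pairs at or above t, made monotone in t
(q-value style).  Pairs with FDR < `fdr_cut` (default 0.05) become
candidate edges.  Spearman is used for robustness to the heavy tails
common in proteomic abundance data; the correlation sign is kept as an
edge attribute and the edge weight is |rho|.

**Planar backbone (PMFG).** Candidate edges are inserted greedily in
decreasing weight order (ties broken lexicographically by gene pair);
an edge is kept iff the graph remains planar, stopping at the planar
bound 3(n−2).  Planarity is decided by the linear-time left–right
test behind a single internal predicate.  Two exact shortcuts keep
this fast without changing the result: an edge joining two distinct
connected components is always planar-safe, and a component already
holding 3(n−2) edges can accept no further edge by Euler's bound.
The final graph is re-certified planar.

**Multiscale modules.** Modules are detected by recursive top-down
splitting of the *positive* backbone: only positively correlated
edges bind genes into a module.  This sign-coherence convention (the
"signed network" convention familiar from WGCNA) matters: a module's
summary expression is only meaningful for genes that co-vary in the
same direction, and strong negative edges — which encode antagonism
*between* programs and feed the PCPIC cross-talk stage — would
otherwise act as shortcuts gluing two opposed communities into one
module.

Within a connected parent, nodes are partitioned by a deterministic
k-medoids (PAM BUILD seeding, lowest-index tie-breaks) on
shortest-path distances with edge length 1 − rho, for k = 2..4.
Clusters smaller than `min_size` (default 10) are dropped from a
proposal rather than vetoing it — dangling low-degree genes must not
block a real split — and a proposal needs at least two surviving
children.  Split quality is the *contrast* statistic: pair-weighted
mean within-child similarity minus mean between-child similarity
(similarity = 1 − normalized path distance), multiplied by the
fraction of parent nodes covered, so a split can neither score well by
merely inheriting a tight parent nor by shedding its periphery.

A split is accepted at resolution α iff its quality exceeds α × the
95th percentile of the same statistic on null replicates of the
parent: the parent's own positive candidate correlations (from the
screening stage) are assigned to uniformly random gene pairs and
greedily re-filtered to a planar backbone, and the full split search
is re-run on each replicate.  Three properties of this null are
deliberate.  First, it re-optimizes: an optimized observed statistic
compared against unoptimized random partitions would accept splits on
any graph, because graph distances always cluster.  Second, it
randomizes the *pair assignment*, not merely the weights: both the
backbone topology and the candidate pair set carry the module signal,
so weight shuffling alone leaves the null block-structured and
powerless.  Third, it rebuilds from the same candidate *supply* so
the null backbone reaches the same saturation/triangulation level as
the observed one — a sparser random rewiring has systematically
different path geometry and miscalibrates the accept rate.  For
tractability the supply is capped at the 3.5n strongest candidates
(the planar bound is 3n − 6, so the capped null still saturates).

Larger α is more stringent: each accepted split records the largest α
in the grid (default {0.5, 1, 2}) at which it passes, capped by its
parent's value so that a resolution cut of the tree is well defined;
`modules_at(α)` returns the leaves of the subtree of splits accepted
at ≥ α.  Reporting defaults to α = 1.  Disconnected parents fall
apart into their connected components directly (components below
`min_size` are dropped).  All recursion, seeding and permutation draw
from named substreams of one master seed, so results are
bit-reproducible.

**Hubs.** The null degree distribution pools node degrees from PMFGs
rebuilt on weight-shuffled candidate lists (default 50 replicates); a
node is a hub iff its backbone degree exceeds the (1 − `hub_q`)
pooled-null quantile (default hub_q = 0.05).

## Module preservation

A module is scored against every module of a target network with the
one-sided Fisher exact test (hypergeometric upper tail) on the 2×2
overlap table; the universe of each comparison is the intersection of
the gene sets *measured* in the two datasets, not the network node
sets — node sets are nearly coextensive with the modules themselves,
which would collapse fold enrichment toward 1 by construction.
BH-FDR is applied across the target modules of one query (best-match
semantics, not a global correction).  The best match is the smallest
FDR (ties: raw p, then label) and the call is **strong** if best FDR
< `q_strong` (0.05) and fold ≥ `fold_min` (2), **weak** if not strong
but best raw p < `p_weak` (0.05), else **none**.  The three-way
thresholds are this package's operationalization of a qualitative
strong/weak/none classification; all are config-exposed.

## Pan-cancer protein interaction communities

The module overlap graph has one node per (cohort, module) and an
undirected edge wherever a cross-cohort best-match call is strong in
at least one direction; same-cohort edges never occur.  Communities
are connected components spanning at least `span_min` distinct
cohorts (default: all cohorts).  The **core** of a community is the
set of genes occurring in member modules from at least `core_min`
cohorts (default: majority, ⌈span/2⌉ — monotone: raising `core_min`
never grows the core).

Per cohort, a community's summary expression is the mean of z-scored
core-gene rows over tumor samples (mean z-score rather than a leading
eigen-component: sign-stable and robust for small cores).  For each
community pair, per-cohort Spearman correlations between summaries
are combined as the median rho with Fisher's method on the two-sided
p-values; a cross-talk edge is kept iff the combined p < `p_edge`
(0.05), signed by the median rho.  Core sets are also tested for
enrichment in each cohort's up/down differential signatures.

## Key-regulator ranking

For every node with at least `min_neighbors` (5) neighbors within
`h` (2) steps on the backbone, the neighborhood is tested for overlap
enrichment against the cohort's up- and down-signatures (universe =
network nodes), with BH-FDR per signature across nodes.  A node is a
driver iff min(FDR_up, FDR_down) < `q_driver` (0.05).  Hub status is
computed independently; a driver need not be a hub.  The pan-cancer
ranking orders genes by cohorts-as-driver, then cohorts-as-hub, then
best FDR, then gene id — a total order.  The reported up/down counts
are the cohorts whose neighborhood enrichment favored the up vs the
down signature.

Because the enrichment test is exact and discrete, its null p-values
are conservative (stochastically larger than uniform), never
anti-conservative; the test suite verifies validity at fixed
thresholds and checks exact calibration through the randomized
probability-integral transform, the standard uniformity diagnostic
for discrete test statistics.

## Synthetic data generator

The generator emulates the structure of a multi-cohort proteogenomic
study: several cohorts on a shared gene universe, each with a
proteome and a matched transcriptome.

* **Modules** are single-latent-factor blocks: within a cohort, each
  active module has a factor ~ N(0, `latent_effect_sd`²) per sample,
  and member gene values are loading × factor + baseline + noise,
  loadings ~ U(0.6, 1.0) drawn once per module (so the module looks
  the same in every cohort carrying it).  Factors of different
  modules can be correlated through a user-supplied coupling matrix
  (used to plant anti-correlated communities).
* **Layers** share the factors and loadings; each layer draws its own
  Gaussian noise, giving partial proteome/transcriptome concordance.
* **Differential effects** are mean shifts of ±`dep_effect` (default
  2 log-units) applied to tumor samples of module members (one
  coherent direction per module) and to scattered background genes; a
  fraction `frac_proteome_specific` (default 0.3) of each cohort's
  shifted genes receive the shift in the proteome only.
* **Regulators**: one designated member per module gets the maximal
  loading (1.0) and reduced noise (×0.3), making it the cleanest
  readout of the factor and hence the strongest-connected member —
  the planted ground truth for hub and driver recovery.

Reference study conditions used throughout the tests: seven cohorts
of 50 tumor / 30 normal samples, noise SD 0.5, a 500-gene universe
with one pan-cohort module of 40 genes and two cohort-specific
modules of 30 genes, `dep_effect` 2.  What passing these benchmarks
shows is that every stage recovers the structure it is designed to
recover under its own model assumptions, with calibrated error rates;
what they do not show is robustness to features of real proteomic
data the generator deliberately omits — missingness patterns, batch
and TMT-ratio artifacts, non-Gaussian abundance distributions,
correlated noise across genes, and modules that are not
single-factor blocks.

## Scaled problem sizes and numerical conventions

Simulation-based checks run at deliberately modest sizes chosen as
package defaults: networks up to a few hundred genes (the
implementation targets ≤ ~2,000), 20–50 permutations for screening
and clustering nulls, 25–50 hub-null rebuilds, and a 3-cohort
120-gene panel for the byte-reproducibility check.  Tie-breaks are
lexicographic by gene id everywhere (candidate ordering, k-medoids,
best-match selection, rankings), so every stage is deterministic
given its seed; all seeds derive from one master seed through named
SHA-256 substreams.  p-values are clipped to (0, 1]; empty query or
target sets yield the p = 1, fold = 0 convention; an empty community
core is retained with a warning rather than dropped.

## Known limitations

* Preservation is overlap-based only; correlation-pattern statistics
  (Z-summary style) are out of scope by design.
* The exact multi-set test models sets as uniform random draws — it
  ignores gene-level heterogeneity in detectability.
* PMFG construction is O(candidates × planarity test) in pure
  Python; networks beyond ~2,000 genes are impractical.
* The split test's planar-rebuild null is conservative for parents
  whose module boundary is carried mostly by edge *presence* rather
  than weights when the candidate density is very high.
* Driver scoring treats the up- and down-signatures separately; a
  combined bidirectional test is not implemented.
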