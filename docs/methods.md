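# Methods

## Activity scoring

For one observation unit (cell or pseudocell) the genes are ordered by
decreasing expression and the recovery curve R(x) counts regulon genes
among the top x ranks for x = 1..k. The scored gene set is the TF plus
its targets; regulon genes absent from the matrix are dropped with a
logged count (gene matching is exact-string and case-sensitive —
silent fuzzy matching hides identifier problems). The window is
k = max(1, ⌊top_fraction · n_genes⌋) with top_fraction defaulting to
0.05, the convention of AUCell-style recovery scoring. The score is

    RAS = Σ_{x=1}^{k} R(x) / max-step-sum,

where the denominator is the step-sum of a regulon placed entirely at
the top of the ranking (k·|G| − |G|(|G|−1)/2 for |G| ≤ k, else
k(k+1)/2). This makes [0, 1] an exact range: 1 is attainable and
testable, 0 means no regulon gene in the window. Scoring depends only
on ranks, so it is invariant to monotone transforms of a unit's
profile, and no normalization of the input matrix is required (the run
configuration records whatever preprocessing the caller applied).

Ties dominate sparse count data (most genes are 0), so tie handling is
explicit. The default breaks ties uniformly at random under a seeded
generator, one generator for the whole matrix, units processed in row
order — reproducible and unbiased. The `average_rank` alternative
scores each tied gene at its *expected* contribution over all
tie-breaks: for a tie block spanning descending ranks [a, b], a member
gene contributes the mean of (k − r + 1) over r in [a, min(b, k)]
divided by the block size. On an all-constant profile this yields
exactly the expected AUC of a random gene set, |G|·k(k+1)/(2n) over
the max-step-sum.

Binarization Z-scores each regulon column across all units of the
matrix (population SD) and thresholds strictly at Z > 2.5. A
zero-variance column binarizes to all zeros with a warning rather
than erroring, since constant regulons are common in small subsets.
Per-regulon adaptive thresholds are deliberately out of scope; a
single global cutoff is what the downstream analyses assume.

## Specificity

The regulon's raw activity column (never Z scores, which can be
negative and admit no probability reading) is normalized to sum to 1,
as is the 0/1 indicator of the cell type. With base-2 entropy
H(P) = −Σ p log₂ p, the Jensen–Shannon divergence

    JSD(P_R, P_C) = H((P_R + P_C)/2) − (H(P_R) + H(P_C))/2

lies in [0, 1] (natural log would break that bound); the result is
clipped against floating-point drift. RSS = 1 − JSD. An everywhere-zero
regulon has no distribution; it is reported missing with a warning
rather than given an arbitrary score. Rankings within a cell type
break RSS ties alphabetically so output ordering is stable. The
annotation field that defines "cell type" is a parameter, so
specificity can be computed at any label resolution (major type, or
tissue × cluster).

## Avg20 pooling

Within each (tissue, cell type) stratum, a random permutation is cut
into ⌊n/20⌋ full groups; each group's mean profile is one pseudocell
inheriting the stratum's labels. Remainder cells are dropped by
default — keeping groups homogeneous in size — with
`keep_as_smaller_group` (optionally floored by `min_group_size`)
available for small cell types. One seeded generator processes strata
in sorted order, so plans are machine-independent; when every stratum
size divides the group size, pooling conserves total expression mass
exactly. The three-replicate protocol is orchestrated by the pipeline,
which derives each replicate's seed from the master seed by hashing.

## Regulon modules

Pearson correlation of activity columns (zero-variance regulons
dropped, ≥3 units required) feeds the Connection Specificity Index:

    CSI(A,B) = |{C ∉ {A,B} : PCC(A,C) < PCC(A,B) ∧ PCC(B,C) < PCC(A,B)}| / (N − 2)

with strict inequalities, both conditions required, and CSI(A,A) = 1
by convention. An exhaustive triple-loop oracle in the test suite pins
this exact variant. Modules come from average-linkage agglomerative
clustering of CSI rows with Euclidean distance, cut at a user-chosen
number of modules (no automatic cut rule is imposed; the linkage
method is configurable since only the metric is canonical). Regulons
are sorted by name before clustering, making the partition independent
of input order — which also means sub-module detection inside one
module is literally the same function applied to the restricted CSI
sub-matrix. The regulon association network keeps pairs with CSI
strictly above 0.7.

## Cell-type network and MCL

Cell types are summarized by mean RAS profiles; edges connect pairs
with Spearman ρ strictly above 0.8 (computed as Pearson on ranks;
constant profiles are left isolated with a warning). MCL runs on the
unweighted adjacency by default (a `weighted` flag uses ρ) with
self-loops of weight 1, column normalization, expansion by matrix
squaring, inflation 2 with renormalization, and pruning of entries
below 1e-5; iteration stops when the flow matrix changes by less than
1e-8 (error after 200 iterations). Clusters are read from attractor
rows (positive diagonal mass), overlapping attractor systems merged;
nodes attracted nowhere join their strongest neighbor's cluster, and
isolated nodes become singletons. Group labels G1, G2, … are assigned
by decreasing size with lexicographic tie-break, so labels are
reproducible. A debug flag asserts column-stochasticity at every
iteration.

## Validation statistics

* **Silhouette**: S_i = (b_i − a_i)/max(a_i, b_i) from a precomputed
  distance matrix; a_i is the mean within-label distance, b_i the
  minimum mean distance to another label. Singleton labels score 0 by
  convention. A one-sided two-sample t test (pooled variance) compares
  two score sets, e.g. pooled vs single-cell scoring.
* **Top-rank enrichment**: given a table of co-expression datasets
  (unique rank, p value, related flag from case-insensitive keyword
  matching), datasets at p < 0.01 are "significant" and a one-sided
  Fisher exact test asks whether related datasets are over-represented
  among them. The 2×2 construction (significance × relatedness) is the
  operationalization of "enriched in the top ranks" consistent with
  selecting significant datasets first; it is recorded in every report
  so alternates can be compared.
* **Permutation null**: a caller-supplied score function is evaluated
  on the input gene set and on 1000 (default) equally sized sets drawn
  without replacement from the universe; p = #{random > observed}/n
  with a strict inequality (so a score constant under permutation
  gives p = 0), reported as "< 1/n" when the count is 0. External
  co-expression and co-citation services are consumed as exported
  tables / callables, keeping all statistics network-free.
* **Replicate consistency**: TF-set overlaps between pooling
  replicates are tested one-sided Fisher against an explicit TF
  universe (the margin must be supplied, never guessed). Activity
  agreement is the Pearson correlation of vectorized upper-triangle
  distance matrices. Because regulon definitions are inputs here (not
  re-inferred per replicate), the pipeline's replicate check computes,
  per replicate, pseudocell RAS averaged into (tissue, cell type)
  stratum profiles and correlates the stratum-level distance matrices,
  which are comparable across replicates by construction.

## Synthetic data

The generator plants known structure in an atlas-shaped dataset.
Per-gene baseline means are drawn from Gamma(shape 2, mean =
`baseline_mean`, default 1 count): gene-level heterogeneity gives each
regulon a background activity level that is consistent across cell
types, as in real data where regulon size and member expression vary.
Counts are negative binomial with variance μ + 0.5 μ² (dispersion
exposed), thinned by independent Bernoulli dropout (default rate 0.3).
Cell types are grouped into families, one per planted module; a
module's regulons (TF and targets co-elevated, so rank-based scoring
can see the set) are active across the whole family — full effect
(default 4-fold) in each regulon's own primary cell type, intermediate
effect (midway, 2.5-fold) in the other members. Regulon gene blocks
are disjoint, keeping ground truth unambiguous.

The default benchmark is 5 cell types × 2 tissues × 50 cells (500
cells), 2,000 genes, 12 regulons of 50 targets in 3 modules, seed 7;
it runs in about a second, and the recovery tests sweep it over 10
generator seeds. What passing recovery shows: the pipeline's scores
rank planted signal above negative-binomial noise at these effect
sizes and recover planted partitions. What it does not show:
robustness to batch effects, doublets, ambient RNA, gene-gene
correlation beyond regulon co-elevation, or marker structure of any
real atlas — none of which the generator emulates. An effect size just
above 1 at small n is the documented negative control: recovery
degrades, as it should.

## Numerical and design choices

* JSD clipped to [0, 1]; entropies treat 0·log 0 as 0.
* AUC normalization by the maximal achievable step-sum (exact upper
  bound of 1).
* Strict inequalities at every published cutoff (Z > 2.5, CSI > 0.7,
  ρ > 0.8, CI_random > CI_true), matching their printed form.
* Problem sizes in the test suite (10-seed sweeps of the 500-cell
  benchmark, 10⁴ simulated enrichment tables, 10³ permutation-null
  trials at 200 permutations, exhaustive AUC/CSI oracles up to 12
  genes / 8 regulons) are chosen so the full suite completes in well
  under a minute while keeping estimator noise far from the asserted
  margins.
* The Fisher calibration simulation uses 500 datasets with ~100
  significant at the 0.01 cutoff: the exact test is discrete, and
  coarser tables make its achievable size so conservative that no
  implementation could sit near the nominal level.
* Degenerate inputs error loudly (empty annotation, all-zero
  distributions, single-label silhouette, missing cell annotations)
  rather than being silently dropped; warnings cover recoverable cases
  (zero-variance columns, constant profiles, absent regulon genes).

## Known limitations

Regulon inference itself (co-expression module discovery and motif
pruning) is upstream and out of scope: regulons are inputs. The MCL
implementation is dense (fine for hundreds of cell types, not for
graphs with many thousands of nodes). The number of regulon modules is
a required user choice; no gap statistic or cut-height heuristic is
provided. Activity scoring loops over units in Python with vectorized
inner work, which is comfortable at atlas scale (~10⁵ cells ×
hundreds of regulons) but not optimized beyond that.
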