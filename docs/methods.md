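# Methods

This note documents the models, numerical choices and limitations
behind `comolink`. It describes what the code computes; every number
quoted here is produced by the test suite or `scripts/acceptance.py`.

## Overlap model

The central quantity is the probability that two diseases share *k*
significant genes by chance. With a background of *N* genes, *M*
significant in disease A and *s* in disease B, the shared count under
the null of independent draws without replacement follows the
hypergeometric law; its pmf, both tails, mean *sM/N* and variance
*sM(N−M)(N−s)/[N²(N−1)]* are all exposed. Two conventions circulate for
the headline "hypergeometric value" of such a comparison: the point
probability h(k) and the upper tail P(X ≥ k). The package computes
both and reports **the upper tail as the headline value**: it is the
statistically meaningful quantity ("at least this much overlap"), and
it is the convention that recomputes the reference summary-table
values from their printed counts to within 1% (the point probability
deviates by up to a factor ~1.5 on the same rows).

The background *N* is always an explicit caller input. The pipeline's
default is the sum of the two diseases' tested gene counts — the
convention under which the reference tables reproduce. No attempt is
made to infer a "true" genome-wide background; with different *N* the
tail changes materially and that choice belongs to the analyst.

Numerics: log-gamma throughout, never factorials or products. Tails
are log-sum-exp sums over the support, exact to the working precision;
log-probabilities as small as −6000 nats (overlap probabilities below
10⁻²⁵⁰⁰) remain finite and correct, verified against big-integer
combinatorics. The decimal rendering derives mantissa and base-10
exponent directly from the natural log so the printed string survives
double underflow. Out-of-support *k* yields pmf 0 with tails fixed at
0/1 by side. The Jaccard index is evaluated as an exact rational
before any rounding.

## Differential expression

The DE stage is a deliberately simple two-group test — the scientific
weight of the package is downstream of it, and precomputed DE tables
can be supplied to bypass it entirely.

* **Normalization**: median-of-ratios size factors (per-sample median
  of count/geometric-mean ratios over genes nonzero in every sample).
* **Model**: negative binomial in mean–dispersion form,
  Var = μ + aμ². Gene-wise dispersion by method of moments from the
  within-group sample variances, averaged across groups and floored at
  a = 0.01. No shrinkage across genes.
* **Statistic**: difference of log normalized group means with a
  delta-method standard error, √[(m+am²)/(n·(m+pc)²)] per group,
  referred two-sided to a Student t with n₁+n₂−2 degrees of freedom.
  The t reference is a small-sample calibration choice: with 10
  samples per group the variance estimate is noisy enough that a
  normal reference runs anti-conservative (measured type-I ≈ 0.068 at
  nominal 0.05), while the t reference measures ≈ 0.051, inside the
  package's accepted calibration band [0.03, 0.07].
* **Pseudocount**: pc = 0.5 on normalized group means before log2
  ratios, so fold changes stay finite when one group is all zeros.
* **Degenerate genes**: all-zero genes are dropped before testing;
  genes zero in exactly one group get their fold change from the
  pseudocount rule and a p-value from the floored-dispersion variance.
* **Filter**: significance requires p < 0.05 **and** |log2FC| > 1,
  both inequalities strict, so boundary rows are excluded; the raw
  p-value is used (no multiple-testing correction at this stage — a BH
  column is attached for information only). The sign of log2FC assigns
  up/down.
* **Alternative path** (`de.method = qn_ttest`): size-factor
  normalization, log2(x+1), quantile normalization across samples,
  ordinary two-sided two-sample t-test. Quantile normalization maps
  every column onto the cross-column rank means; ties receive the mean
  of the reference values over their rank span, which makes the
  operation idempotent.

Gene identity is uppercased, whitespace-stripped symbols; no alias or
ortholog resolution is attempted.

## Enrichment

Over-representation of a query list against GMT collections uses the
same hypergeometric upper tail with N = |background|, M = term size,
s = |query ∩ background|, k = |query ∩ term|, BH-adjusted within each
collection, ranked by (p, larger term first, term id). The default
background is the collection universe unioned with the query; callers
pin N explicitly to reproduce any specific table convention.
Shared-term analysis intersects the significant term ids of two
disorders and feeds the resulting (A, B, C) and (N, M, s, k) back into
the Jaccard and hypergeometric machinery; N defaults to the total
terms tested for A plus those tested for B. Both raw-p and adjusted-p
significance accounting are exposed, since published counts mix the
two conventions. GO-style collections go through the same flat
treatment — no ontology DAG propagation.

## Variant catalogs

Catalog exports are gene-level tables; SNP-to-gene mapping is upstream
and out of scope. A gene is retained when **any** of its records has
p < 10⁻⁵ (strict), catalogs merge by gene-level union with per-source
provenance retained, and trait assignment is by caller-declared label
per file rather than free-text matching. Consensus genes are the
intersection of a pair's transcriptomic shared genes (all three
direction strata) with its shared catalog genes.

## Co-expression

Correlation is Pearson on log2(count+1) profiles, by default over the
case samples of one dataset (co-expression of the disease state), with
pooling available. Zero-variance genes are excluded and reported.
Clustering is agglomerative with **complete linkage** on d = 1 − r:
this linkage is chosen because the cluster criterion is "all pairwise
correlation above the threshold", and a complete-linkage cut strictly
below 1 − r guarantees exactly that floor — which the extractor also
asserts directly against the correlation matrix. Alternative readings
of the threshold rule (average or minimum block correlation) would be
weaker and are not implemented. Merge ties follow the deterministic
nearest-neighbor-chain order of the clustering routine. Clusters
smaller than 2 genes are dropped and the rest ordered by size. The
dendrogram exports as Newick with branch lengths.

## Synthetic data

The generator produces every pipeline input with planted truth, under
one explicit seed through a single `numpy.random.Generator`.

* **Counts**: gene-wise NB with baseline means log-uniform on
  [5, 500] counts, dispersion 0.1, 10 samples per group, 1000 genes,
  10% of genes differentially expressed at |log2FC| = 2 with
  Bernoulli(½) signs — a moderately powered iPSC-style comparison.
  These defaults are the package's standard validation conditions.
* **Disease pairs**: exactly round(shared_fraction·|planted A|) of A's
  DE genes re-planted in B, sign concordance controllable.
* **Co-expression blocks**: genes in a block share a per-sample latent
  Gaussian factor added to the log-mean, loading √ρ against √(1−ρ)
  idiosyncratic noise, so within-block log-count correlation is ρ and
  background genes are independent. The factor is standardized to unit
  realized variance across the samples, so the planted correlation
  does not inherit the sampling noise of the factor's variance. Count
  parameters for this generator are deliberately quiet (baseline mean
  2000, log-sd 1.0, dispersion 0.01) so counting noise attenuates the
  planted correlation by well under 1%.
* **Catalogs**: exactly n_significant genes log-uniform on
  [p_floor, 10⁻⁵), the rest uniform on [10⁻⁵, 1], sources cycling
  through five catalog names.
* **Gene sets**: terms sampled from the universe; planted terms draw a
  declared fraction of their members from a designated query set.

What the generator does **not** emulate: library-size and GC biases,
gene–gene correlation outside the planted blocks, heavy-tailed
dispersion across genes, linkage structure among catalog variants, and
single-cell zero inflation. Passing the synthetic validation therefore
demonstrates the statistical machinery is correct and calibrated under
its stated model — not that the DE test matches a full DESeq2/limma
analysis on real GEO data.

## Validation results (recomputed by the suite and acceptance script)

* Reference-table recomputation: upper-tail values within 1% of all
  four printed transcriptomic-row statistics; Jaccard indices exact to
  the printed decimals.
* Exhaustive oracle agreement for all (N ≤ 60, M, s, k) and unit pmf
  mass up to N = 2000.
* Planted shared-DE recovery: mean recovered shared count ≈ 49.8 of 50
  planted (10 seeds); null type-I ≈ 0.05.
* Cluster recovery: planted blocks of 25/21/17/18 recovered with mean
  ARI 1.0 at r > 0.7 across 10 seeds.
* Enrichment: planted terms recovered at BH ≤ 0.05 in 100% of
  replicates; null false-positive term rate ≪ 0.05.

## Known limitations

* The NB Wald test is not a DESeq2 clone: no dispersion shrinkage, no
  independent filtering, no outlier handling. On real data with few
  replicates its gene lists will differ from DESeq2's.
* Overlap statistics treat genes as exchangeable; no correction for
  gene length, expression level or co-annotation bias.
* Enrichment ranking is p-value only — no odds-ratio or combined
  score, so orderings need not match web enrichment tools.
* Published GWAS-row gene-level table values could not be reproduced
  under the stated law with their printed counts under either
  convention; those rows are excluded from the recomputation targets.
* Counts of significant genes/pathways on the original public datasets
  depend on catalog snapshots and database versions and are not
  desk-reproducible; the pipeline reports what its inputs yield.
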