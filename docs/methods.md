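# Methods

This note records the models, defaults and numerical choices behind
`pathstrat`, and what the synthetic validation does and does not establish.

## Per-sample enrichment

**Ranking statistic.** Sample *j*'s genes are ranked by
`s_g = x_gj − mean_k x_gk`, the difference from the cohort mean on the log2
scale, with the scored sample included in the mean (the simplest reading of
"compared with the average of the whole dataset"). Ties in the statistic are
broken by ascending gene symbol so rankings are reproducible. Because the
statistic subtracts the per-gene cohort mean, adding a constant to a gene
row changes nothing.

**Enrichment score.** The weighted Kolmogorov–Smirnov running sum over the
ranked list: genes in the set add `|s|^p` normalized over in-set genes,
genes outside subtract `1/(N − N_hit)`; ES is the signed maximum-magnitude
deviation. On an exact tie between the best positive and negative deviation
the positive value is returned. The weight defaults to `p = 1` (the standard
choice); `p = 0` is retained because several closed-form identities hold
there and make exact tests possible. If every in-set statistic is zero the
hit increments fall back to uniform (`1/N_hit`); the score of a set with no
genes in the ranked list is *missing*, never zero. A set covering the whole
list has ES = 1 by convention (the miss penalty is undefined there).

**Normalization and significance.** Each sample × set ES is divided by the
mean |ES| of same-sign null scores obtained by re-drawing random gene sets
of the same size from that sample's ranked list (gene-label permutation;
default 1000 draws). Phenotype permutation is not an option here because
each sample is scored alone against the cohort mean. A two-sided permutation
p-value (share of null |ES| ≥ observed |ES|) is stored alongside. One
permutation pool is drawn per sample and shared across set sizes — the first
*m* entries of a uniformly random permutation are exactly a uniform random
*m*-subset, so the sharing is an optimization, not an approximation. Seeds
for the per-sample generators are spawned deterministically from the global
seed.

## Signatures

PCA treats samples as observations and gene sets as variables, standardized
to unit variance (correlation PCA): NES magnitudes vary systematically with
set size, and standardization stops large sets from dominating the
components. Sets with any missing NES and constant variables are dropped
with a log message. Component signs are fixed so the variable with the
largest |loading| loads positively, making outputs stable across BLAS/SVD
implementations; flipping a component's sign exactly swaps its positive and
negative signatures. Contribution of a variable to a component is its
squared-loading share, in percent.

A signature for (component, direction) takes the top-20 sets by contribution
among sets whose loading sign matches the direction (ranking *within the
signed subset*, the first of the two readings of "top contributing sets in a
direction"; the alternative — ranking all sets by signed loading — is one
flag away), then keeps the genes present in at least 5 of them. Both
thresholds (20, 5) are the method's standard values and are configurable.
Names follow `<datasetCode><collectionCode>-<component><P|N>`; the collection
codes are "2" (canonical pathways) and "6" (oncogenic).

## Clustering

Consensus clustering follows Monti resampling: 80% subsamples without
replacement, seeded k-means (k-means++ initialization) on each subsample,
co-clustering counts normalized by co-sampling counts. The number of
clusters minimizes PAC — the fraction of off-diagonal consensus entries
strictly inside (0.1, 0.9) — with ties resolved toward smaller k. Final
labels come from average-linkage hierarchical clustering of 1 − consensus.
The inner algorithm, the resample fraction and the PAC criterion are this
package's documented choices; the analysis style the package implements
reports a cluster count without naming its selection rule, and PAC is the
standard scalarization of consensus CDFs.

NMF clustering shifts the profile to non-negative by subtracting its global
minimum (NES can be negative; the shift is a documented modeling choice),
then runs multiplicative-update NMF with 20 random restarts, keeping the
lowest Frobenius reconstruction error; samples go to their largest basis
coefficient. The random-forest check reports out-of-bag accuracy of
predicting the consensus labels from the profile, overall and per cluster.

## Survival

Kaplan–Meier uses the product-limit estimator; subjects censored exactly at
an event time stay in the risk set for that time's deaths. The median is the
first event time with S(t) ≤ 0.5 (the dashed-line convention of survival
figures), undefined when S never reaches 0.5. The log-rank statistic is the
Mantel–Cox quadratic form with hypergeometric variance over the first k−1
groups (pseudo-inverse for safety); both estimators are implemented directly
and validated against an independent reference implementation in the test
suite. Pairwise comparisons are adjusted by Benjamini–Hochberg by default:
the correction this literature reports as "Bonferroni–Hochberg" does not
exist under that name, so BH is the default and plain Bonferroni is a flag.

The limiting-dilution estimator fits the single-hit Poisson model
`P(well negative) = exp(−f · dose)` as an intercept-only binomial GLM with
complementary log-log link and offset `log(dose)`; `f = exp(intercept)`,
with a normal-theory CI on the log scale. With a single dose this reduces to
the closed form `f = −ln(neg/wells)/dose`. When every well responds, or
none does, the MLE sits on the boundary: the estimate is flagged and no CI
is reported.

## Single-cell scores

Score(cell, set) = mean expression of the set's *detected* genes − mean
expression of *all* detected genes, in that cell. Detection is dataset-wide
by default (nonzero in ≥ 1 cell); per-cell detection is a flag. Two
identities follow directly and are enforced in tests: the all-detected-genes
set scores exactly zero everywhere, and adding a constant to one cell leaves
its scores unchanged. Correlation maps use Pearson r across cells with
two-sided p-values, BH adjustment over unordered pairs (displayed raw below
/ adjusted above the diagonal by convention), and average-linkage grouping
of signatures on 1 − r (3 groups by default; configurable). Zero-variance
score vectors leave their pairs undefined rather than silently dropping.

## Coexpression modules

Unsigned weighted network: adjacency `|r|^β`. When β is not supplied, the
smallest power in 1..20 whose connectivity distribution fits a scale-free
law with R² ≥ 0.8 is chosen, falling back to the argmax R². Planted-block
validation data with a handful of equal-sized modules are *not* scale-free,
so the automatic rule is indifferent there; the desk-scale analyses and the
validation suite therefore pass the canonical unsigned-network default
β = 6 explicitly. Topological overlap similarity, average-linkage clustering
of 1 − TOM and a static cut at height 0.99 define modules (the dynamic
hybrid tree cut of the canonical implementation is deliberately not
reproduced — the static cut is simpler and deterministic and adequate at
this scale); clusters below `min_module_size` (default 10) stay unassigned.
Module eigengenes are the first principal component of the module's
standardized expression, sign-fixed to correlate positively with mean module
expression and unit-normalized. kME is each gene's correlation with an
eigengene; hub genes are module members with kME ≥ 0.8 ranked descending
(kME compared at 10 decimals so exact ties break by symbol, not float
noise). Module–cluster association correlates eigengenes with cluster
indicators (point-biserial), assigns each module to its best cluster and
BH-adjusts across modules.

## Annotation

Differential expression is a per-gene Welch two-sample t-test (cluster vs.
rest) with BH adjustment; Welch is the package's choice where the analysis
tradition names no test. Degenerate genes (zero variance in both groups) get
p = 1 when means agree, the smallest positive double and a flag when they
differ. ORA is the hypergeometric upper tail of the query/term overlap in a
stated universe, BH-adjusted across terms. The upstream-regulator caller is
an open stand-in for proprietary curated-knowledge tools: ORA of a
regulator's targets against a signature plus, when targets carry +/− signs
(encoded as symbol suffixes in GMT), a direction score
`(concordant − discordant)/√(targets)`; calls require adjusted p < 0.05 and
|score| ≥ 2. It claims no equivalence to any proprietary z-score or
knowledge base.

## Synthetic data: what it emulates and what it does not

`simulate_bulk` draws gene baselines from Normal(7, 1.5) (typical log2
intensities) with Normal(0, noise_sd) noise, splits samples near-equally
into k clusters, and gives each cluster a disjoint *program pool* of
`program_size` genes shifted by ±`effect` in its own samples. The gene-set
collection contains `programs_per_cluster` planted sets per cluster — each
an 80%-inclusion random subset of the pool — plus `n_decoys` size-matched
random decoys. The within-cluster redundancy is deliberate: real pathway
collections are highly redundant, and the ≥ 5-of-top-20 synthesis step is
only meaningful when several high-contributing sets share genes. Survival
times are Exponential(hazard of cluster) with independent censoring: each
subject is censored with probability `censor_rate` at a Uniform(0, event
time) time. Defaults (2000 genes, 60 samples, 3 clusters, effect 2, noise 1,
hazards 0.04/0.07/0.10 per month, 20% censoring) describe a mid-sized,
strongly structured cohort.

`simulate_single_cell` plants one program per cell state on a homogeneous
baseline (constant 2.0 plus noise) — per-cell scores are background-relative,
so gene-specific baselines would only add a constant per-set offset — and
applies uniform dropout by zeroing entries.

Not emulated: count-distribution effects (negative binomial dispersion,
library-size variation), batch effects, doublets, correlated censoring,
overlapping programs across clusters, and non-scale-free vs. scale-free
topology distinctions. Passing the planted-recovery suite therefore shows
the machinery is correct and well-calibrated under its own model; it does
not certify performance on real cohorts with weaker, confounded signals.

## Problem sizes and determinism

The validation suite runs at deliberately modest sizes chosen as the
smallest that make the checks sharp: 200 random instances for the
enrichment-score oracle; 200 sample–set pairs at 1000 permutations for null
calibration; 10 seeds × (40 samples, 1000 genes, 16 planted + 40 decoy
sets) for signature recovery; 10 seeds × (60 samples, k = 3) for cluster
recovery; 100 random tables plus 1000 null and 200 alternative replicates
for the survival engine; 400 cells for single-cell scores; 200 simulated
assays for limiting-dilution coverage; and the full default pipeline run
twice for byte-identical determinism. Every stochastic step takes an
explicit seed; the pipeline derives per-stage sub-seeds from the global seed
by hashing the stage name, so disabling or reordering stages never shifts
another stage's stream.

## Known limitations

* Gene-label permutation tests sets against a "random gene set" null, not a
  phenotype null; NES magnitudes are comparable within a sample but carry no
  cross-cohort FDR.
* The static TOM tree cut can split large diffuse modules that the dynamic
  hybrid cut would keep; module counts are therefore not comparable to
  canonical WGCNA runs.
* The LDA CI is normal-theory on the log-frequency scale and degrades near
  the response boundaries (almost all wells positive or negative).
* PAC prefers the sharpest consensus; with nested cluster structure it can
  choose the coarser level.
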