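# pathstrat

Pathway-utilization stratification of tumor expression cohorts.

Bulk tumor cohorts such as glioblastoma are heterogeneous in ways that
subtype labels capture only partially. `pathstrat` stratifies a cohort by
*which pathways each tumor actually uses*: every sample is scored against
every gene set of a pathway collection, the resulting enrichment profile is
distilled into compact gene signatures, samples are grouped by consensus
clustering, and the groups are interrogated for survival differences,
single-cell program activity, coexpression modules and candidate upstream
regulators. It is written for computational biologists who want the whole
chain as a reusable, tested Python library rather than a one-off script
collection.

## The method

1. **Per-sample preranked GSEA.** For sample *j*, every gene is ranked by
   `s_g = x_gj − mean_k x_gk` (difference from the cohort mean on the log2
   scale). A gene set *S* is scored by the weighted Kolmogorov–Smirnov
   running sum: hits add `|s_g|^p / Σ_{g∈S} |s_g|^p`, misses subtract
   `1/(N − |S|)`; the enrichment score ES is the signed maximum-magnitude
   deviation. The normalized score is
   `NES = ES / mean(|ES*|)` over same-sign null scores `ES*` from random
   same-size gene sets (gene-label permutation, seeded).
2. **Signature synthesis.** The samples × sets NES matrix is decomposed by
   correlation PCA. The contribution of set *i* to component *k* is
   `100 · w_ik² / Σ_i w_ik²` (squared loading share). For each component and
   direction, the genes present in ≥ 5 of the top-20 contributing sets form
   a signature named `<dataset><collection>-<component><P|N>` (e.g. `T2-1N`:
   TCGA-derived, canonical collection, PC1, negative direction).
3. **Consensus clustering.** Monti-style resampled k-means with co-clustering
   frequencies normalized by co-sampling counts; the number of clusters
   minimizes PAC (the proportion of consensus entries in (0.1, 0.9)). NMF
   clustering and a random-forest out-of-bag check corroborate the labels.
4. **Survival.** Kaplan–Meier product-limit curves per cluster and pairwise
   Mantel–Cox log-rank tests with Benjamini–Hochberg adjustment; a
   limiting-dilution estimator (single-hit Poisson, complementary log-log
   binomial regression) covers stem-cell frequency assays.
5. **Single cells.** Per-cell signature score = mean expression of the set's
   detected genes − mean of all detected genes; signature–signature Pearson
   maps with raw and FDR-adjusted significance and hierarchical grouping.
6. **Coexpression.** `|r|^β` adjacency, topological overlap, average-linkage
   modules, module eigengenes, kME-ranked hub genes, and module–cluster
   association.

Every stage is exercised on a synthetic-data generator that plants known
cluster programs, survival hazards and cell states, so the whole chain is
testable without external cohorts.

## Worked example

```bash
python examples/03_clustering_and_survival.py
```

```
PAC per k: {2: 0.677, 3: 0.0, 4: 0.256, 5: 0.315}
chosen k = 3
cluster 1: n=20, median survival 8.2 months
cluster 2: n=20, median survival 17.5 months
cluster 3: n=20, median survival 16.6 months

 group_a  group_b  chi_square    p_raw    p_adj
       2        3    0.294221 0.587528 0.587528
       2        1   10.539089 0.001169 0.003506
       3        1    6.794026 0.009146 0.013720
```

The simulated cohort has three planted pathway programs; PAC = 0 at k = 3
says resampled clusterings agree perfectly there, and the recovered clusters
separate survival exactly where hazards were planted (cluster 1 was given
the highest event rate — its median of 8.2 months is the shortest, and both
of its pairwise log-rank comparisons reject after BH adjustment, while the
two low-hazard clusters do not differ).

Other examples cover the enrichment profile (`01`), signature synthesis
(`02`), single-cell scoring (`04`), coexpression modules (`05`), the
limiting-dilution estimator (`06`) and the end-to-end pipeline with its
provenance manifest (`07`). A thin CLI mirrors the library:
`pathstrat simulate|enrich|signatures|cluster|survival|lda|sc-score|modules|de|ora|run`.

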