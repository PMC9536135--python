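"""Score gene programs in single cells and map their correlations.

Per-cell score = mean expression of the set's detected genes minus the mean
of all detected genes.  Scores of a planted cycling-like and a stem-like
program are anticorrelated across cells because each cell occupies one state.
"""

from pathstrat import GeneSet, cell_scores, correlation_map, simulate_single_cell

cycling = GeneSet("CYCLING", "meta-signature", tuple(f"CCG{i:02d}" for i in range(30)))
stemlike = GeneSet("STEMLIKE", "stemness program", tuple(f"STG{i:02d}" for i in range(30)))

matrix, truth = simulate_single_cell(
    n_cells=400,
    states=[("cycling", cycling, 2.0), ("stem-like", stemlike, 2.0)],
    noise_sd=1.0, dropout=0.3, seed=8,
)
scores = cell_scores(matrix, [cycling, stemlike])
print(f"scored {len(scores.cells)} cells, {len(scores.detected_genes)} detected genes")

cmap = correlation_map(scores, n_groups=2)
r = cmap.r.loc["CYCLING", "STEMLIKE"]
q = cmap.p_adj.loc["CYCLING", "STEMLIKE"]
print(f"r(CYCLING, STEMLIKE) = {r:.3f}, FDR-adjusted p = {q:.2e}")
print("signature groups:", {k: int(v) for k, v in cmap.clusters.items()})
print()
print("The negative correlation reflects mutually exclusive cell states:")
print("cells high on the cycling program are low on the stem-like one.")
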