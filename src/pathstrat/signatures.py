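"""PCA decomposition of enrichment profiles and gene-signature synthesis.

The enrichment profile (samples x gene sets of NES) is decomposed by PCA with
samples as observations and gene sets as variables, standardized to unit
variance (correlation PCA — NES scales differ across set sizes).  The
*contribution* of a gene set to a component is the percentage share of its
squared loading.  A gene signature for a component/direction collects the
genes shared by at least ``min_overlap`` of the ``top_n`` sets contributing
in that direction, and is named
``<datasetCode><collectionCode>-<component><P|N>`` — e.g. ``T2-1N`` for a
TCGA-derived, canonical-collection, PC1, negative-direction signature.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, GeneSet, GeneSetCollection
from .enrichment import EnrichmentProfile, normalize_es

logger = logging.getLogger("pathstrat")


@dataclass
class PCAResult:
    """Scores, loadings, explained variance and percentage contributions.

    Component signs are fixed deterministically: the variable with the
    largest absolute loading on each component has a positive loading.
    """

    scores: pd.DataFrame                 # samples x components
    loadings: pd.DataFrame               # gene sets x components
    explained_variance_ratio: np.ndarray
    contributions: pd.DataFrame          # gene sets x components, percent

    def __post_init__(self):
        if (self.contributions.to_numpy() < -1e-12).any():
            raise ValueError("contributions must be non-negative")
        sums = self.contributions.sum(axis=0).to_numpy()
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("per-component contributions must sum to 100")


@dataclass
class GeneSignature:
    """A named directional gene list synthesized from top-contributing sets."""

    name: str
    genes: tuple[str, ...]
    component: int                  # 1-based
    direction: str                  # "positive" | "negative"
    source_sets: tuple[str, ...]
    membership_counts: dict[str, int]

    def as_gene_set(self) -> GeneSet:
        prov = (
            f"component PC{self.component} {self.direction}; "
            f"{len(self.source_sets)} source sets"
        )
        return GeneSet(name=self.name, description=prov, genes=self.genes)


def pca_decompose(profile: EnrichmentProfile, n_components: int = 2) -> PCAResult:
    """Correlation PCA of an enrichment profile (gene sets as variables).

    Gene sets with any missing NES are dropped (logged), as are constant
    variables that cannot be scaled.  contribution(j, k) =
    100 * loading(j, k)^2 / sum_j loading(j, k)^2.
    """
    nes = profile.nes
    complete = nes.columns[nes.notna().all(axis=0)]
    dropped = set(nes.columns) - set(complete)
    if dropped:
        logger.info("dropping %d gene set(s) with missing NES: %s", len(dropped), sorted(dropped))
    X = nes[complete]
    sd = X.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning("dropping constant variable(s): %s", list(constant))
        X = X.drop(columns=constant)
        sd = sd.drop(index=constant)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 usable gene sets")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T  # variables x components, unit-norm columns

    # deterministic sign fix: largest-|loading| variable loads positively
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0, keepdims=True)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=nes.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        contributions=pd.DataFrame(contrib, index=X.columns, columns=comp_names),
    )


def synthesize_signature(
    pca: PCAResult,
    collection: GeneSetCollection,
    component: int,
    direction: str,
    dataset_code: str,
    top_n: int = 20,
    min_overlap: int = 5,
) -> GeneSignature:
    """Synthesize a gene signature from the top contributing sets in one direction.

    Sets whose loading sign matches ``direction`` are ranked by contribution
    (ties by contribution then name); the signature keeps genes present in at
    least ``min_overlap`` of the ``top_n`` selected sets.  Defaults follow
    standard practice for this analysis: top 20 sets, genes shared by >= 5.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    comp = f"PC{component}"
    if comp not in pca.loadings.columns:
        raise KeyError(f"component {comp} not in PCA result")
    load = pca.loadings[comp]
    contrib = pca.contributions[comp]
    mask = load > 0 if direction == "positive" else load < 0
    candidates = contrib[mask].sort_values(ascending=False)
    # stable tie-break by name after contribution
    candidates = candidates.iloc[
        np.lexsort((candidates.index.to_numpy(), -candidates.to_numpy()))
    ]
    if len(candidates) < top_n:
        logger.warning(
            "only %d set(s) with %s loading on %s (top_n=%d); using all",
            len(candidates), direction, comp, top_n,
        )
    selected = list(candidates.index[:top_n])
    counts: Counter[str] = Counter()
    for name in selected:
        counts.update(collection[name].genes)
    genes = tuple(sorted(g for g, c in counts.items() if c >= min_overlap))
    if not genes:
        raise ValueError(
            f"no gene appears in >= {min_overlap} of the top {len(selected)} sets; "
            "lower min_overlap or raise top_n"
        )
    name = f"{dataset_code}{collection.code}-{component}{'P' if direction == 'positive' else 'N'}"
    return GeneSignature(
        name=name,
        genes=genes,
        component=component,
        direction=direction,
        source_sets=tuple(selected),
        membership_counts={g: counts[g] for g in genes},
    )


def score_signature_matrix(
    matrix: ExpressionMatrix,
    signatures: list[GeneSignature],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentProfile:
    """Score synthesized signatures as gene sets on any expression matrix.

    Each signature is treated as a plain gene set and run through the same
    permutation-normalized enrichment as the primary collections; the result
    is the samples x signatures NES matrix.  Signatures with zero overlap in
    the matrix come back as missing columns.
    """
    if not signatures:
        raise ValueError("signatures must be nonempty")
    collection = GeneSetCollection(sets=[s.as_gene_set() for s in signatures], label="signatures")
    return normalize_es(matrix, collection, n_perm=n_perm, seed=seed, weight=weight)
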