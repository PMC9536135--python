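"""Per-sample preranked gene-set enrichment against the cohort mean.

Each sample is ranked by the difference between its log2 expression and the
cohort-wide mean expression of each gene (the sample itself included in the
mean).  A gene set is scored on that ranked list with the weighted
Kolmogorov-Smirnov running sum: genes in the set add ``|stat|^w`` (normalized
over in-set genes), genes outside subtract ``1/(N - N_hit)``; the enrichment
score (ES) is the signed maximum-magnitude deviation of the running sum.

The normalized enrichment score (NES) divides the observed ES by the mean
magnitude of same-sign null ES values from a gene-label permutation null:
random gene sets of the same size are re-drawn from the ranked list.  A
two-sided permutation p-value (fraction of null |ES| at least as large as
the observed |ES|) is recorded alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger("pathstrat")


@dataclass
class RankedList:
    """A sample's genes ordered best-to-worst by ranking statistic."""

    sample: str
    genes: np.ndarray   # ordered symbols
    stat: np.ndarray    # non-increasing ranking statistic

    def __post_init__(self):
        if len(self.genes) != len(self.stat):
            raise ValueError("genes and stat must have equal length")
        if np.any(np.diff(self.stat) > 1e-12):
            raise ValueError("ranking statistic must be non-increasing")

    def positions(self, gene_set: GeneSet) -> np.ndarray:
        """Sorted 0-based positions of the set's genes present in the list."""
        index = {g: i for i, g in enumerate(self.genes)}
        return np.sort([index[g] for g in gene_set.genes if g in index])


@dataclass
class EnrichmentProfile:
    """Samples x gene-sets matrices of NES, raw ES and permutation p-values."""

    nes: pd.DataFrame
    es: pd.DataFrame
    pvals: pd.DataFrame
    n_perm: int
    seed: int
    weight: float = 1.0

    def __post_init__(self):
        if self.nes.shape != self.es.shape:
            raise ValueError("nes and es shapes differ")
        both = self.nes.notna() & self.es.notna()
        if not (np.sign(self.nes[both].fillna(0)) == np.sign(self.es[both].fillna(0))).all().all():
            raise ValueError("sign(nes) must equal sign(es)")

    @property
    def samples(self) -> list[str]:
        return list(self.nes.index)

    @property
    def gene_sets(self) -> list[str]:
        return list(self.nes.columns)


def rank_vs_cohort_mean(matrix: ExpressionMatrix, sample: str) -> RankedList:
    """Rank one sample's genes by expression difference from the cohort mean.

    stat_g = expr(g, sample) - mean_s expr(g, s), the mean taken over all
    samples including the scored one.  Genes sort by stat descending; ties
    break by ascending symbol.
    """
    if sample not in matrix.values.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    v = matrix.values
    stat = (v[sample] - v.mean(axis=1)).to_numpy()
    genes = np.asarray(matrix.genes)
    # lexsort: last key is primary -> -stat first, then symbol ascending
    order = np.lexsort((genes, -stat))
    return RankedList(sample=sample, genes=genes[order], stat=stat[order])


def _weights_at(stat: np.ndarray, positions: np.ndarray, weight: float) -> np.ndarray:
    """Normalized hit increments at the given positions (handles all-zero stats)."""
    if weight == 0:
        w = np.ones(positions.shape, dtype=float)
    else:
        w = np.abs(stat[positions]) ** weight
    total = w.sum(axis=-1, keepdims=True)
    # degenerate all-zero statistics: fall back to uniform increments
    safe = np.where(total == 0, 1.0, total)
    w = np.where(total == 0, 1.0 / w.shape[-1], w / safe)
    return w


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score of one set on one ranked list.

    Returns ``(es, running_sum)`` where ``running_sum[i]`` is the value of the
    running sum after position ``i``.  Raises if no set gene is present in the
    ranked list (callers that score many sets mark such sets unscored instead).
    On an exact tie between the largest positive and negative deviation the
    positive one is returned, for reproducibility.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    positions = ranked.positions(gene_set)
    if positions.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the ranked list")
    n = len(ranked.genes)
    m = positions.size
    delta = np.full(n, (-1.0 / (n - m)) if m < n else 0.0)
    delta[positions] = _weights_at(ranked.stat, positions, weight)
    running = np.cumsum(delta)
    pos = max(running.max(), 0.0)
    neg = min(running.min(), 0.0)
    es = pos if pos >= -neg else neg
    return float(es), running


def _es_batch(stat: np.ndarray, positions: np.ndarray, weight: float) -> np.ndarray:
    """Vectorized ES for a batch of position sets.

    positions: (B, m) array of sorted 0-based hit positions into a ranked
    list with statistic ``stat`` (length N, non-increasing).  Returns (B,) ES.
    Peaks occur immediately after a hit, valleys immediately before one, so
    only 2m candidate deviations need checking per row.
    """
    n = stat.shape[0]
    m = positions.shape[1]
    if m == n:
        return np.ones(positions.shape[0])
    w = _weights_at(stat, positions, weight)
    c = np.cumsum(w, axis=1)
    pen = 1.0 / (n - m)
    miss = (positions - np.arange(m)) * pen
    peak = (c - miss).max(axis=1)
    valley = (c - w - miss).min(axis=1)
    pos = np.maximum(peak, 0.0)
    neg = np.minimum(valley, 0.0)
    return np.where(pos >= -neg, pos, neg)


def normalize_es(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentProfile:
    """Per-sample, per-set permutation-normalized enrichment profile.

    For every sample the genes are ranked against the cohort mean; each set's
    ES is normalized by the mean |ES| of same-sign null scores from ``n_perm``
    random same-size gene sets (gene-label permutation).  One permutation pool
    is drawn per sample and shared across set sizes (the first m entries of a
    random permutation are a uniform random m-subset).  Sets with no overlap
    in a sample are marked missing, as are sets whose null has no same-sign
    scores.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    samples = matrix.samples
    set_names = collection.names()
    nes = pd.DataFrame(np.nan, index=samples, columns=set_names)
    es_df = pd.DataFrame(np.nan, index=samples, columns=set_names)
    pv = pd.DataFrame(np.nan, index=samples, columns=set_names)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(samples))
    for si, sample in enumerate(samples):
        ranked = rank_vs_cohort_mean(matrix, sample)
        n = len(ranked.genes)
        index = {g: i for i, g in enumerate(ranked.genes)}
        rng = np.random.default_rng(child_seeds[si])
        pool = np.argsort(rng.random((n_perm, n)), axis=1)  # rows are permutations
        null_cache: dict[int, np.ndarray] = {}
        for gs in collection:
            positions = np.sort([index[g] for g in gs.genes if g in index])
            m = positions.size
            if m == 0:
                logger.warning("set %s has no overlap in sample %s; unscored", gs.name, sample)
                continue
            obs = _es_batch(ranked.stat, positions[None, :], weight)[0]
            if m not in null_cache:
                null_cache[m] = _es_batch(ranked.stat, np.sort(pool[:, :m], axis=1), weight)
            null = null_cache[m]
            same_sign = null[np.sign(null) == np.sign(obs)] if obs != 0 else null
            es_df.loc[sample, gs.name] = obs
            pv.loc[sample, gs.name] = np.mean(np.abs(null) >= abs(obs))
            if same_sign.size == 0:
                logger.warning(
                    "no same-sign null ES for set %s in sample %s; NES missing", gs.name, sample
                )
                continue
            nes.loc[sample, gs.name] = obs / np.mean(np.abs(same_sign))
    return EnrichmentProfile(nes=nes, es=es_df, pvals=pv, n_perm=n_perm, seed=seed, weight=weight)
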