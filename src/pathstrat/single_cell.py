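"""Per-cell signature scoring and signature-signature correlation maps.

The score of a gene set in a cell is the mean expression of the set's
detected genes minus the mean expression of all detected genes in that cell,
so the all-detected-genes set scores exactly zero everywhere and adding a
constant to a cell leaves its scores unchanged.  "Detected" is defined
dataset-wide by default (nonzero in at least one cell); per-cell detection
is available by flag.

The correlation map reports pairwise Pearson correlations of signature
scores across cells with two-sided raw p-values (by convention shown below
the diagonal) and Benjamini-Hochberg adjusted p-values over all unordered
pairs (above the diagonal), plus an average-linkage hierarchical grouping of
the signatures on 1 - r distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger("pathstrat")


@dataclass
class CellScoreMatrix:
    """Cells x signatures matrix of per-cell signature scores."""

    scores: pd.DataFrame            # cells x signatures
    detected_genes: tuple[str, ...]

    @property
    def cells(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class CorrelationMap:
    r: pd.DataFrame        # symmetric, unit diagonal
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame    # BH over unordered pairs
    clusters: pd.Series    # signature -> group id
    alpha: float = 0.05

    def __post_init__(self):
        a = self.r.to_numpy()
        finite = np.isfinite(a)
        if not np.allclose(np.where(finite, a, 0), np.where(finite.T, a.T, 0)):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(a)) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        both = self.p_raw.notna() & self.p_adj.notna()
        if (self.p_adj[both] < self.p_raw[both] - 1e-12).any().any():
            raise ValueError("adjusted p must be >= raw p")

    def significant(self, adjusted: bool = True) -> pd.DataFrame:
        p = self.p_adj if adjusted else self.p_raw
        return p < self.alpha


def cell_scores(
    matrix: ExpressionMatrix,
    sets: list[GeneSet],
    per_cell_detection: bool = False,
) -> CellScoreMatrix:
    """Score each gene set in each cell against the all-detected-genes background.

    score(cell, set) = mean expr of detected set genes - mean expr of all
    detected genes, per cell.  Sets with no detected genes give a missing
    column (logged); an empty set is an error.
    """
    if not sets:
        raise ValueError("at least one gene set is required")
    v = matrix.values  # genes x cells
    detected_mask = (v != 0).any(axis=1)
    detected = tuple(v.index[detected_mask])
    scores = pd.DataFrame(np.nan, index=v.columns, columns=[s.name for s in sets])
    if per_cell_detection:
        det = (v != 0).to_numpy()
        vals = v.to_numpy()
        with np.errstate(invalid="ignore"):
            global_mean = np.where(det.any(axis=0), (vals * det).sum(axis=0) / det.sum(axis=0), np.nan)
        for s in sets:
            rows = v.index.isin(s.genes)
            d = det[rows]
            x = vals[rows]
            with np.errstate(invalid="ignore"):
                set_mean = np.where(d.any(axis=0), (x * d).sum(axis=0) / d.sum(axis=0), np.nan)
            scores[s.name] = set_mean - global_mean
        return CellScoreMatrix(scores=scores, detected_genes=detected)

    background = v.loc[list(detected)]
    global_mean = background.mean(axis=0)
    for s in sets:
        if len(s.genes) == 0:
            raise ValueError(f"gene set {s.name!r} is empty")
        present = [g for g in s.genes if g in background.index]
        if not present:
            logger.warning("set %s has no detected genes; column missing", s.name)
            continue
        scores[s.name] = background.loc[present].mean(axis=0) - global_mean
    return CellScoreMatrix(scores=scores, detected_genes=detected)


def correlation_map(
    score_matrix: CellScoreMatrix,
    alpha: float = 0.05,
    n_groups: int = 3,
) -> CorrelationMap:
    """Pairwise Pearson correlation of signature scores with BH adjustment.

    Requires >= 3 cells and >= 2 signatures with complete scores.
    Zero-variance score vectors leave their pairs undefined (NaN).
    Signatures are grouped by average-linkage clustering of 1 - r, cut into
    ``n_groups`` groups.
    """
    S = score_matrix.scores.dropna(axis=1, how="any")
    names = list(S.columns)
    if S.shape[0] < 3 or len(names) < 2:
        raise ValueError("need >= 3 cells and >= 2 scored signatures")
    p = len(names)
    r = pd.DataFrame(np.eye(p), index=names, columns=names)
    p_raw = pd.DataFrame(np.nan, index=names, columns=names)
    p_adj = pd.DataFrame(np.nan, index=names, columns=names)
    np.fill_diagonal(p_raw.values, 0.0)
    np.fill_diagonal(p_adj.values, 0.0)

    sd = S.std(axis=0, ddof=1)
    pairs, raws = [], []
    for a, b in combinations(names, 2):
        if sd[a] == 0 or sd[b] == 0:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(S[a], S[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p_raw.loc[a, b] = p_raw.loc[b, a] = res.pvalue
        pairs.append((a, b))
        raws.append(res.pvalue)
    if raws:
        adj = multipletests(np.asarray(raws), method="fdr_bh")[1]
        for (a, b), q in zip(pairs, adj):
            p_adj.loc[a, b] = p_adj.loc[b, a] = q

    d = 1.0 - r.to_numpy()
    d = np.where(np.isfinite(d), d, 2.0)  # undefined pairs treated as maximally distant
    np.fill_diagonal(d, 0.0)
    Z = average(squareform((d + d.T) / 2, checks=False))
    clusters = pd.Series(
        fcluster(Z, t=min(n_groups, p), criterion="maxclust"), index=names
    )
    return CorrelationMap(r=r, p_raw=p_raw, p_adj=p_adj, clusters=clusters, alpha=alpha)
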