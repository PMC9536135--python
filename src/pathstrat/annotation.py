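"""Cluster annotation: differential expression, overrepresentation analysis,
and a transparent upstream-regulator stand-in.

Differential expression is a per-gene Welch two-sample t-test of one cluster
against the rest with Benjamini-Hochberg adjustment.  Overrepresentation
analysis (ORA) is the hypergeometric upper tail of the query/term overlap in
a stated universe.  The upstream-regulator caller combines ORA of a
regulator's target set against a signature with a sign-concordance direction
score; it is an open, documented stand-in for proprietary curated-knowledge
tools and makes no claim to reproduce their z-scores or knowledge base.

Signed regulons are encoded in GMT by suffixing target symbols with ``+`` or
``-`` (e.g. ``CDK1+``); unsigned regulons yield a direction of
``undetermined``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet, GeneSetCollection
from .signatures import GeneSignature

logger = logging.getLogger("pathstrat")


@dataclass
class RegulatorCall:
    regulator: str
    p: float
    p_adj: float
    direction_score: float | None
    call: str                      # activated | inhibited | undetermined
    n_targets: int
    overlap: int


def differential_expression(
    matrix: ExpressionMatrix, labels: pd.Series, cluster
) -> pd.DataFrame:
    """Welch t-test of one cluster vs. the rest, per gene, BH-adjusted.

    Returns a DataFrame indexed by gene with columns log_fc (cluster mean
    minus rest mean, log2 scale), t, df, p, p_adj.  Genes with zero variance
    in both groups get p = 1 when the means agree and the smallest
    representable p (flagged in the ``degenerate`` column) when they differ.
    """
    y = labels.loc[matrix.samples]
    in_c = (y == cluster).to_numpy()
    if in_c.sum() < 2 or (~in_c).sum() < 2:
        raise ValueError("cluster and complement each need >= 2 samples")
    a = matrix.values.to_numpy()[:, in_c]
    b = matrix.values.to_numpy()[:, ~in_c]
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.asarray(res.statistic)
        p = np.asarray(res.pvalue)
        df = np.asarray(res.df)
    var0 = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    degenerate = var0 & (log_fc != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(var0 & (log_fc == 0), 0.0, t)
        p = np.where(var0 & (log_fc == 0), 1.0, p)
        p = np.where(degenerate, np.finfo(float).tiny, p)
        t = np.where(degenerate, np.sign(log_fc) * np.inf, t)
    out = pd.DataFrame(
        {
            "log_fc": log_fc,
            "t": t,
            "df": df,
            "p": p,
            "degenerate": degenerate,
        },
        index=matrix.genes,
    )
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["log_fc", "t", "df", "p", "p_adj", "degenerate"]]


def ora(
    query: list[str], terms: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query gene list in each term.

    p = P[X >= overlap] with X ~ Hypergeometric(universe, term, query); BH
    adjustment across terms.  Query genes outside the universe are dropped
    with a warning; term genes are intersected with the universe.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    q = {g.upper() for g in query}
    outside = q - universe_set
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped", len(outside))
        q &= universe_set
    M = len(universe_set)
    rows = []
    for term in terms:
        t = set(term.genes) & universe_set
        overlap = len(t & q)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(t), len(q))) if t else 1.0
        rows.append(
            {
                "term": term.name,
                "overlap": overlap,
                "term_size": len(t),
                "query_size": len(q),
                "universe_size": M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _parse_signed(genes: tuple[str, ...]) -> tuple[dict[str, int], bool]:
    """Strip +/- suffixes from regulon targets; returns (gene -> sign, signed?)."""
    signs: dict[str, int] = {}
    signed = False
    for g in genes:
        if g.endswith("+"):
            signs[g[:-1]] = 1
            signed = True
        elif g.endswith("-"):
            signs[g[:-1]] = -1
            signed = True
        else:
            signs[g] = 0
    return signs, signed


def upstream_regulators(
    signature: GeneSignature,
    regulons: GeneSetCollection,
    universe: list[str],
    p_adj_max: float = 0.05,
    score_min: float = 2.0,
) -> list[RegulatorCall]:
    """Rank candidate upstream regulators of a signature.

    Per regulator: hypergeometric overlap p of its targets with the
    signature's genes in the universe; if targets carry +/- signs, a
    direction score (concordant - discordant) / sqrt(n targets in universe)
    relative to the signature's direction.  A regulator is called activated
    (inhibited) when p_adj < ``p_adj_max`` and the score is >= ``score_min``
    (<= -``score_min``); unsigned regulons are always ``undetermined``.
    """
    universe_set = {g.upper() for g in universe}
    sig_genes = {g for g in signature.genes if g in universe_set}
    sig_sign = 1 if signature.direction == "positive" else -1
    M = len(universe_set)
    if M == 0:
        raise ValueError("universe is empty")
    raw = []
    for reg in regulons:
        signs, signed = _parse_signed(reg.genes)
        targets = {g: s for g, s in signs.items() if g in universe_set}
        hit = sig_genes & set(targets)
        p = float(stats.hypergeom.sf(len(hit) - 1, M, len(targets), len(sig_genes))) if targets else 1.0
        score = None
        if signed and targets:
            conc = sum(1 for g in hit if targets[g] * sig_sign > 0)
            disc = sum(1 for g in hit if targets[g] * sig_sign < 0)
            score = (conc - disc) / np.sqrt(len(targets))
        raw.append((reg.name, min(p, 1.0), score, len(targets), len(hit)))
    p_adj = multipletests([r[1] for r in raw], method="fdr_bh")[1]
    calls = []
    for (name, p, score, n_t, ov), q in zip(raw, p_adj):
        if score is None or q >= p_adj_max or abs(score) < score_min:
            call = "undetermined"
        else:
            call = "activated" if score > 0 else "inhibited"
        calls.append(
            RegulatorCall(
                regulator=name, p=p, p_adj=float(q), direction_score=score,
                call=call, n_targets=n_t, overlap=ov,
            )
        )
    calls.sort(key=lambda c: (c.p, c.regulator))
    return calls
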