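"""Weighted coexpression module detection, module-cluster association, and
hub genes.

The network follows the standard weighted-coexpression construction:
adjacency ``|pearson r|^beta`` with the soft threshold beta chosen as the
smallest power whose connectivity distribution shows an approximately
scale-free fit (R^2 >= 0.8), topological overlap similarity between genes,
average-linkage clustering of 1 - TOM with a static cut, and module
eigengenes as the first principal component of each module's expression.
kME — a gene's correlation with a module eigengene — ranks hub genes.

This is a deliberately simplified core: the tree cut is static (not the
dynamic hybrid cut) and the network is unsigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("pathstrat")


@dataclass
class ModuleSet:
    power: int
    assignments: pd.Series       # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame     # samples x modules, unit-norm columns
    kme: pd.DataFrame            # genes x modules
    scale_free_r2: float

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignments) - {0})

    def genes_in(self, module: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module])


@dataclass
class HubGeneReport:
    hubs: dict[int, pd.Series]   # module -> kME values of hub genes, ordered
    kme_min: float
    top_k: int


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over binned connectivities."""
    k = connectivity[connectivity > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float) / k.size
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 3:
        return 0.0
    res = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(res.rvalue**2)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zeroed diagonal."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    matrix: ExpressionMatrix,
    power: int | None = None,
    min_module_size: int = 10,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Detect coexpression modules from a genes x samples expression matrix.

    Requires >= 8 samples and >= 2 * min_module_size genes.  Constant gene
    rows are dropped with a warning.  If ``power`` is None the smallest beta
    in 1..20 with scale-free fit R^2 >= 0.8 is used (otherwise the argmax).
    Modules are numbered 1..M by decreasing size; genes in clusters smaller
    than ``min_module_size`` stay unassigned (module 0).
    """
    v = matrix.values
    if v.shape[1] < 8:
        raise ValueError("module detection needs >= 8 samples")
    sd = v.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning("dropping %d constant gene row(s)", len(constant))
        v = v.drop(index=constant)
    if v.shape[0] < 2 * min_module_size:
        raise ValueError("module detection needs >= 2 * min_module_size genes")
    genes = list(v.index)
    corr = np.corrcoef(v.to_numpy())
    corr = np.clip(np.abs(corr), 0.0, 1.0)

    r2 = {}
    if power is None:
        for beta in range(1, 21):
            a = corr**beta
            np.fill_diagonal(a, 0.0)
            r2[beta] = _scale_free_r2(a.sum(axis=1))
            if r2[beta] >= 0.8:
                power = beta
                break
        if power is None:
            power = max(r2, key=r2.get)
        fit = r2[power]
    else:
        a = corr**power
        np.fill_diagonal(a, 0.0)
        fit = _scale_free_r2(a.sum(axis=1))

    adjacency = corr**power
    tom = tom_similarity(adjacency)
    d = np.maximum(1.0 - tom, 0.0)  # guard against TOM float overshoot past 1
    np.fill_diagonal(d, 0.0)
    Z = average(squareform((d + d.T) / 2, checks=False))
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes.index[sizes >= min_module_size]
    # renumber kept modules 1..M by size descending (ties by raw id)
    order = sorted(keep, key=lambda cid: (-sizes[cid], cid))
    mapping = {cid: i + 1 for i, cid in enumerate(order)}
    assignments = pd.Series([mapping.get(c, 0) for c in raw], index=genes)

    eigengenes = {}
    for mod in sorted(mapping.values()):
        sub = v.loc[assignments.index[assignments == mod]]
        z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=1)).T.to_numpy()
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eg = vt[0]
        mean_expr = sub.mean(axis=0).to_numpy()
        if np.corrcoef(eg, mean_expr)[0, 1] < 0:
            eg = -eg
        eigengenes[mod] = eg / np.linalg.norm(eg)
    eg_df = pd.DataFrame(eigengenes, index=v.columns)

    kme = pd.DataFrame(index=genes, columns=eg_df.columns, dtype=float)
    vz = v.to_numpy()
    vz = (vz - vz.mean(axis=1, keepdims=True)) / vz.std(axis=1, ddof=1, keepdims=True)
    for mod in eg_df.columns:
        e = eg_df[mod].to_numpy()
        ez = (e - e.mean()) / e.std(ddof=1)
        kme[mod] = np.clip(vz @ ez / (v.shape[1] - 1), -1.0, 1.0)

    return ModuleSet(
        power=int(power), assignments=assignments, eigengenes=eg_df, kme=kme,
        scale_free_r2=float(fit),
    )


def module_cluster_association(modules: ModuleSet, labels: pd.Series) -> pd.DataFrame:
    """Assign each module to the cluster its eigengene correlates with most.

    Each eigengene is correlated with each cluster's indicator vector
    (point-biserial r); the module goes to the cluster with the largest r,
    with a two-sided p and BH adjustment across modules.
    """
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    if modules.eigengenes.shape[1] == 0:
        raise ValueError("module set has no modules")
    y = labels.loc[modules.eigengenes.index]
    rows = []
    for mod in modules.eigengenes.columns:
        eg = modules.eigengenes[mod].to_numpy()
        best = None
        for c in clusters:
            ind = (y == c).to_numpy(dtype=float)
            res = stats.pearsonr(eg, ind)
            if best is None or res.statistic > best[1]:
                best = (c, res.statistic, res.pvalue)
        rows.append({"module": mod, "cluster": best[0], "r": best[1], "p": best[2]})
    out = pd.DataFrame(rows).set_index("module")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def hub_genes(modules: ModuleSet, top_k: int = 10, kme_min: float = 0.8) -> HubGeneReport:
    """Top hub genes per module: members with kME >= kme_min, ranked by kME.

    Ties break by gene symbol; kME is compared at 10 decimal places so that
    exact ties are not broken by floating-point noise.  An unattainable
    threshold simply yields empty hub lists.
    """
    hubs: dict[int, pd.Series] = {}
    for mod in modules.module_ids():
        members = modules.genes_in(mod)
        k = modules.kme.loc[members, mod]
        k = k[k >= kme_min]
        order = np.lexsort((np.asarray(k.index), -np.round(k.to_numpy(), 10)))
        hubs[mod] = k.iloc[order].head(top_k)
    return HubGeneReport(hubs=hubs, kme_min=kme_min, top_k=top_k)
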