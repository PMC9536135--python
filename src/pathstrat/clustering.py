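"""Sample grouping on enrichment profiles: consensus clustering with
automatic choice of k, an NMF alternative, and a random-forest robustness
check.

Consensus clustering follows the Monti resampling scheme: repeatedly
subsample the cohort, cluster each subsample with seeded k-means, and record
how often each pair of samples lands in the same cluster, normalized by how
often the pair was co-sampled.  The proportion of ambiguous clustering
(PAC) — the fraction of off-diagonal consensus entries strictly between 0.1
and 0.9 — is minimized over the candidate k's; final labels come from
average-linkage hierarchical clustering of 1 - consensus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning

from .enrichment import EnrichmentProfile

logger = logging.getLogger("pathstrat")


def _profile_array(profile: EnrichmentProfile | pd.DataFrame) -> pd.DataFrame:
    """Complete-column NES matrix from a profile (or a plain DataFrame)."""
    nes = profile.nes if isinstance(profile, EnrichmentProfile) else profile
    keep = nes.columns[nes.notna().all(axis=0)]
    if len(keep) < nes.shape[1]:
        logger.info("dropping %d column(s) with missing values", nes.shape[1] - len(keep))
    return nes[keep]


@dataclass
class ConsensusResult:
    k_range: tuple[int, ...]
    consensus: dict[int, pd.DataFrame]   # per-k symmetric sample x sample
    pac: dict[int, float]
    chosen_k: int
    labels: pd.Series                    # sample -> cluster (1..k)
    n_resamples: int
    seed: int

    def __post_init__(self):
        for k, m in self.consensus.items():
            a = m.to_numpy()
            if not np.allclose(a, a.T):
                raise ValueError(f"consensus matrix for k={k} is not symmetric")
            if a.min() < -1e-12 or a.max() > 1 + 1e-12:
                raise ValueError(f"consensus entries for k={k} outside [0, 1]")
        if self.chosen_k not in self.k_range:
            raise ValueError("chosen_k not in k_range")


@dataclass
class RobustnessReport:
    oob_accuracy: float
    per_cluster_accuracy: dict[int, float]
    n_trees: int
    seed: int

    def __post_init__(self):
        accs = [self.oob_accuracy, *self.per_cluster_accuracy.values()]
        if any(not 0 <= a <= 1 for a in accs):
            raise ValueError("accuracies must lie in [0, 1]")


def consensus_cluster(
    profile: EnrichmentProfile | pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_resamples: int = 250,
    subsample: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Monti-style consensus clustering over a range of k.

    Inner clusterer is k-means (k-means++ init, seeded).  PAC(k) is the
    fraction of off-diagonal consensus entries in (0.1, 0.9); chosen_k is the
    PAC minimizer (ties -> smaller k).  Final labels are average-linkage
    hierarchical clusters of 1 - consensus at chosen_k.
    """
    X = _profile_array(profile)
    n = X.shape[0]
    k_range = tuple(sorted(k_range))
    if not all(2 <= k <= n - 1 for k in k_range):
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    if n_resamples < 50:
        raise ValueError("n_resamples must be >= 50")
    arr = X.to_numpy()
    m = max(2, int(np.floor(subsample * n)))

    ss = np.random.SeedSequence(seed)
    consensus: dict[int, pd.DataFrame] = {}
    pac: dict[int, float] = {}
    off_diag = ~np.eye(n, dtype=bool)
    for k, child in zip(k_range, ss.spawn(len(k_range))):
        rng = np.random.default_rng(child)
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(
                n_clusters=k, init="k-means++", n_init=3,
                random_state=int(rng.integers(2**31 - 1)),
            )
            lab = km.fit_predict(arr[idx])
            same = (lab[:, None] == lab[None, :]).astype(float)
            together[np.ix_(idx, idx)] += same
            cosampled[np.ix_(idx, idx)] += 1.0
        if np.any(cosampled[off_diag] == 0):
            raise ValueError(
                "some sample pair was never co-sampled; increase n_resamples"
            )
        cons = np.divide(together, cosampled, out=np.zeros_like(together), where=cosampled > 0)
        np.fill_diagonal(cons, np.where(np.diag(cosampled) > 0, 1.0, 0.0))
        cons = (cons + cons.T) / 2
        consensus[k] = pd.DataFrame(cons, index=X.index, columns=X.index)
        vals = cons[off_diag]
        pac[k] = float(np.mean((vals > 0.1) & (vals < 0.9)))

    chosen_k = min(k_range, key=lambda k: (pac[k], k))
    d = 1.0 - consensus[chosen_k].to_numpy()
    np.fill_diagonal(d, 0.0)
    Z = average(squareform(d, checks=False))
    labels = pd.Series(fcluster(Z, t=chosen_k, criterion="maxclust"), index=X.index)
    return ConsensusResult(
        k_range=k_range, consensus=consensus, pac=pac, chosen_k=chosen_k,
        labels=labels, n_resamples=n_resamples, seed=seed,
    )


def nmf_cluster(
    profile: EnrichmentProfile | pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
) -> pd.Series:
    """Cluster samples by non-negative matrix factorization of the profile.

    NES can be negative, so the profile is shifted to non-negative by
    subtracting its global minimum.  Multiplicative-update NMF is restarted
    ``n_restarts`` times; the factorization with the lowest Frobenius
    reconstruction error wins and each sample is assigned to its largest
    basis coefficient.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _profile_array(profile)
    arr = X.to_numpy()
    arr = arr - arr.min()
    ss = np.random.SeedSequence(seed)
    best_err, best_W = np.inf, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for child in ss.spawn(n_restarts):
            rs = int(np.random.default_rng(child).integers(2**31 - 1))
            model = NMF(
                n_components=k, solver="mu", init="random",
                max_iter=max_iter, random_state=rs,
            )
            W = model.fit_transform(arr)
            if model.reconstruction_err_ < best_err:
                best_err, best_W = model.reconstruction_err_, W
    return pd.Series(np.argmax(best_W, axis=1) + 1, index=X.index)


def rf_robustness(
    profile: EnrichmentProfile | pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> RobustnessReport:
    """Out-of-bag accuracy of a random forest predicting cluster labels."""
    X = _profile_array(profile)
    y = labels.loc[X.index].to_numpy()
    values, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        singles = values[counts < 2].tolist()
        raise ValueError(f"singleton cluster(s): {singles}")
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, bootstrap=True
    )
    rf.fit(X.to_numpy(), y)
    oob_pred = rf.classes_[np.argmax(rf.oob_decision_function_, axis=1)]
    per_cluster = {
        int(c): float(np.mean(oob_pred[y == c] == c)) for c in values
    }
    return RobustnessReport(
        oob_accuracy=float(np.mean(oob_pred == y)),
        per_cluster_accuracy=per_cluster,
        n_trees=n_trees,
        seed=seed,
    )
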