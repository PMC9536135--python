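"""Kaplan-Meier estimation, log-rank comparisons with multiplicity
correction, and limiting-dilution (single-hit Poisson) frequency estimation.

The Kaplan-Meier and Mantel-Cox log-rank engines are implemented directly
(they are small, and an independent reference implementation is used as an
oracle in the test suite).  The "Bonferroni-Hochberg" correction reported for
pairwise survival comparisons in this literature is ambiguous; here the
default is Benjamini-Hochberg step-up FDR with plain Bonferroni available by
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import SurvivalTable

logger = logging.getLogger("pathstrat")


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times of a group."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # risk-set size just before each event time
    median: float | None    # first event time with S(t) <= 0.5, None if never

    def __post_init__(self):
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("S(t) must be non-increasing")
        if self.survival.size and (self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12):
            raise ValueError("S(t) must lie in [0, 1]")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float
    groups: tuple

    def __post_init__(self):
        if self.chi_square < 0 or not 0 <= self.p <= 1:
            raise ValueError("invalid log-rank result")


@dataclass
class LDAResult:
    """Single-hit Poisson estimate of the frequency of assay-initiating cells."""

    frequency: float
    ci_low: float | None
    ci_high: float | None
    doses: tuple[float, ...]
    wells: tuple[int, ...]
    negatives: tuple[int, ...]
    boundary: bool = False
    model: str = "single-hit Poisson (cloglog binomial, unit slope in log dose)"


def _group_data(table: SurvivalTable, group) -> pd.DataFrame:
    if "group" not in table.data.columns:
        raise ValueError("survival table has no 'group' column")
    sub = table.data[table.data["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} is empty")
    return sub


def km_curve(table: SurvivalTable, group=None) -> KMCurve:
    """Kaplan-Meier product-limit curve for one group (or the whole table).

    Subjects censored at an event time t remain in the risk set for the
    deaths at t and leave afterwards.  The median is the smallest event time
    with S(t) <= 0.5, undefined (None) if S never reaches 0.5.
    """
    data = table.data if group is None else _group_data(table, group)
    times = data["time"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=int)
    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    s = 1.0
    for t in event_times:
        n_t = int(np.sum(times >= t))
        d_t = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
    surv_arr = np.asarray(surv)
    median = None
    below = np.flatnonzero(surv_arr <= 0.5) if surv_arr.size else np.array([])
    if below.size:
        median = float(event_times[below[0]])
    return KMCurve(
        times=event_times, survival=surv_arr, at_risk=np.asarray(at_risk, dtype=int),
        median=median,
    )


def logrank_test(table: SurvivalTable, groups: tuple | None = None) -> LogRankResult:
    """Mantel-Cox log-rank test across two or more groups.

    At each distinct event time the observed-minus-expected death counts per
    group accumulate with the hypergeometric variance-covariance; the
    statistic is the quadratic form over the first k-1 groups and p comes
    from the chi-square upper tail with df = k - 1.
    """
    data = table.data
    if "group" not in data.columns:
        raise ValueError("survival table has no 'group' column")
    if groups is None:
        groups = tuple(pd.unique(data["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = data[data["group"].isin(groups)]
    for g in groups:
        if not (data["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    times = data["time"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=int)
    gidx = data["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    k = len(groups)
    if events.sum() == 0:
        raise ValueError("no events in any group")

    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(np.sum((times == t) & (events == 1)))
        n_j = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_j = np.bincount(gidx[(times == t) & (events == 1)], minlength=k).astype(float)
        e_j = d_t * n_j / n_t
        OmE += d_j - e_j
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1)
            V += factor * (np.diag(n_j / n_t) - np.outer(n_j, n_j) / n_t**2)
    v = OmE[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(v @ np.linalg.pinv(Vsub) @ v) if v.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi_square=chi2, df=df, p=p, groups=tuple(groups))


def pairwise_logrank_adjusted(
    table: SurvivalTable, groups: tuple | None = None, method: str = "bh"
) -> pd.DataFrame:
    """All pairwise log-rank tests with multiplicity adjustment across pairs.

    method "bh" (Benjamini-Hochberg step-up, default) or "bonferroni".
    Returns a DataFrame with columns group_a, group_b, chi_square, p_raw, p_adj.
    """
    if method not in ("bh", "bonferroni"):
        raise ValueError("method must be 'bh' or 'bonferroni'")
    if groups is None:
        groups = tuple(pd.unique(table.data["group"]))
    rows = []
    for a, b in combinations(groups, 2):
        res = logrank_test(table, groups=(a, b))
        rows.append({"group_a": a, "group_b": b, "chi_square": res.chi_square, "p_raw": res.p})
    out = pd.DataFrame(rows)
    sm_method = "fdr_bh" if method == "bh" else "bonferroni"
    out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method=sm_method)[1]
    return out


def lda_frequency(doses, wells, negatives, alpha: float = 0.05) -> LDAResult:
    """Limiting-dilution frequency under the single-hit Poisson model.

    With initiating-cell frequency f, a well seeded with d cells is negative
    with probability exp(-f d), so the probability a well responds satisfies
    cloglog(P(positive)) = log f + log d.  The fit is an intercept-only
    binomial GLM with complementary log-log link and offset log(dose);
    f = exp(intercept) with a normal-theory CI on the log scale.  For a
    single dose this reduces to the closed form f = -ln(neg/wells) / dose.
    """
    doses = np.asarray(doses, dtype=float)
    wells = np.asarray(wells, dtype=int)
    negatives = np.asarray(negatives, dtype=int)
    if not (doses.shape == wells.shape == negatives.shape):
        raise ValueError("doses, wells, negatives must have equal length")
    if np.any(negatives < 0) or np.any(negatives > wells):
        raise ValueError("negatives must satisfy 0 <= negatives <= wells at each dose")
    if np.any(doses <= 0) or np.any(wells <= 0):
        raise ValueError("doses and wells must be positive")

    positives = wells - negatives
    if positives.sum() == 0 or negatives.sum() == 0:
        # every well negative (or every well positive): MLE on the boundary
        logger.warning("all wells %s: frequency estimate is a boundary value, no CI",
                       "negative" if positives.sum() == 0 else "positive")
        if positives.sum() == 0:
            freq = 0.0
        else:
            freq = 1.0
        return LDAResult(
            frequency=freq, ci_low=None, ci_high=None,
            doses=tuple(doses), wells=tuple(wells), negatives=tuple(negatives),
            boundary=True,
        )

    endog = np.column_stack([positives, negatives])
    exog = np.ones((len(doses), 1))
    model = sm.GLM(
        endog, exog,
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=np.log(doses),
    )
    import warnings

    with warnings.catch_warnings():
        # a single-dose fit has zero residual df; the MLE and its SE are still valid
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit()
    intercept = float(fit.params[0])
    se = float(fit.bse[0])
    z = stats.norm.ppf(1 - alpha / 2)
    freq = float(np.exp(intercept))
    return LDAResult(
        frequency=min(freq, 1.0),
        ci_low=float(np.exp(intercept - z * se)),
        ci_high=float(min(np.exp(intercept + z * se), 1.0)),
        doses=tuple(doses), wells=tuple(wells), negatives=tuple(negatives),
    )
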