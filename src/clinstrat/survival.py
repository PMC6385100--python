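"""Kaplan-Meier estimation, multi-group log-rank testing, and the
random-gene-set resampling null.

"5-year" outcome tests are operationalized by administrative censoring:
events after the horizon (default 60 months) become censored observations at
the horizon; records at or before it are untouched.

The resampling null asks whether the clinically guided gene set separates
outcomes better than chance: random gene sets of the same size are drawn,
clustered with identical settings, and their log-rank p-values compared with
the observed one ("smaller" means strictly smaller).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import kmeans_correlation
from .containers import ExpressionMatrix, OutcomeTable
from .preprocess import standardize_genes

log = logging.getLogger("clinstrat")


@dataclass
class KMCurve:
    group: str
    times: np.ndarray  # ordered distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: pd.Series  # events per group
    expected: pd.Series  # hypergeometric-expected events per group


@dataclass
class NullComparisonResult:
    observed_p: float
    null_ps: np.ndarray
    n_smaller: int  # null p strictly below the observed p
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.null_ps)


def truncate_horizon(outcomes: OutcomeTable, horizon: float = 60.0) -> OutcomeTable:
    """Administratively censor every record beyond ``horizon`` months.

    An event at exactly the horizon stays an event.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not np.isfinite(horizon):
        return OutcomeTable(outcomes.data.copy(), outcomes.endpoint)
    data = outcomes.data.copy()
    over = data["time"] > horizon
    data.loc[over, "time"] = horizon
    data.loc[over, "event"] = False
    return OutcomeTable(data, outcomes.endpoint)


def km_estimate(outcomes: OutcomeTable, group: str = "all") -> KMCurve:
    """Product-limit survival estimate for one group of samples.

    Samples censored exactly at an event time are counted as at risk at that
    time (the standard convention).
    """
    mask = outcomes.complete_mask
    if not mask.any():
        raise ValueError("empty group")
    time = outcomes.time[mask]
    event = outcomes.event[mask]
    event_times = np.unique(time[event])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_risk = int(np.sum(time >= t))
        d = int(np.sum(event & (time == t)))
        s *= 1.0 - d / n_risk
        surv[i] = s
        at_risk[i] = n_risk
    return KMCurve(group=group, times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(outcomes: OutcomeTable, groups: pd.Series) -> LogRankResult:
    """Mantel-Haenszel log-rank test across two or more groups.

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the risk sets; the summed
    (O - E) vector is combined through the summed covariance matrix into a
    chi-square statistic with (G - 1) degrees of freedom. No continuity
    correction.
    """
    if set(groups.index) != set(outcomes.sample_ids):
        raise ValueError("groups and outcomes cover different samples")
    groups = groups.loc[outcomes.sample_ids]
    mask = outcomes.complete_mask
    time = outcomes.time[mask]
    event = outcomes.event[mask]
    g_labels, g_codes = np.unique(groups.to_numpy()[mask], return_inverse=True)
    n_groups = len(g_labels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if not event.any():
        raise ValueError("no events")

    observed = np.zeros(n_groups)
    expected = np.zeros(n_groups)
    cov = np.zeros((n_groups, n_groups))
    for t in np.unique(time[event]):
        at_risk = time >= t
        n_t = int(at_risk.sum())
        d_t = int(np.sum(event & (time == t)))
        n_g = np.bincount(g_codes[at_risk], minlength=n_groups).astype(float)
        d_g = np.bincount(g_codes[event & (time == t)], minlength=n_groups).astype(float)
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    df = n_groups - 1
    p = float(stats.chi2.sf(chi2, df))
    p = max(p, np.nextafter(0.0, 1.0))
    return LogRankResult(
        chi_square=chi2,
        df=df,
        p_value=p,
        observed=pd.Series(observed, index=g_labels, name="observed"),
        expected=pd.Series(expected, index=g_labels, name="expected"),
    )


def random_geneset_null(
    expr: ExpressionMatrix,
    outcomes: OutcomeTable,
    geneset_size: int,
    k: int,
    observed_p: float,
    n_draws: int,
    n_replicates: int = 100,
    horizon: float = 60.0,
    seed: int = 0,
) -> NullComparisonResult:
    """Compare the observed log-rank p-value with p-values from ``n_draws``
    uniformly random gene sets of the same size, each standardized and
    clustered with the identical settings (k, replicates, distance); only
    the genes and the seed differ between draws.
    """
    if geneset_size > expr.n_genes:
        raise ValueError("gene-set size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    truncated = truncate_horizon(outcomes, horizon)
    null_ps = np.empty(n_draws)
    gene_ids = np.asarray(expr.gene_ids)
    for i in range(n_draws):
        draw = rng.choice(len(gene_ids), size=geneset_size, replace=False)
        sub = standardize_genes(expr.subset_genes(gene_ids[draw]))
        clusters = kmeans_correlation(
            sub, k, n_replicates=n_replicates, seed=int(rng.integers(2**31))
        )
        null_ps[i] = logrank_test(truncated, clusters.assignment).p_value
    n_smaller = int(np.sum(null_ps < observed_p))
    log.info("resampling null: %d / %d draws below observed p", n_smaller, n_draws)
    return NullComparisonResult(
        observed_p=observed_p, null_ps=null_ps, n_smaller=n_smaller, seed=seed
    )
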