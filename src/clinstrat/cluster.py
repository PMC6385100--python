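"""k-means over samples in correlation geometry, plus partition concordance.

Correlation distance between two sample profiles is 1 - r. On rows that have
been centered to zero mean and scaled to unit norm, 1 - r equals half the
squared Euclidean distance, so Lloyd iterations on the transformed rows
minimize total correlation distance directly: the assignment step picks the
nearest centroid, and the update step (mean of members, re-centered and
re-normalized) maximizes within-cluster correlation by Cauchy-Schwarz.
Each replicate restarts from its own k-means++ style initialization; the
replicate with the lowest objective wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import ExpressionMatrix

log = logging.getLogger("clinstrat")

MAX_ITER = 300


@dataclass
class ClusterResult:
    assignment: pd.Series  # sample id -> cluster index 1..K
    objective: float  # total within-cluster correlation distance
    n_replicates_run: int
    best_replicate_seed: int


@dataclass
class ConcordanceResult:
    ari: float
    contingency: pd.DataFrame  # clusters x labels count table


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation between two sample profiles; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("profiles must have equal length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance profile")
    return float(1.0 - (xc @ yc) / (nx * ny))


def _standardize_rows(rows: np.ndarray) -> np.ndarray:
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance sample profile")
    return centered / norms


def _plusplus_init(U: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding in correlation distance (D(x, c) = 1 - x . c)."""
    n = U.shape[0]
    centers = np.empty((k, U.shape[1]))
    centers[0] = U[rng.integers(n)]
    d = 1.0 - U @ centers[0]
    for j in range(1, k):
        d = np.clip(d, 1e-15, None)
        probs = d / d.sum()
        centers[j] = U[rng.choice(n, p=probs)]
        d = np.minimum(d, 1.0 - U @ centers[j])
    return centers


def _lloyd(U: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    n = U.shape[0]
    centers = _plusplus_init(U, k, rng)
    assign = np.full(n, -1)
    prev_obj = np.inf
    for _ in range(MAX_ITER):
        sim = U @ centers.T  # correlation of each sample with each centroid
        new_assign = sim.argmax(axis=1)
        # re-seed empty clusters with the sample farthest from its centroid
        for j in range(k):
            if not np.any(new_assign == j):
                dist = 1.0 - sim[np.arange(n), new_assign]
                far = int(dist.argmax())
                centers[j] = U[far]
                new_assign[far] = j
                sim = U @ centers.T
        obj = float(np.sum(1.0 - (U @ centers.T)[np.arange(n), new_assign]))
        assert obj <= prev_obj + 1e-9, "Lloyd objective increased"
        if np.array_equal(new_assign, assign):
            break
        assign, prev_obj = new_assign, obj
        for j in range(k):
            members = U[assign == j]
            c = members.mean(axis=0)
            c = c - c.mean()
            norm = np.linalg.norm(c)
            if norm > 0:
                centers[j] = c / norm
    obj = float(np.sum(1.0 - (U @ centers.T)[np.arange(n), assign]))
    return assign, obj


def kmeans_correlation(
    expr: ExpressionMatrix, k: int, n_replicates: int = 100, seed: int = 0
) -> ClusterResult:
    """Cluster samples (columns of ``expr``) into ``k`` groups under
    correlation distance, best of ``n_replicates`` seeded restarts.

    ``expr`` should already be gene-standardized; sample profiles are
    additionally row-standardized internally (see module docstring).
    """
    n = expr.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    U = _standardize_rows(expr.values.T)  # samples x genes
    replicate_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    best: tuple[float, np.ndarray, int] | None = None
    for rep, ss in enumerate(replicate_seeds):
        assign, obj = _lloyd(U, k, np.random.default_rng(ss))
        if best is None or obj < best[0]:
            best = (obj, assign, rep)
    obj, assign, rep = best
    return ClusterResult(
        assignment=pd.Series(assign + 1, index=expr.sample_ids, name="cluster"),
        objective=obj,
        n_replicates_run=n_replicates,
        best_replicate_seed=rep,
    )


def adjusted_rand_index(a: pd.Series, b: pd.Series) -> ConcordanceResult:
    """Hubert-Arabie adjusted Rand index between two partitions of the same
    samples, with the clusters x labels contingency table."""
    if set(a.index) != set(b.index):
        raise ValueError("partitions cover different sample sets")
    b = b.loc[a.index]
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    contingency = pd.crosstab(a, b)
    return ConcordanceResult(ari=ari, contingency=contingency)
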