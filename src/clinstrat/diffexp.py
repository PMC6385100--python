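"""Permutation-based differential expression, SAM-style, on a rank statistic.

Each gene is scored by the standardized Wilcoxon rank-sum z of the focal
group against the rest (tie-corrected null variance). Group labels are
permuted a configurable number of times — the same permutation applied to
all genes, preserving gene-gene correlation — and for each threshold t equal
to an observed |z| the false discovery rate is estimated as the median
across permutations of the null exceedance count divided by the observed
exceedance count. A gene's q-value is the smallest estimated FDR over
rejection regions containing it, which makes q monotone in |z|.

A variance-stabilizing fudge factor is not applicable to a rank statistic
and is intentionally absent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

log = logging.getLogger("clinstrat")


@dataclass
class DEResult:
    gene_id: str
    statistic: float  # signed z; positive = higher in the focal group
    direction: str  # "up" or "down" in the focal group
    q_value: float
    rank: int  # 1 = largest |z|


def wilcoxon_z(gene: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum statistic of the focal group.

    z = (W - n1(n+1)/2) / sd, with the usual tie-corrected variance.
    Returns 0 when every sample shares one value (zero null variance).
    """
    gene = np.asarray(gene, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    if not in_group.any() or in_group.all():
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(gene)
    z = _z_from_ranks(ranks[None, :], in_group, _tie_term(gene[None, :]))
    return float(z[0])


def _tie_term(X: np.ndarray) -> np.ndarray:
    """Per-gene tie correction sum(t^3 - t) over tied groups."""
    srt = np.sort(X, axis=1)
    terms = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        terms[i] = np.sum(counts**3 - counts)
    return terms


def _z_from_ranks(ranks: np.ndarray, in_group: np.ndarray, tie_terms: np.ndarray) -> np.ndarray:
    n = ranks.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    w = ranks[:, in_group].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_terms / (12.0 * n * (n - 1))
    z = np.zeros(ranks.shape[0])
    ok = var > 0
    z[ok] = (w[ok] - mu) / np.sqrt(var[ok])
    return z


def permutation_qvalues(
    expr: ExpressionMatrix,
    in_group: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[DEResult]:
    """Observed z per gene plus permutation q-values (see module docstring).

    All genes share each permutation, and the whole procedure is reproducible
    from ``seed``.
    """
    in_group = np.asarray(in_group, dtype=bool)
    if not in_group.any() or in_group.all():
        raise ValueError("focal mask selects all or no samples")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    X = expr.values
    n_genes, n = X.shape
    ranks = np.vstack([stats.rankdata(row) for row in X])
    tie_terms = _tie_term(X)
    obs_z = _z_from_ranks(ranks, in_group, tie_terms)
    obs_abs = np.abs(obs_z)

    rng = np.random.default_rng(seed)
    n1 = int(in_group.sum())
    perm_members = np.zeros((n, n_permutations))
    for p in range(n_permutations):
        perm_members[rng.choice(n, size=n1, replace=False), p] = 1.0
    w_perm = ranks @ perm_members  # genes x permutations
    mu = n1 * (n + 1) / 2.0
    n2 = n - n1
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_terms / (12.0 * n * (n - 1))
    sd = np.sqrt(np.where(var > 0, var, 1.0))
    null_abs = np.abs((w_perm - mu) / sd[:, None])
    null_abs[var <= 0, :] = 0.0

    # order genes by decreasing |z|; ties by gene id for determinism
    gene_ids = np.asarray(expr.gene_ids)
    order = np.lexsort((gene_ids, -obs_abs))
    thresholds = obs_abs[order]
    # per-permutation null exceedance counts at every threshold, via one
    # sorted pass per permutation
    null_counts = np.empty((n_permutations, n_genes), dtype=np.int64)
    asc_thresholds = thresholds[::-1]
    for p in range(n_permutations):
        col = np.sort(null_abs[:, p])
        null_counts[p] = (n_genes - np.searchsorted(col, asc_thresholds, side="left"))[::-1]
    # observed exceedances: ties share the count of the whole tied block
    asc_obs = np.sort(obs_abs)
    obs_counts = (n_genes - np.searchsorted(asc_obs, asc_thresholds, side="left"))[::-1]
    fdr = np.clip(np.median(null_counts, axis=0) / obs_counts, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]

    results = []
    for pos, idx in enumerate(order):
        results.append(
            DEResult(
                gene_id=str(gene_ids[idx]),
                statistic=float(obs_z[idx]),
                direction="up" if obs_z[idx] >= 0 else "down",
                q_value=float(q_sorted[pos]),
                rank=pos + 1,
            )
        )
    return results


def top_de_genes(results: list[DEResult], n_top: int = 1000, q_cut: float = 0.05) -> list[str]:
    """Genes with q below ``q_cut``, ordered by decreasing |z| (ties by gene
    id), truncated to ``n_top``."""
    if n_top < 1:
        raise ValueError("n_top must be positive")
    passing = [r for r in results if r.q_value < q_cut]
    passing.sort(key=lambda r: (-abs(r.statistic), r.gene_id))
    if not passing:
        warnings.warn("no genes pass the q-value cutoff")
    elif len(passing) < n_top:
        warnings.warn(f"only {len(passing)} genes pass the q-value cutoff")
    return [r.gene_id for r in passing[:n_top]]


def de_overlap(gene_lists: dict[str, list[str]]) -> dict[str, int]:
    """Pairwise and joint intersection sizes of per-subtype DE gene lists."""
    if len(gene_lists) < 2:
        raise ValueError("need at least 2 gene lists")
    names = list(gene_lists)
    sets = {n: set(g) for n, g in gene_lists.items()}
    out: dict[str, int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}&{b}"] = len(sets[a] & sets[b])
    out["&".join(names)] = len(set.intersection(*sets.values()))
    return out


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.statistic, r.direction, r.q_value, r.rank) for r in results],
        columns=["gene", "z", "direction", "q_value", "rank"],
    )
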