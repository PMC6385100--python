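"""Mixed-type maximum-relevance / minimum-redundancy gene selection.

For each clinical variable a gene subset is grown greedily: relevance of a
gene to a categorical variable is the one-way ANOVA F statistic of its
expression across the variable's levels; relevance to a continuous variable
is the absolute Pearson correlation. Redundancy of a candidate is its mean
absolute Pearson correlation to the genes already selected. The first gene
maximizes relevance alone; every later step maximizes the quotient
phi = D / R (the MIQ criterion, with F or |PCC| standing in for mutual
information). The search is restricted to the top-``pool`` genes by marginal
relevance, and the per-variable selections are unioned into one candidate
set for clustering.

Relevance scales differ between the two kinds (F is unbounded, |PCC| <= 1)
but are never compared across variables: selection is strictly per-variable.

Absolute values are used for the Pearson terms in both relevance and
redundancy: signed means would let anticorrelated genes cancel, defeating
the "least correlated among themselves" goal, and the sign of a
gene-covariate correlation carries no selection-relevant information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CATEGORICAL, CONTINUOUS, ClinicalTable, ExpressionMatrix

log = logging.getLogger("clinstrat")

#: Redundancy below this is treated as zero; phi is then D / R_FLOOR, making
#: near-orthogonal genes maximally attractive while keeping phi finite.
R_FLOOR = 1e-12


@dataclass
class GreedyTrace:
    """One step of the greedy search: the gene picked and its scores."""

    step: int  # 1-based selection order
    gene_id: str
    relevance_D: float
    redundancy_R: float  # mean |PCC| to previously selected; 0.0 at step 1
    phi: float  # D at step 1, D / max(R, R_FLOOR) afterwards


@dataclass
class SelectionResult:
    per_variable: dict[str, list[GreedyTrace]]
    union_genes: list[str] = field(default_factory=list)
    pool_size: int = 0
    k_per_variable: int = 0


# ---------------------------------------------------------------------------
# relevance and redundancy primitives


def relevance_categorical(gene: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic of a gene's expression across label groups.

    Samples with a missing label are dropped first. Single-sample groups are
    allowed (they contribute zero within-group sum of squares). Returns 0
    when the between-group sum of squares is 0.
    """
    gene = np.asarray(gene, dtype=float)
    labels = np.asarray(labels, dtype=object)
    keep = ~pd.isna(labels)
    gene, labels = gene[keep], labels[keep]
    codes, counts = _encode(labels)
    n_groups = len(counts)
    if n_groups < 2:
        raise ValueError("need at least 2 non-empty groups")
    if len(gene) - n_groups == 0:
        raise ValueError("degenerate grouping: zero within-group degrees of freedom")
    return float(categorical_relevance_all(gene[None, :], codes, counts)[0])


def relevance_continuous(gene: np.ndarray, covariate: np.ndarray) -> float:
    """Absolute Pearson correlation between a gene and a continuous covariate."""
    gene = np.asarray(gene, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    keep = np.isfinite(covariate)
    gene, covariate = gene[keep], covariate[keep]
    if len(gene) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(gene) == 0 or np.ptp(covariate) == 0:
        raise ValueError("zero-variance input")
    return float(continuous_relevance_all(gene[None, :], covariate)[0])


def redundancy(gene: np.ndarray, selected: np.ndarray) -> float:
    """Mean absolute Pearson correlation of a candidate gene to each
    already-selected gene."""
    selected = np.atleast_2d(np.asarray(selected, dtype=float))
    if selected.shape[0] == 0:
        raise ValueError("selected set is empty")
    gene = np.asarray(gene, dtype=float)
    if np.ptp(gene) == 0:
        raise ValueError("zero-variance gene")
    u = _row_unit(gene[None, :])
    v = _row_unit(selected)
    return float(np.mean(np.abs(v @ u[0])))


def _encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, codes = np.unique(labels.astype(str), return_inverse=True)
    counts = np.bincount(codes)
    return codes, counts


def _row_unit(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so u_i . u_j = PCC(x_i, x_j)."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # zero-variance rows correlate 0 with everything
    return centered / norms


def categorical_relevance_all(
    X: np.ndarray, codes: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """F statistic of every gene (row of X) against integer-coded groups."""
    n = X.shape[1]
    n_groups = len(counts)
    indicator = np.zeros((n, n_groups))
    indicator[np.arange(n), codes] = 1.0
    group_sums = X @ indicator  # genes x groups
    group_means = group_sums / counts
    grand_mean = X.mean(axis=1, keepdims=True)
    ssb = ((group_means - grand_mean) ** 2 * counts).sum(axis=1)
    sst = ((X - grand_mean) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    df_b, df_w = n_groups - 1, n - n_groups
    if df_w == 0:
        raise ValueError("degenerate grouping: zero within-group degrees of freedom")
    msb, msw = ssb / df_b, ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssb == 0, 0.0, np.where(msw == 0, np.inf, msb / np.where(msw == 0, 1, msw)))
    return f


def continuous_relevance_all(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|PCC| of every gene (row of X) with a continuous covariate."""
    u = _row_unit(X)
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)
    if y_norm == 0:
        raise ValueError("zero-variance covariate")
    return np.abs(u @ (yc / y_norm))


def relevance_all(X: np.ndarray, values: pd.Series, kind: str) -> np.ndarray:
    """Relevance of every gene to one clinical column, dispatched on kind."""
    if kind == CATEGORICAL:
        labels = values.to_numpy(dtype=object)
        keep = ~pd.isna(labels)
        codes, counts = _encode(labels[keep])
        if len(counts) < 2:
            raise ValueError(f"clinical variable {values.name!r}: fewer than 2 groups")
        return categorical_relevance_all(X[:, keep], codes, counts)
    if kind == CONTINUOUS:
        y = values.to_numpy(dtype=float)
        keep = np.isfinite(y)
        return continuous_relevance_all(X[:, keep], y[keep])
    raise ValueError(f"unknown variable kind {kind!r}")


# ---------------------------------------------------------------------------
# greedy search


def select_for_variable(
    expr: ExpressionMatrix,
    values: pd.Series,
    kind: str,
    pool: int,
    k: int,
) -> list[GreedyTrace]:
    """Greedy MIQ selection of ``k`` genes for one clinical variable.

    Ties in phi are broken by higher relevance, then lexicographic gene id,
    so the output is deterministic across platforms.
    """
    if k > pool:
        raise ValueError("k must not exceed pool")
    pool = min(pool, expr.n_genes)
    if k > pool:
        raise ValueError("k exceeds the number of available genes")
    gene_ids = np.asarray(expr.gene_ids)
    X = expr.values
    rel = relevance_all(X, values, kind)
    if np.all(rel == 0):
        warnings.warn(f"all relevances are zero for variable {values.name!r}")
    # top-`pool` by relevance; ties by gene id for determinism
    order = np.lexsort((gene_ids, -rel))[:pool]
    pool_ids = gene_ids[order]
    pool_rel = rel[order]
    U = _row_unit(X[order])
    return greedy_miq(pool_rel, pool_ids, lambda i: np.abs(U @ U[i]), k)


def greedy_miq(
    pool_rel: np.ndarray,
    pool_ids: np.ndarray,
    abs_corr_to,
    k: int,
) -> list[GreedyTrace]:
    """Greedy MIQ search over a candidate pool already sorted by
    (relevance desc, gene id asc).

    ``abs_corr_to(i)`` returns the vector of |PCC| between candidate ``i``
    and every candidate — computed lazily so only the k selected genes ever
    need their correlation profile.
    """
    pool = len(pool_rel)
    trace: list[GreedyTrace] = []
    selected_mask = np.zeros(pool, dtype=bool)
    first = 0  # pool order is (relevance desc, id asc)
    selected_mask[first] = True
    trace.append(GreedyTrace(1, str(pool_ids[first]), float(pool_rel[first]), 0.0, float(pool_rel[first])))
    abs_corr_sum = np.asarray(abs_corr_to(first), dtype=float).copy()

    for step in range(2, k + 1):
        r_mean = abs_corr_sum / (step - 1)
        phi = pool_rel / np.maximum(r_mean, R_FLOOR)
        phi[selected_mask] = -np.inf
        tied = np.flatnonzero(phi == phi.max())
        if len(tied) > 1:
            tied = tied[np.lexsort((pool_ids[tied], -pool_rel[tied]))]
        pick = int(tied[0])
        selected_mask[pick] = True
        trace.append(
            GreedyTrace(step, str(pool_ids[pick]), float(pool_rel[pick]),
                        float(r_mean[pick]), float(phi[pick]))
        )
        abs_corr_sum += np.abs(abs_corr_to(pick))
    return trace


def integrate_union(per_variable: dict[str, list[GreedyTrace]]) -> list[str]:
    """Union of the per-variable selections, ordered by first appearance over
    variables (in the given order) then selection rank; duplicates once."""
    seen: dict[str, None] = {}
    for traces in per_variable.values():
        for t in traces:
            seen.setdefault(t.gene_id, None)
    return list(seen)


def select_all_variables(
    expr: ExpressionMatrix, clin: ClinicalTable, pool: int, k: int
) -> SelectionResult:
    """Run the per-variable greedy search for every clinical variable and
    union the selections into the clustering candidate set."""
    per_variable: dict[str, list[GreedyTrace]] = {}
    for name in clin.data.columns:
        per_variable[name] = select_for_variable(
            expr, clin.data[name], clin.kinds[name], pool, k
        )
        log.info("selected %d genes for clinical variable %r", k, name)
    union = integrate_union(per_variable)
    log.info("union of per-variable selections: %d genes", len(union))
    return SelectionResult(per_variable, union, pool_size=pool, k_per_variable=k)


def selection_to_frame(result: SelectionResult) -> pd.DataFrame:
    """Flatten a SelectionResult into a tidy table (variable, rank, gene, D, R, phi)."""
    rows = []
    for var, traces in result.per_variable.items():
        for t in traces:
            rows.append((var, t.step, t.gene_id, t.relevance_D, t.redundancy_R, t.phi))
    return pd.DataFrame(rows, columns=["variable", "rank", "gene", "D", "R", "phi"])
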