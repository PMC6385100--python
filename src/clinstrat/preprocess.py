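"""Filtering, imputation, and per-gene standardization.

The order of operations in the full pipeline is: sample exclusions ->
flat-feature filtering (expression and clinical) -> clinical imputation ->
per-gene standardization. Standardization is recomputed over whichever
sample set is about to be clustered, so subgroup re-analyses re-standardize
over the subgroup.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONTINUOUS,
    Bundle,
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
)

log = logging.getLogger("clinstrat")


@dataclass
class PreprocessReport:
    genes_removed_flat: int = 0
    clinical_vars_removed_flat: int = 0
    cells_imputed: dict[str, int] = field(default_factory=dict)
    samples_excluded: dict[str, int] = field(default_factory=dict)


def flat_filter(
    table: ExpressionMatrix | ClinicalTable, threshold: float = 0.80
) -> tuple[ExpressionMatrix | ClinicalTable, list[str]]:
    """Drop features whose single most frequent value covers strictly more
    than ``threshold`` of the samples.

    The mode is an exact match (exact numeric equality for continuous
    features); missing values never count toward it. A feature flat on
    exactly ``threshold * N`` samples is kept.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(table, ExpressionMatrix):
        n = table.n_samples
        mode_counts = _row_mode_counts(table.values)
        keep = mode_counts <= threshold * n
        removed = [g for g, k in zip(table.gene_ids, keep) if not k]
        if not keep.any():
            raise ValidationError("no informative features after flat filter")
        return ExpressionMatrix(table.data.loc[keep]), removed
    n = len(table.sample_ids)
    removed = []
    for name in table.data.columns:
        counts = table.data[name].value_counts(dropna=True)
        if len(counts) and counts.iloc[0] > threshold * n:
            removed.append(name)
    kept_cols = [c for c in table.data.columns if c not in removed]
    if not kept_cols:
        raise ValidationError("no informative features after flat filter")
    kinds = {c: table.kinds[c] for c in kept_cols}
    return ClinicalTable(table.data[kept_cols].copy(), kinds), removed


def _row_mode_counts(values: np.ndarray) -> np.ndarray:
    """Count of the most frequent exact value per row."""
    ordered = np.sort(values, axis=1)
    # run-length encode each sorted row
    change = np.ones_like(ordered, dtype=bool)
    change[:, 1:] = ordered[:, 1:] != ordered[:, :-1]
    counts = np.empty(values.shape[0], dtype=int)
    for i in range(values.shape[0]):
        starts = np.flatnonzero(change[i])
        counts[i] = int(np.diff(np.append(starts, values.shape[1])).max())
    return counts


def impute_clinical(clin: ClinicalTable) -> tuple[ClinicalTable, PreprocessReport]:
    """Fill missing clinical cells: continuous -> column median, categorical
    -> most frequent level (ties broken by lexicographic level name)."""
    data = clin.data.copy()
    report = PreprocessReport()
    for name in data.columns:
        col = data[name]
        missing = col.isna()
        if not missing.any():
            report.cells_imputed[name] = 0
            continue
        if missing.all():
            raise ValidationError(f"clinical variable {name!r} is entirely missing")
        if clin.kinds[name] == CONTINUOUS:
            fill = float(col.median(skipna=True))
        else:
            counts = col.value_counts(dropna=True)
            top = counts[counts == counts.iloc[0]]
            fill = sorted(top.index)[0]
        data.loc[missing, name] = fill
        report.cells_imputed[name] = int(missing.sum())
    return ClinicalTable(data, dict(clin.kinds)), report


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale every gene to mean 0, SD 1 (ddof=1) over the current
    samples; zero-variance genes are dropped with a warning."""
    values = expr.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}")
        values, sd = values[keep], sd[keep]
    centered = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(centered, index=np.asarray(expr.gene_ids)[keep], columns=expr.sample_ids)
    )


def apply_exclusions(bundle: Bundle, exclude_ids: set[str], reason: str = "excluded") -> tuple[Bundle, PreprocessReport]:
    """Drop an explicit list of samples (e.g. male / metastatic / unknown-tissue
    records supplied as metadata) from every table of the bundle."""
    keep = [s for s in bundle.sample_ids if s not in exclude_ids]
    if not keep:
        raise ValidationError("all samples excluded")
    report = PreprocessReport(samples_excluded={reason: len(bundle.sample_ids) - len(keep)})
    return bundle.subset_samples(keep), report


def preprocess_bundle(
    bundle: Bundle, flat_threshold: float = 0.80
) -> tuple[Bundle, PreprocessReport]:
    """Flat-filter expression and clinical tables, then impute clinical."""
    expr, genes_removed = flat_filter(bundle.expression, flat_threshold)
    clin, vars_removed = flat_filter(bundle.clinical, flat_threshold)
    clin, impute_report = impute_clinical(clin)
    report = PreprocessReport(
        genes_removed_flat=len(genes_removed),
        clinical_vars_removed_flat=len(vars_removed),
        cells_imputed=impute_report.cells_imputed,
    )
    log.info(
        "preprocess: removed %d flat genes, %d flat clinical variables",
        report.genes_removed_flat, report.clinical_vars_removed_flat,
    )
    return Bundle(expr, clin, bundle.outcomes, bundle.labels), report
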