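"""Readers and writers for the tab-separated table formats.

Expression is genes-as-rows TSV (the orientation UCSC Xena exports use);
clinical, outcome and label tables are samples-as-rows TSV with a header.
Missing clinical values may be encoded by any of a configurable set of
tokens (empty cell, "NA", "Unknown"); all become the NaN missing marker,
never a category level of their own.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    CATEGORICAL,
    CONTINUOUS,
    ClinicalTable,
    ExpressionMatrix,
    LabelTable,
    OutcomeTable,
    ValidationError,
)

log = logging.getLogger("clinstrat")

DEFAULT_MISSING_TOKENS = ("", "NA", "Unknown")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: no genes")
    try:
        values = df.astype(np.float64)  # exact round-trip parsing
    except (ValueError, TypeError):
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValidationError(
                        f"{path}: non-numeric cell {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    matrix = ExpressionMatrix(values)
    log.info("read expression: %d genes x %d samples from %s", matrix.n_genes, matrix.n_samples, path)
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_clinical(
    path: str | Path,
    variable_kinds: Mapping[str, str],
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> ClinicalTable:
    """Read a samples x variables TSV; column types come from ``variable_kinds``.

    Columns absent from ``variable_kinds`` fall back to an inference rule:
    continuous iff all non-missing cells parse as numbers and the column has
    more than 10 distinct values, else categorical.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    tokens = set(missing_tokens)
    df = df.apply(lambda col: col.where(~col.isin(tokens), np.nan))
    kinds: dict[str, str] = {}
    for name in df.columns:
        if name in variable_kinds:
            kinds[name] = variable_kinds[name]
        else:
            kinds[name] = _infer_kind(df[name])
            log.info("inferred kind %s for clinical variable %r", kinds[name], name)
    return ClinicalTable(df, kinds)


def _infer_kind(col: pd.Series) -> str:
    non_missing = col.dropna()
    numeric = pd.to_numeric(non_missing, errors="coerce")
    if numeric.notna().all() and non_missing.nunique() > 10:
        return CONTINUOUS
    return CATEGORICAL


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")
    kinds_path = Path(path).with_suffix(".kinds.tsv")
    pd.Series(dict(table.kinds), name="kind").to_csv(kinds_path, sep="\t", index_label="variable")


def read_clinical_kinds(path: str | Path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col=0)["kind"]
    return {str(k): str(v) for k, v in s.items()}


def read_outcomes(path: str | Path, endpoint: str = "survival") -> OutcomeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    event = df["event"]
    if event.dtype == object:
        event = event.map({"True": True, "False": False, "1": True, "0": False})
    return OutcomeTable(pd.DataFrame({"time": df["time"], "event": event.astype("boolean")}), endpoint)


def write_outcomes(table: OutcomeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def read_labels(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    return LabelTable(df.iloc[:, 0])


def write_labels(table: LabelTable, path: str | Path) -> None:
    table.labels.rename("label").to_csv(path, sep="\t", index_label="sample")
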