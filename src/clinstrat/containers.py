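"""Typed containers for the tables the pipeline consumes.

All tables are aligned by sample *identifier*, never by column position:
TCGA-style exports routinely arrive with samples in inconsistent orders, so
positional alignment silently corrupts analyses. Expression values are
log2(count+1)-scale doubles; clinical tables mix categorical and continuous
columns with an explicit missing marker (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(f"duplicate {what} identifier(s): {', '.join(map(str, dups.index[:5]))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix, log2(x+1) scale.

    ``data`` has gene identifiers as the index and sample identifiers as
    columns. Missing expression is not supported: every cell must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.columns[
                [not np.issubdtype(dt, np.number) for dt in self.data.dtypes]
            ]
            raise ValidationError(f"non-numeric expression column(s): {list(bad[:5])}")
        if not np.all(np.isfinite(values)):
            rows, cols = np.where(~np.isfinite(values))
            gene, sample = self.data.index[rows[0]], self.data.columns[cols[0]]
            raise ValidationError(f"non-finite expression at gene {gene!r}, sample {sample!r}")
        self.data = self.data.astype(np.float64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])


@dataclass
class ClinicalVariable:
    name: str
    kind: str  # CATEGORICAL or CONTINUOUS

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise ValidationError(f"unknown variable kind {self.kind!r} for {self.name!r}")


@dataclass
class ClinicalTable:
    """Samples x variables table; NaN marks a missing value in either kind."""

    data: pd.DataFrame  # index: sample ids
    kinds: Mapping[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing_kinds = [c for c in self.data.columns if c not in self.kinds]
        if missing_kinds:
            raise ValidationError(f"variable kind undeclared for: {missing_kinds}")
        self.kinds = {c: self.kinds[c] for c in self.data.columns}
        for name, kind in self.kinds.items():
            ClinicalVariable(name, kind)
            if kind == CONTINUOUS:
                col = pd.to_numeric(self.data[name], errors="coerce")
                bad = col.isna() & self.data[name].notna()
                if bad.any():
                    sample = self.data.index[bad.to_numpy()][0]
                    raise ValidationError(
                        f"continuous variable {name!r} has unparseable value "
                        f"{self.data.loc[sample, name]!r} at sample {sample!r}"
                    )
                self.data[name] = col.astype(np.float64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[ClinicalVariable]:
        return [ClinicalVariable(n, k) for n, k in self.kinds.items()]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy(), dict(self.kinds))


@dataclass
class OutcomeTable:
    """Per-sample right-censored time-to-event records for one endpoint.

    ``time`` is in months; ``event`` True means the event was observed,
    False means the record is censored at ``time``. Records with missing
    time or event flag are retained and exposed through ``complete_mask``
    rather than silently dropped.
    """

    data: pd.DataFrame  # index: sample ids; columns: time, event
    endpoint: str = "survival"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        if not {"time", "event"}.issubset(self.data.columns):
            raise ValidationError("outcome table needs 'time' and 'event' columns")
        if self.endpoint not in ("survival", "recurrence"):
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        t = pd.to_numeric(self.data["time"], errors="coerce")
        if (t.dropna() < 0).any():
            raise ValidationError("negative event/censoring time")
        self.data = self.data.assign(time=t)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def complete_mask(self) -> np.ndarray:
        return (self.data["time"].notna() & self.data["event"].notna()).to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=bool)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OutcomeTable":
        return OutcomeTable(self.data.loc[list(sample_ids)].copy(), self.endpoint)


@dataclass
class LabelTable:
    """Reference partition per sample, e.g. PAM50 subtype calls (input only)."""

    labels: pd.Series  # index: sample ids, values: str

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample")
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def subset_samples(self, sample_ids: Iterable[str]) -> "LabelTable":
        return LabelTable(self.labels.loc[list(sample_ids)].copy())


@dataclass
class Bundle:
    """Expression + clinical + outcomes (+ optional reference labels) over one
    identical, identically ordered sample set."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    outcomes: dict[str, OutcomeTable] = field(default_factory=dict)
    labels: LabelTable | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    def subset_samples(self, sample_ids: Iterable[str]) -> "Bundle":
        ids = list(sample_ids)
        return Bundle(
            expression=self.expression.subset_samples(ids),
            clinical=self.clinical.subset_samples(ids),
            outcomes={k: v.subset_samples(ids) for k, v in self.outcomes.items()},
            labels=self.labels.subset_samples(ids) if self.labels is not None else None,
        )


def align_tables(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    outcomes: Mapping[str, OutcomeTable] | OutcomeTable,
    labels: LabelTable | None = None,
) -> Bundle:
    """Intersect sample identifiers across all tables and reorder every table
    to the canonical order (expression-matrix order restricted to the
    intersection). Raises if the intersection is empty. Idempotent.
    """
    if isinstance(outcomes, OutcomeTable):
        outcomes = {outcomes.endpoint: outcomes}
    id_sets = [set(expr.sample_ids), set(clin.sample_ids)]
    id_sets += [set(o.sample_ids) for o in outcomes.values()]
    if labels is not None:
        id_sets.append(set(labels.sample_ids))
    common = set.intersection(*id_sets)
    if not common:
        raise ValidationError("no samples shared across all tables")
    order = [s for s in expr.sample_ids if s in common]
    return Bundle(
        expression=expr.subset_samples(order),
        clinical=clin.subset_samples(order),
        outcomes={k: v.subset_samples(order) for k, v in outcomes.items()},
        labels=labels.subset_samples(order) if labels is not None else None,
    )
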