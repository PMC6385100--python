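"""Cohort simulator with planted subtype structure.

Generates the four tables the pipeline consumes — expression, clinical,
outcomes (survival + recurrence), reference labels — plus the ground truth
behind them, so every downstream stage can be scored against a known answer.

The generative model is deliberately minimal:

* Background genes are independent Gaussians on the log2 scale.
* Each subtype owns a disjoint block of informative genes whose mean is
  shifted by ``effect_size`` noise-SDs in that subtype's samples.
* Categorical clinical variables are noisy readouts of the subtype (a planted
  subtype-to-level mapping with label-noise ``1 - clinical_link_strength``).
* Continuous clinical variables are the mean expression of a small set of
  linked informative genes plus Gaussian noise, so Pearson relevance has a
  planted truth.
* Event times are exponential with a per-subtype hazard, independently
  censored (exponential censoring plus an administrative follow-up horizon).

No attempt is made to mimic RSEM normalization, batch effects, or gene-gene
correlation beyond the planted blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import child_seeds
from .containers import (
    CATEGORICAL,
    CONTINUOUS,
    ClinicalTable,
    ExpressionMatrix,
    LabelTable,
    OutcomeTable,
)

#: Baseline log2 expression level and noise SD of the background genes.
BASELINE_MEAN = 8.0
NOISE_SD = 1.0


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    subtype_of_sample: dict[str, int]  # sample id -> subtype in 1..G
    informative_genes: dict[int, list[str]]  # subtype -> gene ids
    clinically_linked_genes: dict[str, list[str]]  # clinical variable -> gene ids
    hazard_of_subtype: dict[int, float]  # events per month
    recurrence_hazard_of_subtype: dict[int, float]
    effect_size: float

    @property
    def background_genes_excluded(self) -> set[str]:
        return {g for genes in self.informative_genes.values() for g in genes}


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    outcomes: dict[str, OutcomeTable]
    labels: LabelTable
    truth: SyntheticTruth
    params: dict = field(default_factory=dict)


def simulate_cohort(
    n_samples: int = 300,
    n_genes: int = 2000,
    n_subtypes: int = 3,
    n_informative_per_subtype: int = 50,
    effect_size: float = 2.0,
    n_clinical_categorical: int = 3,
    n_clinical_continuous: int = 2,
    clinical_link_strength: float = 0.9,
    hazards: Sequence[float] = (0.005, 0.010, 0.015),
    recurrence_hazards: Sequence[float] | None = None,
    censor_rate: float = 0.003,
    horizon: float = 120.0,
    label_noise: float = 0.0,
    n_linked_per_continuous: int = 5,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate one cohort; fully reproducible from ``seed``.

    ``hazards`` (events/month, one per subtype) drive survival times;
    ``recurrence_hazards`` default to the same rates. ``horizon`` is the
    administrative end of follow-up in months.
    """
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes")
    if n_informative_per_subtype * n_subtypes > n_genes:
        raise ValueError("informative genes exceed total genes")
    if len(hazards) != n_subtypes:
        raise ValueError(f"hazards has length {len(hazards)}, expected {n_subtypes}")
    if recurrence_hazards is None:
        recurrence_hazards = tuple(hazards)
    if len(recurrence_hazards) != n_subtypes:
        raise ValueError("recurrence_hazards length mismatch")
    if not 0 <= clinical_link_strength <= 1:
        raise ValueError("clinical_link_strength must lie in [0, 1]")

    seeds = child_seeds(seed, 6)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    # Balanced subtype membership in a seeded random order.
    rng = np.random.default_rng(seeds[0])
    subtype = rng.permutation(np.resize(np.arange(n_subtypes), n_samples))

    rng = np.random.default_rng(seeds[1])
    values = rng.normal(BASELINE_MEAN, NOISE_SD, size=(n_genes, n_samples))
    informative: dict[int, list[str]] = {}
    for g in range(n_subtypes):
        rows = slice(g * n_informative_per_subtype, (g + 1) * n_informative_per_subtype)
        values[rows][:, subtype == g] += effect_size * NOISE_SD
        informative[g + 1] = gene_ids[rows]
    expression = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    rng = np.random.default_rng(seeds[2])
    clinical_cols: dict[str, object] = {}
    kinds: dict[str, str] = {}
    linked: dict[str, list[str]] = {}
    levels = [f"level{g + 1}" for g in range(n_subtypes)]
    for j in range(n_clinical_categorical):
        name = f"cat_{j + 1}"
        mapping = rng.permutation(n_subtypes)  # subtype -> level index
        col = np.array([levels[mapping[s]] for s in subtype], dtype=object)
        noise_mask = rng.random(n_samples) > clinical_link_strength
        col[noise_mask] = rng.choice(levels, size=int(noise_mask.sum()))
        clinical_cols[name] = col
        kinds[name] = CATEGORICAL
        # The subtype is readable from every informative block, so all
        # planted genes are linked to a subtype-valued variable.
        linked[name] = [g for genes in informative.values() for g in genes]
    for j in range(n_clinical_continuous):
        name = f"cont_{j + 1}"
        owner = (j % n_subtypes) + 1
        block = informative[owner]
        lo = (j * n_linked_per_continuous) % max(1, len(block) - n_linked_per_continuous + 1)
        genes = block[lo : lo + n_linked_per_continuous]
        signal = expression.data.loc[genes].mean(axis=0).to_numpy()
        if clinical_link_strength <= 0:
            col = rng.normal(0.0, 1.0, n_samples)
            linked[name] = []
        else:
            noise_sd = float(np.std(signal)) * (1 - clinical_link_strength) / clinical_link_strength
            col = signal + rng.normal(0.0, noise_sd, n_samples)
            linked[name] = list(genes)
        clinical_cols[name] = col
        kinds[name] = CONTINUOUS
    clinical = ClinicalTable(pd.DataFrame(clinical_cols, index=sample_ids), kinds)

    outcomes = {
        "survival": _simulate_endpoint(
            "survival", subtype, hazards, censor_rate, horizon, seeds[3], sample_ids
        ),
        "recurrence": _simulate_endpoint(
            "recurrence", subtype, recurrence_hazards, censor_rate, horizon, seeds[4], sample_ids
        ),
    }

    rng = np.random.default_rng(seeds[5])
    label_values = np.array([f"subtype{s + 1}" for s in subtype], dtype=object)
    flip = rng.random(n_samples) < label_noise
    label_values[flip] = [f"subtype{rng.integers(n_subtypes) + 1}" for _ in range(int(flip.sum()))]
    labels = LabelTable(pd.Series(label_values, index=sample_ids))

    truth = SyntheticTruth(
        subtype_of_sample={s: int(g) + 1 for s, g in zip(sample_ids, subtype)},
        informative_genes=informative,
        clinically_linked_genes=linked,
        hazard_of_subtype={g + 1: float(hazards[g]) for g in range(n_subtypes)},
        recurrence_hazard_of_subtype={
            g + 1: float(recurrence_hazards[g]) for g in range(n_subtypes)
        },
        effect_size=float(effect_size),
    )
    params = dict(
        n_samples=n_samples, n_genes=n_genes, n_subtypes=n_subtypes,
        n_informative_per_subtype=n_informative_per_subtype, effect_size=effect_size,
        clinical_link_strength=clinical_link_strength, censor_rate=censor_rate,
        horizon=horizon, seed=seed,
    )
    return SyntheticCohort(expression, clinical, outcomes, labels, truth, params)


def _simulate_endpoint(endpoint, subtype, hazards, censor_rate, horizon, seed, sample_ids):
    rng = np.random.default_rng(seed)
    rate = np.asarray(hazards, dtype=float)[subtype]
    t_event = rng.exponential(1.0 / rate)
    t_censor = (
        rng.exponential(1.0 / censor_rate, size=len(subtype))
        if censor_rate > 0
        else np.full(len(subtype), np.inf)
    )
    observed = np.minimum(np.minimum(t_event, t_censor), horizon)
    event = (t_event <= t_censor) & (t_event <= horizon)
    return OutcomeTable(
        pd.DataFrame({"time": observed, "event": event}, index=list(sample_ids)), endpoint
    )


def inject_missing(clin: ClinicalTable, rate: float, seed: int = 0) -> ClinicalTable:
    """Independently blank each cell with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0:
        return ClinicalTable(clin.data.copy(), dict(clin.kinds))
    rng = np.random.default_rng(seed)
    mask = rng.random(clin.data.shape) < rate
    data = clin.data.copy()
    for j, col in enumerate(data.columns):
        if clin.kinds[col] == CATEGORICAL:
            data[col] = data[col].astype(object)
        data.loc[mask[:, j], col] = np.nan
    return ClinicalTable(data, dict(clin.kinds))


def add_flat_features(
    expr: ExpressionMatrix, n_flat: int, flat_fraction: float, seed: int = 0
) -> ExpressionMatrix:
    """Append ``n_flat`` genes that are constant on ``ceil(flat_fraction * N)``
    randomly chosen samples and random elsewhere — fixtures for the flat
    filter."""
    if not 0 < flat_fraction <= 1:
        raise ValueError("flat_fraction must lie in (0, 1]")
    if n_flat == 0:
        return ExpressionMatrix(expr.data.copy())
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    n_const = math.ceil(flat_fraction * n)
    rows = {}
    for i in range(n_flat):
        row = rng.normal(BASELINE_MEAN, NOISE_SD, n)
        const_at = rng.choice(n, size=n_const, replace=False)
        row[const_at] = rng.normal(BASELINE_MEAN, NOISE_SD)
        rows[f"FLAT{i + 1:04d}"] = row
    flat = pd.DataFrame.from_dict(rows, orient="index", columns=expr.data.columns)
    return ExpressionMatrix(pd.concat([expr.data, flat]))
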