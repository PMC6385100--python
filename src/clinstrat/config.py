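"""Run configuration and seeded randomness.

One global seed drives the whole pipeline; every component draws from a
child seed derived deterministically via :class:`numpy.random.SeedSequence`,
so each stage (and each table the simulator writes) is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("clinstrat")


@dataclass
class PipelineConfig:
    """Tunable parameters of the stratification pipeline.

    k_per_variable
        Genes kept by the greedy mRMR search for each clinical variable.
    pool
        Pre-filter size: the greedy search only considers the top-``pool``
        genes by marginal relevance for that variable.
    n_clusters
        k for k-means on the unioned gene set.
    n_replicates
        Random restarts of k-means; the restart with the lowest objective wins.
    n_null_draws
        Random gene sets drawn for the resampling null comparison.
    n_permutations
        Label permutations for differential-expression q-values.
    horizon_months
        Administrative censoring horizon for "5-year" outcome tests.
    flat_threshold
        A feature whose single most frequent value covers strictly more than
        this fraction of samples is discarded as uninformative.
    standardize_before_selection
        Whether mRMR sees the per-gene standardized matrix (clustering always
        does). Default off: selection runs on the log2 matrix.
    """

    k_per_variable: int = 100
    pool: int = 2000
    n_clusters: int = 5
    n_replicates: int = 100
    n_null_draws: int = 1000
    n_permutations: int = 1000
    horizon_months: float = 60.0
    flat_threshold: float = 0.80
    standardize_before_selection: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_per_variable", "pool", "n_clusters", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_null_draws < 0 or self.n_permutations < 0:
            raise ValueError("draw/permutation counts must be non-negative")
        if self.k_per_variable > self.pool:
            raise ValueError("k_per_variable must not exceed pool")
        if not 0 < self.flat_threshold < 1:
            raise ValueError("flat_threshold must lie in (0, 1)")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat key: value YAML file; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent 31-bit child seeds."""
    states = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1, np.uint32)[0] & 0x7FFFFFFF) for s in states]


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
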