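"""End-to-end orchestration: preprocess -> per-variable mRMR -> union ->
standardize -> correlation k-means -> concordance -> survival/recurrence
log-rank at the horizon -> random-gene-set null, all from one config and one
seed. Subgroup re-analyses rerun the flat filter, reselect features, and
re-standardize over the subgroup before clustering.

The pipeline is a composition of the public stage functions — every
intermediate it writes is a valid input to the corresponding standalone CLI
subcommand.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cluster import ClusterResult, adjusted_rand_index, kmeans_correlation
from .config import PipelineConfig, child_seeds
from .containers import Bundle
from .mrmr import SelectionResult, select_all_variables, selection_to_frame
from .preprocess import preprocess_bundle, standardize_genes
from .survival import logrank_test, random_geneset_null, truncate_horizon

log = logging.getLogger("clinstrat")


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    wall_time: dict[str, float] = field(default_factory=dict)
    union_gene_count: int = 0
    metrics: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class RunArtifacts:
    """In-memory stage outputs of a pipeline run."""

    bundle: Bundle | None = None
    selection: SelectionResult | None = None
    clusters: ClusterResult | None = None
    concordance: object | None = None
    logrank: dict[str, object] = field(default_factory=dict)
    null_comparison: dict[str, object] = field(default_factory=dict)
    manifest: RunManifest | None = None


def run_full_cohort(
    config: PipelineConfig, bundle: Bundle, out_dir: str | Path | None = None
) -> RunArtifacts:
    """Run the whole study flow on an aligned bundle; see module docstring."""
    return _run(config, bundle, config.n_clusters, out_dir)


def run_subgroup(
    config: PipelineConfig,
    bundle: Bundle,
    sample_subset: list[str],
    k: int,
    out_dir: str | Path | None = None,
) -> RunArtifacts:
    """Re-run the flow on a sample subset with its own cluster number:
    features are reselected and expression re-standardized over the subset."""
    missing = set(sample_subset) - set(bundle.sample_ids)
    if missing:
        raise ValueError(f"subset samples absent from bundle: {sorted(missing)[:5]}")
    if len(sample_subset) <= k:
        raise ValueError("subset too small for the requested cluster number")
    return _run(config, bundle.subset_samples(sample_subset), k, out_dir)


def _run(
    config: PipelineConfig, bundle: Bundle, n_clusters: int, out_dir: str | Path | None
) -> RunArtifacts:
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    seeds = child_seeds(config.seed, 2 + len(bundle.outcomes))
    manifest.seeds = {"kmeans": seeds[0], "selection": seeds[1]}
    art = RunArtifacts(manifest=manifest)
    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        clean, report = preprocess_bundle(bundle, config.flat_threshold)
        art.bundle = clean
        manifest.metrics["genes_removed_flat"] = report.genes_removed_flat
        manifest.wall_time[stage] = time.perf_counter() - t0

        stage = "select"
        t0 = time.perf_counter()
        selection_input = (
            standardize_genes(clean.expression)
            if config.standardize_before_selection
            else clean.expression
        )
        pool = min(config.pool, selection_input.n_genes)
        k_per_var = min(config.k_per_variable, pool)
        selection = select_all_variables(selection_input, clean.clinical, pool, k_per_var)
        art.selection = selection
        manifest.union_gene_count = len(selection.union_genes)
        manifest.wall_time[stage] = time.perf_counter() - t0
        if out is not None:
            path = out / "selection.tsv"
            selection_to_frame(selection).to_csv(path, sep="\t", index=False)
            manifest.outputs[stage] = str(path)

        stage = "cluster"
        t0 = time.perf_counter()
        standardized = standardize_genes(clean.expression.subset_genes(selection.union_genes))
        clusters = kmeans_correlation(
            standardized, n_clusters, n_replicates=config.n_replicates, seed=seeds[0]
        )
        art.clusters = clusters
        manifest.metrics["kmeans_objective"] = float(clusters.objective)
        manifest.wall_time[stage] = time.perf_counter() - t0
        if out is not None:
            path = out / "clusters.tsv"
            clusters.assignment.to_csv(path, sep="\t", index_label="sample")
            manifest.outputs[stage] = str(path)

        stage = "concordance"
        if clean.labels is not None:
            conc = adjusted_rand_index(clusters.assignment, clean.labels.labels)
            art.concordance = conc
            manifest.metrics["ari_vs_reference"] = float(conc.ari)
            if out is not None:
                path = out / "concordance.tsv"
                conc.contingency.to_csv(path, sep="\t")
                manifest.outputs[stage] = str(path)
        else:
            manifest.skipped.append(stage)

        for i, (endpoint, outcomes) in enumerate(bundle.outcomes.items()):
            stage = f"logrank_{endpoint}"
            t0 = time.perf_counter()
            truncated = truncate_horizon(outcomes, config.horizon_months)
            lr = logrank_test(truncated, clusters.assignment)
            art.logrank[endpoint] = lr
            manifest.metrics[f"logrank_p_{endpoint}"] = float(lr.p_value)
            manifest.metrics[f"logrank_chi2_{endpoint}"] = float(lr.chi_square)
            manifest.wall_time[stage] = time.perf_counter() - t0

            stage = f"null_{endpoint}"
            if config.n_null_draws > 0:
                t0 = time.perf_counter()
                null_seed = seeds[2 + i]
                manifest.seeds[stage] = null_seed
                null = random_geneset_null(
                    clean.expression,
                    outcomes,
                    geneset_size=len(selection.union_genes),
                    k=n_clusters,
                    observed_p=lr.p_value,
                    n_draws=config.n_null_draws,
                    n_replicates=config.n_replicates,
                    horizon=config.horizon_months,
                    seed=null_seed,
                )
                art.null_comparison[endpoint] = null
                manifest.metrics[f"null_fraction_smaller_{endpoint}"] = (
                    null.n_smaller / null.n_draws if null.n_draws else 0.0
                )
                manifest.wall_time[stage] = time.perf_counter() - t0
                if out is not None:
                    path = out / f"null_ps_{endpoint}.tsv"
                    pd.Series(null.null_ps, name="p").to_csv(path, sep="\t", index_label="draw")
                    manifest.outputs[stage] = str(path)
            else:
                manifest.skipped.append(stage)
    except Exception:
        manifest.failed_stage = stage
        if out is not None:
            manifest.to_file(out / "manifest.yaml")
        raise
    if out is not None:
        manifest.to_file(out / "manifest.yaml")
        manifest.outputs["manifest"] = str(out / "manifest.yaml")
    return art
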