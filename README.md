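# clinstrat

Clinically guided stratification of tumor cohorts from bulk gene-expression
data. Instead of clustering on the genome-wide expression matrix (or on the
most variable genes), `clinstrat` first selects, for every clinical variable,
the genes whose expression is most relevant to that variable and least
redundant among themselves, unions the per-variable selections, and clusters
tumors in that clinically informed gene space. The resulting subtypes are
scored by their association with survival and recurrence.

## Who this is for

Computational biologists analyzing cohorts like TCGA BRCA that come with
three linked tables: a genes × samples expression matrix (log2(x+1)
normalized counts), a samples × variables clinical table (mixed
categorical/continuous, with missing values), and per-sample time-to-event
outcomes. A reference subtype call set (e.g. PAM50) can be supplied for
concordance analysis; it is an input, never computed.

## Method

**Gene selection (mixed-type mRMR).** For a clinical variable *c* and gene
set *S*, relevance is

- D(S, c) = (1/|S|) Σ F(gᵢ; c) for categorical *c* (one-way ANOVA
  F statistic), or
- D(S, c) = (1/|S|) Σ |PCC(gᵢ; c)| for continuous *c* (absolute Pearson
  correlation),

and redundancy is R(S) = (1/|S|²) Σ |PCC(gᵢ; gⱼ)|. The search is greedy
under the quotient criterion (MIQ): the first gene maximizes relevance; each
later gene maximizes φ = D/R, with D its own relevance and R its mean |PCC|
to the already-selected set. Selection is restricted to the top-`pool` genes
by marginal relevance (defaults k = 100 per variable, pool = 2000) and the
per-variable selections are unioned.

**Clustering.** k-means over samples under correlation distance
(1 − Pearson r between sample profiles), genes standardized to mean 0 / SD 1
over the samples being clustered, best of `n_replicates` seeded restarts
(default 100). Concordance with reference labels is the adjusted Rand index.

**Outcome association.** Kaplan–Meier curves and the Mantel–Haenszel
log-rank test across clusters, with administrative censoring at a 60-month
horizon ("5-year" association). A resampling null re-runs the identical
clustering on random gene sets of the same size to ask whether the
clinically guided set beats chance.

**Differential expression.** One-vs-rest Wilcoxon rank-sum z per gene with
permutation-based q-values (SAM-style, median FDR estimate, label
permutations shared across genes), and a top-N / q < 0.05 selection rule.

A synthetic-cohort generator with planted subtypes, clinically linked genes,
and subtype-dependent hazards provides ground truth for every stage; see
`docs/methods.md` for the generative model and design choices.

## Worked example

```python
import clinstrat as cs

cohort = cs.simulate_cohort(n_samples=300, n_genes=2000, seed=42)
bundle = cs.align_tables(cohort.expression, cohort.clinical,
                         cohort.outcomes, cohort.labels)
config = cs.PipelineConfig(n_clusters=3, n_replicates=20, n_null_draws=100, seed=42)
art = cs.run_full_cohort(config, bundle)

m = art.manifest
print(f"union gene count:      {m.union_gene_count}")
print(f"ARI vs reference:      {m.metrics['ari_vs_reference']:.4f}")
print(f"log-rank p (survival): {m.metrics['logrank_p_survival']:.3g}")
print(f"log-rank p (recur.):   {m.metrics['logrank_p_recurrence']:.3g}")
```

prints

```
union gene count:      242
ARI vs reference:      1.0000
log-rank p (survival): 9.68e-07
log-rank p (recur.):   6.34e-08
```

The five clinical variables each contribute 100 genes whose union collapses
to 242 distinct genes (clinically linked genes are selected by several
variables). Clustering on those genes recovers the three planted subtypes
exactly (ARI 1.0 against the reference labels), and because the planted
subtypes carry a 3× hazard ratio, the recovered clusters separate both
5-year endpoints decisively.

The same flow is scriptable from a shell:

```bash
clinstrat --seed 42 --out-dir work simulate
clinstrat --seed 42 --out-dir work preprocess
clinstrat --seed 42 --out-dir work select
clinstrat --seed 42 --out-dir work cluster --k 3
clinstrat --seed 42 --out-dir work survival --endpoint recurrence
clinstrat --seed 42 --out-dir work run-all
```

Subgroup re-analysis (reselect features, re-standardize, recluster a sample
subset — e.g. one subtype at a finer resolution) is
`cs.run_subgroup(config, bundle, sample_ids, k)` or
`clinstrat run-all --subset-file samples.tsv --k 2`.

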