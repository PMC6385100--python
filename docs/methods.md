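# Methods

## Pipeline overview

`clinstrat` stratifies a tumor cohort in five stages, each exposed as a
library function and a CLI subcommand, composed by `run_full_cohort` /
`run_subgroup`:

1. **Alignment and preprocessing.** All tables are joined on sample
   identifiers (never column position); the canonical order is the
   expression matrix's order restricted to the intersection. Features whose
   single most frequent value covers strictly more than `flat_threshold`
   (default 0.80) of samples are discarded as uninformative — exact value
   match, missing cells excluded from the mode, and a feature flat on
   exactly the threshold fraction is kept. Missing clinical cells are then
   imputed: column median for continuous variables, most frequent level for
   categorical ones, ties broken by lexicographic level name. "Unknown"
   tokens in clinical files are missing markers, not category levels.
   Cohort-specific sample exclusions (male, metastatic, unknown-tissue
   records and similar) are a generic exclusion-list input
   (`apply_exclusions`), not hard-coded clinical logic.
2. **Per-variable gene selection** (below).
3. **Standardization and clustering.** Genes are centered and scaled to
   SD 1 (ddof = 1) over exactly the samples about to be clustered; subgroup
   re-analyses therefore re-standardize, and also re-run the flat filter and
   reselect features on the subgroup. Zero-variance genes are dropped with a
   warning rather than erroring, since the flat filter normally removes them
   first.
4. **Outcome association** (below).
5. **Differential expression** (below).

Imputation is performed once at cohort level; subgroup runs reuse the
cohort-level imputations (the subset inherits the already-imputed clinical
table). Re-imputing within a subgroup would let the subgroup's own
composition shift imputed values, which makes subgroup comparisons harder to
interpret.

## Mixed-type mRMR with the quotient criterion

Relevance of gene g to clinical variable c is the one-way ANOVA F statistic
(categorical c) or the absolute Pearson correlation (continuous c);
redundancy of a candidate gene is its mean absolute Pearson correlation to
the genes already selected. The greedy search first takes the gene of
maximal relevance, then at each step the gene maximizing φ = D/R over the
remaining candidates, stopping at `k_per_variable` genes. Candidates are
pre-restricted to the top-`pool` genes by marginal relevance, which bounds
the search cost and mirrors how the method is used at genome scale
(defaults: k = 100, pool = 2000).

Numerical and convention choices:

- **Absolute values.** Both the continuous-relevance and the redundancy
  terms use |PCC|. Signed averaging would let anticorrelated genes cancel
  in the redundancy penalty — the opposite of "least correlated among
  themselves" — and the sign of a gene–covariate correlation carries no
  information about whether the gene is worth selecting.
- **Step 1 has no redundancy**; φ is defined as the relevance itself and
  the stored R is 0.
- **Division guard.** When the mean redundancy falls below 1e−12, φ is
  computed against that floor, so a near-orthogonal gene is maximally
  attractive but φ stays finite.
- **Ties** in φ are broken by higher relevance, then lexicographic gene id;
  the pool pre-filter breaks relevance ties the same way. Selection order is
  therefore deterministic across platforms.
- **Incremental redundancy.** During the greedy search the redundancy of a
  candidate is the mean |PCC| to the genes selected so far. Any fixed
  normalization of the full double-sum redundancy yields the same argmax at
  every step, so the incremental mean is used.
- **Degenerate inputs.** Fewer than two label groups, or zero within-group
  degrees of freedom, is an error; zero between-group sum of squares gives
  F = 0; single-sample groups are allowed and contribute zero within-group
  sum of squares.
- Relevance scales differ between the two kinds (F is unbounded, |PCC| ≤ 1)
  and are never compared across variables: selection is per-variable and
  the selections are unioned (ordered by variable, then selection rank,
  deduplicated). A joint multi-variable selection is out of scope.

Selection runs on the unstandardized log2 matrix by default
(`standardize_before_selection` flips this). Both relevance measures are
invariant to per-gene affine rescaling, so the switch only matters if a
caller standardizes over a different sample set than the selection set.

## Correlation-distance k-means

Correlation distance between sample profiles is 1 − r. Sample rows are
centered to zero mean and scaled to unit norm, after which 1 − r is half
the squared Euclidean distance, so Lloyd iteration minimizes total
correlation distance directly: assignment picks the most-correlated
centroid; the update step takes the member mean, re-centers, and
re-normalizes it (the renormalized mean maximizes within-cluster
correlation by Cauchy–Schwarz, so the objective is non-increasing — this is
asserted on every iteration). Initialization is k-means++-style seeding in
correlation distance; each of `n_replicates` (default 100) restarts draws
its own child seed, and the restart with the lowest objective wins. Empty
clusters are re-seeded with the sample farthest from its centroid.
Convergence: assignments unchanged, or 300 iterations. The cluster number
K is always supplied by the caller; no model-selection criterion is
implemented.

Concordance between partitions is the Hubert–Arabie adjusted Rand index
(computed via scikit-learn, validated in the test suite against an O(N²)
pair-counting oracle), reported with the clusters × labels contingency
table.

## Survival and recurrence association

"5-year" association is operationalized by administrative censoring:
records with time > `horizon_months` (default 60) become censored at the
horizon; an event at exactly the horizon stays an event. Passing an
infinite horizon disables truncation for full-follow-up analyses.

The Kaplan–Meier estimator is the standard product-limit form; samples
censored exactly at an event time count as at risk at that time. The
log-rank test is the G-group Mantel–Haenszel statistic: per distinct event
time, observed minus hypergeometric-expected events per group, combined
through the summed covariance matrix (pseudo-inverse, first G−1 groups)
into a chi-square with G−1 degrees of freedom, upper-tail p, no continuity
correction. The test suite verifies agreement with lifelines to 1e−6 in the
statistic.

p-values on data-driven cluster labels are *not* nominal — the labels were
chosen by an algorithm that looked at the expression data. This usage is
deliberate (it is how such stratifications are scored in practice) and is
why the resampling null exists: `random_geneset_null` redraws gene sets of
the same size uniformly at random, re-standardizes, re-clusters with the
identical K/replicate settings, recomputes the log-rank p per draw, and
counts draws with p *strictly* smaller than the observed one (ties count as
not smaller). Only the gene set and the seed differ between the observed
and null runs.

## Differential expression

One-vs-rest contrasts score each gene by the Wilcoxon rank-sum statistic of
the focal group, standardized by its null mean n₁(n+1)/2 and tie-corrected
variance; zero variance (a gene constant across all samples) gives z = 0.
Group labels are permuted `n_permutations` times (≥ 100 required; default
1000), the same permutation applied to every gene so that gene–gene
correlation is preserved in the null. For each threshold t equal to an
observed |z|, estimated FDR = median over permutations of the null
exceedance count, divided by the observed exceedance count, clipped to
[0, 1]; a gene's q-value is the minimum estimated FDR over thresholds at or
below its |z|, which makes q monotone non-decreasing as |z| decreases. The
median (not mean) permutation count is used, and no variance-stabilizing
fudge factor is applied — that device addresses near-zero denominators of
moderated t-statistics and has no analog for a rank statistic. Top-gene
selection takes genes with q < `q_cut` (default 0.05) in decreasing-|z|
order, truncated to `n_top` (default 1000), warning when fewer survive.

## Synthetic cohorts

`simulate_cohort` generates all four tables plus ground truth. Background
genes are independent Gaussians (mean 8, SD 1 on the log2 scale — a typical
magnitude for log-transformed normalized counts). Each subtype owns a
disjoint block of `n_informative_per_subtype` genes shifted by
`effect_size` noise-SDs in its samples. Categorical clinical variables read
out the subtype through a planted subtype→level permutation with label
noise 1 − `clinical_link_strength`; continuous ones are the mean of a small
linked gene set plus Gaussian noise with SD scaled by
(1 − strength)/strength, so strength 1 is noiseless and strength 0 severs
the link. Event times are exponential with per-subtype hazards
(events/month), censored by an independent exponential time and an
administrative horizon; recurrence uses the same machinery with its own
hazards. One global seed spawns per-table child seeds, so every table is
independently reproducible.

Defaults are the conditions under which the pipeline is validated: 300
samples, 2000 genes, 3 balanced subtypes, 50 informative genes per subtype,
effect size 2, link strength 0.9, hazards (0.005, 0.010, 0.015)/month — a
3× hazard ratio giving roughly 26–59% 10-year event probability per
subtype — censoring rate 0.003/month, 120-month follow-up. The generator
does **not** mimic RSEM normalization, batch effects, library-size
artifacts, or gene–gene correlation beyond the planted blocks; passing
tests demonstrate that the machinery recovers planted structure under an
idealized noise model, not that it will resolve subtypes in any particular
real cohort, where effect sizes are smaller and confounding is real.

Two helper generators build preprocessing fixtures: `inject_missing` blanks
clinical cells independently at a given rate, and `add_flat_features`
appends genes constant on a chosen fraction of samples to exercise the flat
filter on both sides of its threshold.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate at sizes chosen to make
the statistical checks sharp while keeping runs desk-scale: greedy-selection
oracle equivalence on 1000 random instances (P ≤ 12, k ≤ 5) against a
brute-force re-implementation; parameter recovery over 100 simulated cohorts
at the default conditions (30 in the acceptance script); the resampling null
with 200 draws on a cohort whose outcome signal is concentrated in 30 of
2000 genes (so random draws carry almost none of it); differential
expression at 200 permutations; and log-rank calibration over 1000 cohorts
of 100 samples. k-means uses 20 restarts in these runs; the pipeline default
of 100 restarts matters on real data with shallow optima, while the planted
cohorts converge identically from far fewer.

## Known limitations

- The flat filter's exact-equality mode test is appropriate for discretized
  or normalized counts; continuous measurements with jitter will rarely be
  flagged flat.
- Relevance for categorical variables assumes the ANOVA F is meaningful per
  gene (roughly: within-group variances comparable); no rank-based
  alternative is provided.
- The log-rank test assumes non-informative censoring; the generator
  satisfies this by construction.
- No Cox regression, hazard ratios, confidence bands, consensus clustering,
  or cluster-number selection; reference subtype calls are never computed,
  only consumed.
- Expression input is assumed already normalized (log2(x+1) scale); no
  re-normalization or batch correction is performed.
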