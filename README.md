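# patternsurv

Survival stratification of tumor cohorts from the expression **patterns** (not
levels) of small pathway gene panels.

Each sample's panel-restricted expression profile is centered by the cohort
mean and projected onto the unit hypersphere, embedded in 3-D with exact
t-SNE over a perplexity × learning-rate sweep, assigned to clusters with an
eight-configuration Gaussian-mixture procedure, and compared by Kaplan-Meier /
log-rank survival analysis. Random-forest out-of-bag permutation importance
identifies the transcripts driving each clustering, and refinement utilities
support sequential two-panel analysis, integration with whole-matrix
hierarchical partitions, subtype enrichment tests, and stage-restricted
re-analysis. A synthetic-cohort generator with planted ground truth makes
every stage testable end to end.

## Package layout

| module | role |
| --- | --- |
| `patternsurv.io` | GMT panels, TSV expression/phenotype readers & writers, panel subsetting; bundles the 12-panel reference registry (212 unique gene IDs) |
| `patternsurv.synthetic` | seeded cohort simulator: directional pattern clusters, exponential survival with uniform censoring, subtype enrichment, background blocks, nested two-panel refinement |
| `patternsurv.pattern_space` | inverse log2(x+1) transform, cohort-mean centering, unit-norm projection |
| `patternsurv.embedding` | exact 3-D t-SNE (≥2500 iterations + stabilization), density-based cluster discernibility, parameter sweep with repeat-run validation, hold-out confirmation |
| `patternsurv.clustering` | minimal enclosing sphere, 5%-radius perturbation, Gaussian-mixture EM over 8 covariance/perturbation configurations, unity-based selection |
| `patternsurv.survival` | Kaplan-Meier product-limit curves, Mantel-Haenszel log-rank (pairwise and k-group), most-disparate-pair reporting with Bonferroni column |
| `patternsurv.drivers` | 100-tree forest, out-of-bag permutation importance, prominence threshold > 1 |
| `patternsurv.stratify` | sequential two-panel refinement, hierarchical partitions (average linkage, correlation distance), cross-stratification, Fisher/chi-square enrichment, covariate filtering |
| `patternsurv.pipeline` | config-driven orchestration with derived per-stage seeds and deterministic JSON reports |

## CLI

All commands are under one entry point:

```sh
pattern-surv simulate   --config cohort.yaml --seed 1 --out cohort/
pattern-surv run-all    --config run.yaml
pattern-surv embed      --config run.yaml --panel Wnt --seed 1 --out out/
pattern-surv cluster    --coords out/coords.tsv --seed 1 --out out/
pattern-surv survive    --labels out/labels.tsv --pheno cohort/phenotype.tsv --out out/
pattern-surv drivers    --vectors vectors.tsv --labels out/labels.tsv --seed 1 --out out/
pattern-surv refine     --config run.yaml --labels out/labels.tsv --panel2 Notch --cluster 1 --seed 1 --out out/
pattern-surv crosstab   --labels out/labels.tsv --partition dendro.tsv --pheno cohort/phenotype.tsv --out out/
```

A run config is YAML:

```yaml
expression: cohort/expression.tsv   # samples x genes TSV (transpose: true for genes x samples)
phenotype: cohort/phenotype.tsv     # sample_id, os_time, os_event (+ covariates)
panels_file: cohort/panels.gmt      # omit to use the bundled 12-panel registry
panel: Wnt
scale: log2p1                       # or fpkm_uq
work_on_log_scale: false            # true keeps log2 values as vector coordinates
grid: [[15, 100], [30, 100]]        # omit for the full 6x4 sweep grid
refine_panel: Notch                 # optional sequential refinement
seed: 1
out_dir: out/
```

Identical config + seed always reproduces byte-identical reports.

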