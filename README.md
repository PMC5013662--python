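# cescore

Toolkit for an additive centromere/kinetochore expression-score (CES)
signature: derive a consistently-overexpressed gene panel from multi-dataset
tumour/normal comparisons, score samples by the unweighted sum of log2
expression over the panel, stratify patients, and quantify associations with
genomic instability, clinical factors, drug sensitivity (IC50), and survival
— including treatment-stratified outcome analysis. A synthetic-cohort module
with known ground truth stands in for external expression/clinical databases.

## Modules

| module                | what it does |
|-----------------------|--------------|
| `cescore.io`          | tab-delimited expression tables (either orientation), probe→gene collapsing, built-in gene panels (`cenkt31`, `ces14`, `ces9`) |
| `cescore.simulate`    | multi-dataset expression, proportional-hazards survival cohorts with a treatment×stratum interaction, instability metrics with a tunable Spearman target, cell-line IC50 tables with injected outliers; all seeded and substreamed |
| `cescore.selection`   | Welch / moderated differential expression with BH-FDR, cross-dataset prevalence filter, label-permutation overexpression test, panel derivation from evidence sets |
| `cescore.scoring`     | score computation, tertile/quartile/range/fixed stratification, minimal-p survival cut-point scan (reported as uncorrected) |
| `cescore.association` | Spearman tables with joint FDR, rank tests, categorical enrichment (chi-square / Fisher), co-expression edge lists, pairwise-difference Qn robust scale, IC50 quartile analysis with one-sided robust outlier exclusion |
| `cescore.survival`    | Kaplan–Meier, k-group log-rank, multivariate Cox (Efron ties, Wald CIs), fixed-horizon survival chi-square, treatment-stratified forest tables (n ≥ 30 floor) |
| `cescore.pipeline`    | end-to-end orchestration with stage isolation, deterministic report bundles, manifest + config echo |

## CLI

```sh
# full simulate-mode pipeline (deterministic under a fixed seed)
cescore run --seed 7 --out run_bundle/

# generate synthetic datasets + ground truth
cescore simulate --seed 7 --out simdata/

# score an expression table with a built-in panel
cescore score simdata/expression_dataset_0.tsv --panel ces14 --out scores.tsv

# DE screen across datasets and panel derivation
cescore select-panel simdata/expression_dataset_*.tsv --evidence evidence.txt --out panel.tsv

# co-expression edge list / survival comparison
cescore associate expr.tsv --threshold 0.4 --out edges.tsv
cescore survive scores.tsv survival.tsv --out logrank.tsv
```

Expression tables are tab-delimited (first column = feature id, header =
sample ids) with optional `#scale=` / `#roles=` metadata lines. `cescore run
--config cfg.json` accepts a JSON RunConfig for ingest-mode runs on real
tables.

## Conventions worth knowing

- Linear-scale input is converted to `log2(x + 1)`; scores on log2 input are
  plain column sums over the panel.
- Quantile-tertile boundaries put exact-boundary samples in the lower
  stratum; range tertiles split `[min, max]` into equal widths. Both exist
  because either convention is defensible; outputs record the mode used.
- The Qn robust scale reports both the raw pairwise-difference kernel and the
  scaled estimate (2.2219 × finite-sample factor); IC50 outlier exclusion is
  one-sided above the median at 3× the scaled estimate, applied on the log
  scale.
- The minimal-p cut-point scan flags its p-value as a scan minimum; expect
  heavy selection inflation under the null (demonstrated in tests).
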