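# natscreen

A multi-omic screening toolkit for characterising a gene family — built
around the N-terminal acetyltransferase (NAT) complexes — across tumour
cohorts, plus a fully synthetic cohort generator with planted signals so
every screen can be validated without any external download.

## What it does

| Module | Purpose |
|---|---|
| `natscreen.cohort_sim` | Seeded synthetic cohort: expression, methylation β-values, mutations, CNV calls, CRISPR gene effects, survival — with a machine-readable `truth.json` of every planted signal |
| `natscreen.nt_substrate` | Rule engine: iMet cleavage, NAT-complex routing (NatA / NatB / NatC–E–F / NatD histone motif / blocked / unacetylated), and classification of N-terminal missense substitutions |
| `natscreen.genomic_screen` | Alteration frequencies, ORF-length-normalised burden, recurrent-mutation detection, P1–P5 positional profile, amplification-vs-expression association |
| `natscreen.expr_screen` | Tumour-vs-normal differential expression with eligibility (≥10/10 samples), fold-change band and raw p-value thresholds |
| `natscreen.methyl_screen` | Methylation–expression anti-correlation discovery: region filter, β floor, Δβ test, Pearson anti-correlation, expression-change gate (conjunctive) |
| `natscreen.depend_screen` | Essentiality percentiles, cumulative rank curve, co-dependency correlations, paralog-compensation ranking |
| `natscreen.surv_screen` | Median-split Kaplan–Meier + log-rank, univariate Cox (Newton on the Breslow partial likelihood), BH-FDR screen over gene × tumour pairs |
| `natscreen.pipeline` / `natscreen.cli` | Readers/writers, run-all orchestration, truth-vs-output recovery report |

## CLI

```bash
# Generate a seeded cohort with strong planted signals
natscreen simulate --seed 1 --preset strong --out cohort/

# Run every screen and write per-screen TSVs + report.json
natscreen run-all --cohort cohort/ --out results/

# Individual screens
natscreen genomic    --cohort cohort/ --out results/ --min-recurrence 3
natscreen expression --cohort cohort/ --out results/ --fc 1.5 --p 0.01
natscreen methylation --cohort cohort/ --out results/ --delta-beta 0.1 --r-max -0.2
natscreen dependency --cohort cohort/ --out results/ --dependent-gene G0006
natscreen survival   --cohort cohort/ --out results/ --fdr 0.05

# Annotate a mutation table with N-terminal substitution effects
natscreen annotate-nterm --mutations cohort/mutations.tsv \
    --genes cohort/genes.tsv --out annotated.tsv
```

`run-all` accepts `--config config.yaml` (JSON or YAML); unknown keys are
rejected by name, and every threshold in force is recorded in the
`report.json` provenance block. When the cohort directory contains a
`truth.json`, the report also summarises which planted signals were found,
missed, or falsely called.

## Cohort directory format

Tab-separated files with one header line; matrices are genes/probes × samples:
`expression.tsv`, `cell_line_expression.tsv`, `methylation.tsv`,
`gene_effect.tsv`, plus tables `genes.tsv`, `samples.tsv`, `probes.tsv`,
`mutations.tsv`, `cnv.tsv`, `survival.tsv` (optional) and `truth.json`
(optional).

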