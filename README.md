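# pairsplice

Paired differential expression (DE) and differential splicing (DS) analysis of
transcript-level RNA-seq counts, with gene-level aggregation and a paired
gene-set over-representation analysis.

## The problem

Most RNA-seq studies stop at gene-level differential expression and never ask
whether a condition also changes *which* transcripts a gene produces.
`pairsplice` runs both questions against the same data, the same design matrix
and the same statistical engine, so the two answers are directly comparable:

1. **Expression** — does a transcript's abundance change between baseline and
   case?
2. **Splicing** — does a transcript's abundance change *relative to the other
   transcripts of its gene* (differential transcript usage, including
   alternative TSS/TES)?

It is aimed at bioinformaticians with a transcript × sample count matrix
(salmon/kallisto/ARCHS4-style), a two-condition design, a transcript→gene map
and, optionally, GMT gene-set collections.

## Method

For transcript *t* with log2-CPM `y_t`, a weighted linear model is fitted on
the design `X = [1, condition, covariates, surrogate variables]`:

- Unknown confounders are estimated by surrogate-variable analysis
  (permutation parallel analysis for the count, iteratively reweighted SVD
  for the factors) and appended to `X`.
- Observation-level precision weights come from a lowess mean–variance trend
  (weight = trend(fitted log-count)^-4).
- **Expression test**: empirical-Bayes moderated t on the condition
  coefficient β_t; residual variances are shrunk toward a scaled-F prior
  (d₀, s₀²) estimated by moment matching.
- **Splicing test**: moderated t on the relative coefficient
  β_t − weighted-mean(β of the gene's *other* transcripts); only genes with
  ≥ 2 transcripts are testable.
- **Gene level**: transcript p-values are combined by Lancaster's weighted
  Fisher generalization with base means (mean CPM) as the chi-square degrees
  of freedom; expression LFCs by base-mean-weighted mean; the splicing LFC is
  that of the lowest-p transcript. BH adjustment is applied separately per
  analysis, before the two tables are joined.
- **Paired ORA**: hypergeometric over-representation of each analysis'
  significant genes, with separate universes (all tested genes vs
  multi-isoform genes only), and per set a relative risk
  `RR = (overlap/set_size) / (n_sig/n_background)` with enrichment score
  `log2(RR + 0.06)`.

Two simulators make every stage testable without downloads: a
negative-binomial count generator with designed DE effects, isoform switches
and a planted batch confounder (plus truth tables), and a four-scenario
gene-label simulation of the enrichment score.

## Worked example

```python
import pairsplice as ps

# simulate 500 genes, 6 vs 6 samples, with known DE/DS truth
tcm, design, truth = ps.simulate_counts(n_genes=500, seed=7)
result = ps.analyze(tcm, design, seed=7)
s = result.summary
print(s.n_sig_expr, s.n_sig_splice, s.n_overlap)
```

Output for this seed:

```
transcripts after filtering: 1240
multi-isoform genes:         327
surrogate variables:         1
DE genes (padj<0.05):        155
DS genes (padj<0.05):        70
overlap:                     68
DE also DS:                  0.439
DS share of total signal:    0.446
median isoform contribution: 0.853
DE sensitivity vs truth:     0.950
DS sensitivity vs truth:     1.000
```

Reading: 155 genes change total output, 70 change isoform usage, and 68 do
both; splicing carries 44.6% of the total transcriptional signal (the union of
significant genes); within dual-significant genes the significantly switched
transcripts carry a median 85% of the gene's abundance. Both truth-based
sensitivities confirm the designed effects are recovered.

The same pipeline runs from the shell:

```bash
pairsplice simulate-counts sim/ --n-genes 500 --seed 7
pairsplice run --counts sim/counts.tsv --tx2gene sim/tx2gene.tsv \
    --metadata sim/metadata.tsv --outdir out/ --baseline baseline
pairsplice compare out/ora_paired.tsv        # with a --gmt collection
```

Outputs are TSVs (`transcript_results.tsv`, `gene_results.tsv`,
`ora_paired.tsv`, `summary.tsv`) plus a `manifest.json` recording seeds,
parameters and per-stage counts.

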