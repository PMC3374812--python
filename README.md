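# amplimark

Supervised outlier-expression analysis for inferring chromosomal amplicons
associated with early relapse in ER+ breast cancer.

A subset of estrogen-receptor-positive breast cancers relapses early despite
hormonal therapy. Focal chromosomal amplifications (e.g. at 17q12/HER2,
17q21.33-q25.1, 8p11.2, 8q24.3) drive over-expression of their resident
genes in the tumours that carry them, which shows up as heavy right tails in
cohort expression data. `amplimark` turns that observation into a tested
pipeline for people analysing bulk expression cohorts with survival
follow-up:

- **COPA-style outlier calling**: per-batch median/MAD scaling, per-gene
  10%/90% quantile cutoffs, binary high/low outlier matrices, a <10-outlier
  informativeness filter;
- **survival screen**: per-gene log-rank test of outlier vs normal samples
  (p < 0.05) with univariate Cox hazard ratios (Efron ties);
- **phi-coefficient clustering** of binary outlier profiles with iterative
  graph pruning and PCA reporting;
- **amplicon regions**: sliding-window (25 genes, pace 5) one-sided Fisher
  enrichment with genome-wide Benjamini-Hochberg FDR < 5%, merged into named
  regions with marker genes, plus per-sample presence calls;
- **outcome stratification**: Kaplan-Meier curves, log-rank tests and Cox
  models of amplicon carriers vs amplicon-free samples, including
  multivariate adjustment and grade-stratum analyses;
- **clinical scores**: an array-based relative 21-gene recurrence score and
  FISH spot-count classification (tri-class and presence modes, with
  survival-optimised thresholds);
- **a synthetic-cohort generator** with planted amplicons and full ground
  truth, so every stage is verifiable without external data.

## Worked example

```python
from amplimark import AmpliconRelapseModel
from amplimark.simulate import default_config, simulate_cohort

expression, annotation, clinical, truth = simulate_cohort(default_config(seed=1))
results = AmpliconRelapseModel(expression, annotation, clinical).fit()
print(results.summary())
```

```
Amplicon outlier-expression analysis
================================================
samples: 300   genes: 2000   batches: 3
outlier cutoffs: q_low=0.1, q_high=0.9, min_outliers=10
screen: log-rank p < 0.05; hits: 198 high, 107 low
amplicon regions (window 25/pace 5, FDR 0.05): 2
  1q5-q6  (chr1)  markers=24  carrier frequency=0.203
  2q13  (chr2)  markers=24  carrier frequency=0.197
carrier vs no-amplicon survival:
  1q5-q6         HR=3.72 (95% CI 2.61-5.29)  log-rank p=8.21e-15  n=61 vs 191
  2q13           HR=3.14 (95% CI 2.23-4.41)  log-rank p=4.39e-12  n=59 vs 191
  any_amplicon   HR=3.18 (95% CI 2.38-4.24)  log-rank p=2.54e-16  n=109 vs 191
```

The cohort planted two 25-gene amplicons (hazard ratio 4, prevalence 0.25)
into heavy-tailed three-batch expression data. The fitted model finds
exactly those two regions and no others, its per-sample calls track the true
carriers (87% sensitivity, 100% specificity against the generator's truth),
and the carrier-vs-none hazard ratios bracket the planted effect. The
`results` object also carries the per-gene screen table, phi-cluster
membership with PCA coordinates, the full window-enrichment table, the
sample x amplicon call matrix and per-amplicon Kaplan-Meier curves.

The same analysis runs from files:

```bash
amplimark simulate --seed 1 --out cohort/
amplimark run --config cohort/pipeline.yaml
```

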