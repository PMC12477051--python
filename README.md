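# aldhnet

Connectivity-weighted gene-network scoring, molecular-subtype consensus,
survival comparison and enhancer–peak integration for pancreatic ductal
adenocarcinoma (PDAC) expression cohorts.

## What it is for

The aggressive basal-like transcriptional subtype of PDAC is marked by high
expression of ALDH1A3 and a small module of interacting genes.  `aldhnet`
implements the analysis pipeline around that module for computational
biologists working with bulk expression cohorts and matched epigenomic peak
sets:

1. **Network score.** An 8-gene interaction network (ALDH1A3, EMP1, FAM3C,
   IRS2, MAML2, MCC, PMEPA1, SP100) with 13 edges assigns each gene a weight
   *w<sub>g</sub>* — a bidirectional edge contributes one unit split between
   its endpoints, a directed edge half a unit to its target — giving
   coefficients *c<sub>g</sub> = w<sub>g</sub> / Σw*.  Per sample, each gene
   contributes an indicator *I<sub>g</sub> = +1* (top half of cohort
   expression) or *−1* (bottom half), and the score is
   *S = Σ<sub>g</sub> c<sub>g</sub> I<sub>g</sub> ∈ [−1, +1]*.  Cohorts are
   split into High/Low at the median score.
2. **Marker discovery.** 1-D k-means (k = 2) on an anchor gene, rank-sum
   differential expression with Benjamini–Hochberg correction, cross-dataset
   Venn intersection, and the module's Spearman correlation matrix.
3. **Subtype consensus.** NMF clustering of signature-gene submatrices under
   k = 2/3/4 classification schemes, centroid-based cluster naming, and a
   consensus-aggressive flag for samples called unfavourable by ≥ 3 schemes,
   with chi-squared / Fisher association tests against the score groups.
4. **Survival.** Kaplan–Meier curves per score group and the two-group
   log-rank test (via `lifelines`).
5. **Peak integration.** Nearest-TSS peak annotation with strand-aware
   distances and promoter/exonic/intronic/distal classes, TSS-distance
   profiles, feature-distribution chi-squared tests, DE-gene × peak overlap
   fractions, and k-way candidate intersections.
6. **Synthetic cohorts.** Generators for expression matrices with a planted
   correlated module and signature blocks, exponential survival with a
   group hazard ratio, and toy genomes with an exactly planted fraction of
   TSS-proximal peaks — so every stage is testable without access-controlled
   cohort downloads.

## Worked example

```sh
python examples/02_score_cohort.py
```

```
scored 200 samples; score range [-1.000, +1.000]
mean score, true basal-like samples: +0.796
mean score, true classical samples:  -0.531
High group size 100, Low group size 100
```

A synthetic 200-sample cohort is drawn with a planted basal-like axis; the
weighted ±1 indicators give basal-like samples a mean score of +0.80 against
−0.53 for classical samples, and the median split assigns 100 samples to
each group.  The other examples cover coefficients
(`01_network_coefficients.py`), subtype consensus (`03`), survival (`04`),
peak integration (`05` — recovering a planted 411/709 = 58.0 % DE-gene ×
peak overlap exactly) and the full pipeline (`06`).

The same capabilities are exposed on the command line:

```sh
aldhnet run-all --seed 7 --out demo/       # full synthetic demo
aldhnet score --expression expr.tsv --out scores.tsv
aldhnet survival --clinical clin.tsv --scores scores.tsv --out logrank.json
```

Rerunning `run-all` with the same seed reproduces every artifact
bit-identically (checksums are recorded in `manifest.json`).

## Layout

- `src/aldhnet/` — the library (`network`, `scoring`, `markers`, `subtypes`,
  `survival`, `genomic`, `simulate`, `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and acceptance tests
- `docs/methods.md` — the model, assumptions, defaults and limitations
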