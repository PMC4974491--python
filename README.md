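# ascnet

Temporal weighted gene-coexpression network analysis of antibody-secreting
cell (ASC) differentiation under interferon stimulation.

When human plasmablasts differentiate into plasma cells they execute a core
transcriptional program — cell-cycle exit, secretory reprogramming — onto
which environmental cytokines such as IFN-α and IFN-γ superimpose their own
gene modules. `ascnet` implements, as a reusable Python library, the
network-analysis workflow used to dissect such a design: probe×sample log2
expression matrices sampled across **3 cytokine conditions × 8 timepoints ×
3 donors**, analyzed per condition with weighted coexpression networks and
compared across conditions. It is aimed at computational biologists who want
each stage as a tested, importable function rather than a monolithic
script — and it ships a synthetic-data generator that emulates the study
design, so the entire workflow runs and is validated without any download.

## What it computes

- **Preprocessing** (`ascnet.preprocess`): removal of probes undetected
  (detection p ≥ 0.05) on three or more arrays; quantile normalization;
  selection of the top-*n* most variant probes as the network universe.
- **Moderated differential expression**: per-timepoint two-group contrasts
  with empirical-Bayes variance shrinkage,
  s̃² = (d₀s₀² + d·s²)/(d₀ + d), T = Δmean/(s̃·√(1/n₁+1/n₂)),
  hyperparameters (d₀, s₀²) by moment-matching of log sample variances, and
  Benjamini–Hochberg adjustment within each (contrast, timepoint) family.
  Verified against R/limma to machine precision in the test suite.
- **Coexpression networks** (`ascnet.network`): unsigned soft-threshold
  adjacency a\_ij = |cor(x\_i, x\_j)|^β with β = 8; topological overlap
  TOM\_ij = (l\_ij + a\_ij)/(min(k\_i,k\_j) + 1 − a\_ij); average-linkage
  clustering of 1 − TOM; adaptive (dynamic) tree cut with minClusterSize 8
  and cutHeight 0.995; merging of modules whose eigengenes (module PC1)
  are closer than 0.2 in correlation dissimilarity; intramodular
  connectivity kWithin; export of the 50,000 strongest edges with
  betweenness centrality (TSV and GEXF).
- **Cross-condition module matching** (`ascnet.module_match`): one-sided
  Fisher exact overlap of module memberships on the shared universe, −log10 p
  heat-map tables, and greedy label harmonization so maximally overlapping
  modules share a color.
- **Trend-split enrichment** (`ascnet.enrichment`): per-module up/down gene
  lists from the net log2 change across consecutive timepoints (SD > 0.2
  filter, lists under 5 genes dropped); exact hypergeometric enrichment where
  the draw is the gene list, the successes the signature, and the population
  the probes on the platform; signed z = Φ⁻¹(1 − p) with z set to 0 where
  p > 0.05; GMT/OBO/GAF support with annotation propagation to the root.
- **Rewiring** (`ascnet.dynamics`): intramodular connectivity scaled 0–1
  within each module, Δk vs. moderated-T scatter classification (thresholds
  ±0.285 and ±3), and the percent of shared top-100 TOM neighbors between
  conditions.

## Worked example

`examples/` contains one short script per capability. For instance,

```bash
python examples/02_differential_expression.py
```

prints (seed 0):

```
1275 probes survive the detection filter

DE probes (q < 0.05) per timepoint:
contrast   ifn_alpha_vs_none  ifn_gamma_vs_none
timepoint
0.0                        0                  0
2.0                        5                  0
4.0                       47                  1
6.0                       79                 12
12.0                      71                 26
24.0                      71                 54
48.0                      64                 71
96.0                      69                 82
```

i.e. the planted early-sustained IFN-α module drives a differential-
expression burst that is maximal at 6 h and then plateaus, while the
gradually rising IFN-γ module produces counts that keep growing over the
4-day course. `examples/06_rewiring.py` shows the complementary network
view: the strongest planted interferon hub shares only ~1% of its top-100
TOM neighbors between the unstimulated and IFN-α networks (chance level
~8%), because its module simply does not exist without IFN-α.

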