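# citepipe

A tested, reusable pipeline for combined surface-protein (antibody-derived
tag) + targeted-transcript single-cell analysis of PBMC cohorts, together
with a synthetic-cohort generator that provides ground truth for every
stage.

Stages, in the fixed order the pipeline runs them:

1. **QC** (`citepipe.qc`) — sample-tag demultiplexing (mixture-derived
   per-tag thresholds), artificial-doublet kNN expression-doublet flagging
   at a 7.5% default formation rate, a 128-molecule minimum-antibody floor,
   CLR (log2) normalization of antibody counts and per-cell total-count
   normalization of transcripts (scaled to 1000).
2. **Thresholding** (`citepipe.thresholding`) — per-antibody two-component
   Gaussian mixture fitted by EM on CLR values; the intersection of the
   weighted component densities is the minimum expression threshold and
   sub-threshold values are zeroed. A negative-population quantile route
   covers markers with no signal component, and manual overrides are last.
3. **Gating** (`citepipe.gating`) — Boolean immunophenotype gates (CD19+CD3−
   B cells, CD4+/CD8+ T cells within CD3+, classical/intermediate/
   nonclassical monocytes within CD19−CD3−CD56−, and NK cells) assign each
   cell the deepest terminal gate it satisfies.
4. **Clustering** (`citepipe.clustering`) — per major type, antibody-only
   shared-nearest-neighbour graphs and Leiden modularity clustering at
   per-type resolutions (B 0.8, CD4 T 1.0, CD8 T 1.3, CM 0.5, INT 0.4,
   NCM 0.4, NK 0.3), with marker-based post-hoc cluster splits. RNA
   features are rejected by the graph builder.
5. **Statistics** — Wilcoxon rank-sum differential expression with
   Bonferroni correction and the `adj_p < 0.05 & pct.1 > 0.2` filter
   (`citepipe.diffexpr`); per-participant cluster proportions tested by
   continuity-corrected log-odds + ANOVA + Tukey HSD
   (`citepipe.proportions`); the filtered antibody–gene Spearman screen and
   iterated random-forest importance ranking (`citepipe.association`).

`citepipe.synthetic` generates multi-group cohorts (default: 4 groups × 8
participants × 1,300 cells) with known cell types, bimodal antibody counts,
hashtag doublets, and planted proportion shifts / DE genes, reproducible
from one master seed.

## CLI

```sh
citepipe simulate --out cohort/ --seed 1            # synthetic cohort (MTX + CSV)
citepipe qc --cohort cohort/ --out qc/ --floor 128 --doublet-rate 0.075
citepipe threshold --clr qc/adt_clr.csv --out thresholds.csv --exclude CD197
citepipe run-all --cohort cohort/ --out results/ --seed 1
```

`run-all` writes the cell table with QC flags, the per-marker threshold
table, cluster assignments, DE tables (cluster-vs-rest and group contrasts),
proportion tests, the correlation screen, random-forest importance tables,
and a provenance log; every table carries the config hash and seed.

## Layout

```
src/citepipe/
  synthetic.py     cohort generator + ground truth
  matrix.py        CountMatrix container
  qc.py            demux, doublet removal, floor, normalization
  thresholding.py  mixture EM, density intersection, threshold application
  gating.py        Boolean gate definitions and assignment
  clustering.py    SNN graph, Leiden, post-hoc splits, 2-D embedding
  diffexpr.py      Wilcoxon DE screen
  proportions.py   log-odds ANOVA/Tukey proportion tests
  association.py   Spearman screen, random-forest importance
  io.py            MTX/CSV/YAML readers and writers
  pipeline.py      end-to-end driver with provenance
  cli.py           click CLI
  plots.py         diagnostic plots
```
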