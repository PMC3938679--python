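# rhexpress

Cytokine-response transcriptomics of reconstructed human epidermis
(RHE), and what happens to those genes in patients when the cytokine is
blocked.

Monolayer keratinocyte cultures respond weakly to IL-17; a
reconstructed human epidermis — keratinocytes stratified into basal,
spinous, granular and cornified layers — responds far more broadly, and
the genes it induces overlap the psoriasis disease transcriptome.
`rhexpress` is the analysis toolkit for that study design:

* **Filtering + differential expression.** Probes must exceed 3 log2
  units in at least one sample with SD > 0.1.  Paired
  treated-vs-control arrays are tested with an empirical-Bayes
  *moderated paired t-test*: per-probe variances are shrunk toward a
  prior, s̃² = (d0·s0² + df·s²)/(d0 + df), with (d0, s0²) fitted by
  moments on the log-variances, and t = m / √(s̃²/n) referred to
  t with df + d0 degrees of freedom.  Benjamini–Hochberg FDR; DEGs at
  |FCH| > 1.5 and FDR < 0.1.
* **Probe/gene overlap.** Collapse probe-set DEGs to unique genes,
  restrict DEG sets to a smaller platform's probe universe, partition
  2–3 gene sets into Venn regions.
* **Pre-ranked GSEA.** Weighted Kolmogorov–Smirnov enrichment score on
  the log2-FCH ranking, gene-sampling permutation NES/p/FDR.
* **Treatment-recovery scoring.** Per gene: dysregulation d (lesional
  vs non-lesional), treatment effect t (week-2 vs baseline, within
  patient), improvement −t/d·100%; genes improving ≥ 75% are
  "improved", the rest form the residual-disease profile; arms are
  summarized by proportion improved and mean log2 movement toward
  non-lesional levels.
* **Synthetic data.** A seeded generator produces paired experiments,
  platform annotations and multi-arm cohorts with known ground truth
  (planted effects, variance prior, per-gene recovery fractions), so
  every stage can be validated end to end.

## Worked example

```python
import rhexpress as rx

# a 12,000-probe, 4-pair synthetic RHE experiment with known truth
matrix, ann, truth = rx.simulate_rhe_dataset(rx.SimConfig(seed=1))

filtered = rx.filter_probes(matrix)               # max > 3, SD > 0.1
result = rx.ModeratedPairedTTest(filtered, ann).fit()
print(result.summary())
```

```
Moderated paired t-test
=======================================================
probes tested             11869
pairs                         4
prior df (d0)             4.257
prior variance s0^2      0.1008
DEGs (|FCH|>1.5, FDR<0.1)  up: 787  down: 444
```

The fitted prior (d0 ≈ 4.3, s0² ≈ 0.10) recovers the simulation's
variance model — the generator drew σ² with d0 = 4 around s0² = 0.05,
and paired differences double the variance.  787 up / 444 down DEG
probe-sets reflect the planted 10% responsive fraction with a 2:1
up/down split.  Enrichment of the planted responsive signature in the
ranked profile:

```python
ranked = rx.rank_genes(result.table, ann)
sets = rx.simulate.truth_gene_sets(truth, ann)
print(rx.PrerankedGSEA(ranked, sets).fit(n_perm=1000, seed=7).summary())
```

```
                 size      es    nes  p_nominal  fdr_q
set
RESPONSIVE_UP     731  0.9612   3.21      0.001      0
RESPONSIVE_DOWN   412 -0.9306 -3.777      0.001      0
```

Genes with planted positive effects pile up at the top of the ranking
(NES 3.2), the down-regulated ones at the bottom (NES −3.8), both far
beyond anything the permutation null produces.  The full pipeline —
including the three-arm cohort and recovery scoring — runs with one
call (or `rhexpress all` on the command line):

```python
summary = rx.run_pipeline(rx.PipelineConfig(outdir="run", seed=1))
print(summary["stages"]["recovery"]["per_arm"]["il17_blockade"])
```

```
{'n_genes': 883.0, 'n_excluded': 51.0, 'prop_improved': 0.7417893544733862,
 'mean_log2_recovery': 1.7843039309578477, 'fch_recovery': 3.4445223306086286}
```

Under IL-17 blockade, 74% of the scored DEG genes recover at least 75%
of their baseline dysregulation by week 2, and on average they move
1.78 log2 units (3.4-fold) back toward non-lesional levels; the placebo
arm stays at a fold change of ~1.0.

## Command line

```sh
rhexpress simulate --seed 3 --outdir sim/
rhexpress de --matrix sim/expression.tsv --samples sim/samples.tsv \
             --annotation sim/annotation.tsv --out degs.tsv
rhexpress gsea --ranks ranked.tsv --gmt sim/gene_sets.gmt --nperm 1000 --seed 7 --out gsea.tsv
rhexpress recovery --cohort sim/cohort.tsv --samples sim/cohort_samples.tsv \
                   --genes genes.txt --threshold 75 --out recovery/
rhexpress all --config pipeline.yaml
```

All formats are plain TSV (expression matrices, sample sheets,
annotations) and standard GMT for gene sets.

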