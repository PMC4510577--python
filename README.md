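# chromshift

Comparative analysis of activating (H3K4me3) and repressive (H3K27me3)
histone-methylation ChIP-seq profiles across cell states — the kind of
study that asks how *ex vivo* culture of cord-blood CD34+ hematopoietic
stem/progenitor cells remodels promoter chromatin under different cytokine
cocktails (fresh CD34−, fresh CD34+, STF-cultured, STFIA-cultured).

The package implements the full desk-side pipeline:

- **SICER-style island calling** under a Poisson background, tuned for both
  focal promoter peaks (H3K4me3) and multi-kilobase broad domains / BLOCs
  (H3K27me3);
- **genome-wide 500 bp binning**, library normalization, replicate Pearson
  QC and unsupervised hierarchical clustering with Ward's minimum-variance
  linkage;
- **element annotation** of called islands (promoter, 5′UTR, exon, intron,
  3′UTR, TSS, intergenic), island-size kernel densities, and strand-aware
  TSS/gene-body meta-profiles stratified by expression extremes;
- **promoter mark dynamics**: read counting in −1000..+500 bp promoter
  windows, log2 fold-change ranking paired with expression, per-sample
  enriched-promoter sets and Venn partitions, four-state
  (none/K4only/K27only/bivalent) classification and co-occupancy dynamics
  maps across samples;
- a **synthetic-data generator** that plants focal K4 peaks on active/bivalent
  promoters and broad K27 domains over silenced/bivalent gene bodies, with
  replicates, library-size variation, Poisson background and a correlated
  expression table — and exports the ground truth, so every stage is
  testable without external data.

## The model

Reads are reduced to genomic anchors (5′ end shifted 73 bp toward 3′, an
unpaired-end proxy for the fragment midpoint) and counted in non-overlapping
windows of width *w* (default 200 bp). With *N* mapped tags on an effective
genome of length *L*, the background is Poisson with rate λ = *N·w*/*L* per
window. A window is *eligible* when its count reaches the smallest *l*₀ with
P(X ≥ *l*₀; λ) < *p*₀. An *island* is a maximal run of eligible windows in
which consecutive eligible windows are separated by at most *g* bp of
ineligible windows (*g* = *w* for focal marks, 3*w* for broad marks); its
score is Σ −ln P(X = kᵢ; λ) over eligible windows. Island significance is the
Poisson upper tail of the island's total count given its span, controlled
genome-wide by Benjamini–Hochberg at q < 0.01.

A promoter (−1000..+500 bp around the TSS, strand-oriented) is *enriched*
for a mark when it overlaps a significant island by ≥ 1 bp, and *bivalent*
exactly when enriched for both marks — bivalency is the set intersection of
the two per-mark enrichment sets, with no extra thresholding.

## Worked example

```python
import chromshift as cs

cfg = cs.SimulationConfig(n_chroms=2, chrom_length=3_000_000, n_genes=200,
                          reads_per_sample=60_000, min_gene_gap=12_000, seed=7)
layout, genes = cs.generate_genome(cfg)
tags, truth = cs.generate_reads(layout, genes, cfg)

merged = cs.filter_redundant_tags(cs.merge_replicates(
    [tags[("CD34pos", "H3K4me3", r)] for r in range(cfg.n_replicates)]))
k4 = cs.find_islands(merged, layout, cs.FOCAL_PARAMS)
print(f"H3K4me3: {len(k4)} islands, "
      f"{100 * cs.genome_fraction_covered(k4, layout):.2f}% of the genome")

merged27 = cs.filter_redundant_tags(cs.merge_replicates(
    [tags[("CD34pos", "H3K27me3", r)] for r in range(cfg.n_replicates)]))
k27 = cs.find_islands(merged27, layout, cs.BROAD_PARAMS)
print(f"H3K27me3: {len(k27)} islands, "
      f"{100 * cs.genome_fraction_covered(k27, layout):.2f}% of the genome")

windows = cs.promoter_windows(genes, layout)
k4_sets = cs.enriched_promoter_sets({"CD34pos": k4}, windows)
k27_sets = cs.enriched_promoter_sets({"CD34pos": k27}, windows)
states = cs.bivalency_states(k4_sets, k27_sets, [g.gene_id for g in genes])
print(cs.state_counts(states))
```

which prints

```
H3K4me3: 110 islands, 2.13% of the genome
H3K27me3: 175 islands, 31.33% of the genome
          CD34pos
none            2
K4only         80
K27only        88
bivalent       30
```

The activating mark forms many small islands covering ~2% of the genome
while the repressive mark blankets ~31% in broad domains — the focal-vs-BLOC
contrast the caller is built to resolve. All 30 promoters planted as
bivalent in this study are recovered as bivalent (`truth.gene_states` holds
the planted assignments for checking).

The same stages are scriptable from the shell:

```bash
chromshift simulate --seed 7 --out study/
chromshift call-islands --tags study/CD34pos.H3K4me3.rep1.bed \
    --chrom-sizes study/genome.chrom.sizes --mark-profile focal --out k4.bed
chromshift run --config config.yaml        # full pipeline + JSON report
```

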