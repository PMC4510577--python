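# Methods

## Scope

`chromshift` analyses histone-modification ChIP-seq across conditions: it
calls enriched islands for a focal activating mark (H3K4me3) and a broad
repressive mark (H3K27me3), quantifies genome-wide signal in fixed bins for
replicate QC and sample clustering, annotates islands on genomic elements,
builds TSS/gene-body meta-profiles, and classifies promoters into
none/K4only/K27only/bivalent states whose dynamics are tracked across
samples. A first-class synthetic-data generator plants all of this structure
with exported truth, so the pipeline's statistical behaviour is measurable.

## Coordinate and read conventions

All intervals are 0-based, half-open (BED convention); no operation emits
1-based coordinates. Reads enter as BED6 (BED3 accepted; strand defaults to
'+'). The 5′ end of a read is `start` on '+' and `end − 1` on '−'.
Redundancy filtering keeps at most one read per (chromosome, 5′ position,
strand) by default — the conservative standard for unpaired-end ChIP-seq —
and is order-independent. For all counting, a read is anchored at its 5′ end
shifted 73 bp toward 3′, approximating the fragment midpoint of
~146 bp chromatin fragments without paired ends; the shift is configurable.
Replicates of one sample/mark are concatenated before analysis (their union
is the unit of island calling), after per-replicate validation.

## Island calling

Windows of width *w* tile each chromosome from zero (terminal window
truncated). With *N* tags and effective genome length *L* (genome length ×
effective-genome-fraction), the per-window background rate is λ = *N·w/L*.

- **Eligibility**: the threshold *l₀* is the smallest integer with
  P(X ≥ *l₀*; λ) < *p₀* (never below 1, so empty windows are never
  eligible). Decreasing *p₀* can only raise *l₀*.
- **Assembly**: an island is a maximal run of eligible windows in which
  consecutive eligible windows are ≤ *g* bp of ineligible windows apart;
  interior gap windows contribute their reads to the island total but not
  to its score. Islands start and end on eligible windows, are disjoint,
  and are separated by more than *g*. Increasing *g* can only merge
  islands, never split them.
- **Score**: Σ over eligible windows of −ln P(X = k; λ), computed in log
  space to avoid underflow.
- **Significance**: island p-value = Poisson upper tail of the island's
  total read count with expectation λ × (number of spanned windows); a
  truncated terminal window still counts as one standard window in the
  expectation (documented approximation — it is conservative for partial
  windows). Benjamini–Hochberg correction is applied across all islands of
  one sample/mark and islands with q ≥ the FDR threshold (default 0.01)
  are removed. No control library is assumed; when one is provided, the
  expectation becomes the library-size-scaled control count over the same
  span, floored at one window's background rate.

Defaults: *w* = 200 bp, *g* = 200 bp for the focal mark and 600 bp for the
broad mark, *p₀* = 0.2, FDR 0.01, effective genome fraction 0.8 — the
community conventions for focal-vs-broad calling. For boundary-fidelity
studies of ~1 kb focal peaks the package uses *w* = 50, *g* = 100 and
*p₀* = 0.01 (`evaluate.RECOVERY_FOCAL_PARAMS`): with 200 bp windows a 1 kb
feature is grid-covered by ~1.2 kb, capping the achievable Jaccard overlap
near 0.83 regardless of signal, so finer windows are a geometric necessity,
and the stricter eligibility tail keeps background windows from attaching
to island edges at 50 bp granularity.

Known limitation: the background rate is estimated from *all* tags. When
enrichment covers a large genome fraction (dense broad domains), λ is
inflated and weak domains fall below eligibility — visible in the demo
design below. Local-background correction is deliberately out of scope.

## Binning and clustering

The genome is partitioned into fixed bins (default 500 bp, terminal bins
truncated); anchored reads are counted per bin per sample, and column sums
equal library sizes. Normalization: cpm = count × 10⁶ / library size;
log2cpm = log2(cpm + 1). Zero-count bins are retained — they carry
information for Ward heights. Replicate agreement uses Pearson correlation
of log2cpm columns (Spearman behind a flag); a constant column is an error,
not a NaN. Clustering is Ward's minimum-variance linkage on Euclidean
distances between log2cpm columns, via the standard nearest-neighbor-chain
implementation (deterministic; topology is invariant to sample order, which
the tests verify under random permutations).

A caveat for scaled-down genomes: with few reads per million-scale genome,
one read in a 500 bp bin is tens of cpm, so the +1 pseudocount no longer
smooths low counts and log2cpm becomes noisy for sparse focal marks. At
genome scale (reads ≫ bins) this effect vanishes. The clustering-fidelity
study therefore profiles each replicate by its bins across *both* marks,
which is also the natural reading of "cluster the condition replicates".

## Element annotation and profiles

Islands are classified by their midpoint with a fixed precedence:
TSS core (±500 bp of the TSS) > promoter (−1000..+500 strand-oriented,
minus the TSS core) > 5′UTR > 3′UTR > exon > intron > intergenic. UTRs are
exonic sequence outside the CDS, resolved by strand. The precedence is a
declared convention (annotation schemes listing both "promoter" and "TSS"
rarely define their overlap rule); a per-base oracle in the tests confirms
the indexed implementation. Island-size distributions are Gaussian KDEs of
log10 length (degenerate all-equal input is reported as a point mass).

TSS meta-profiles count anchored reads in strand-oriented offset bins
(default ±3 kb, 50 bp steps; upstream negative), scale per million library
tags, and average over genes; gene-body profiles rescale each body to 100
relative bins with 1 kb real-bp flanks. Expression stratification takes the
top/bottom *n* genes by expression with deterministic gene-id tie-breaks.

## Promoter dynamics

Promoter windows are −1000..+500 bp around each TSS ([t−1000, t+500) on
'+', reflected [t−499, t+1001) on '−'; 1500 bp wide except when clipped at
chromosome edges). Counts are cpm-normalized; log2 fold changes use
log2((cpm_a + c)/(cpm_b + c)) with c = 1 cpm, bounding fold changes for
empty promoters, and are ranked descending with the paired expression
log2FC carried per gene. Enrichment is ≥ 1 bp island overlap (a
minimum-overlap-fraction flag exists). With multiple transcripts per gene,
any enriched transcript window marks the gene. Venn partitions enumerate
every membership combination across samples and sum to the union size.
Bivalency is exactly K4-set ∩ K27-set per sample. The co-occupancy map
restricts to genes bivalent in ≥ 1 sample and tallies, per ordered sample
pair, how the first sample's bivalent genes resolve in the second:
retained / resolved-to-K4 / resolved-to-K27 / lost, with the retained
fraction reported.

## Synthetic data

The generator emulates a four-sample (fresh CD34−, fresh CD34+, STF,
STFIA), two-mark design. Genes (default 500 on a 5 Mb, two-chromosome
genome; lengths uniform 2–10 kb; 1–5 exons; a CDS for UTR annotation) are
placed uniformly with a minimum spacing (`min_gene_gap`). The reference
sample (fresh CD34+) assigns exact proportions of gene states — 40%
active, 15% bivalent, 45% silent — and every other sample reassigns a
configurable fraction (default 30%) of gene states, so clustering and
dynamics maps have planted between-condition signal. When
`bivalent_retention` is set, exactly that fraction of reference-bivalent
genes stays bivalent in each other sample and the rest resolve to
active/silent, planting a known retained fraction for the dynamics map.

Reads (36 bp, strands random) are a mixture of uniform background and
feature-placed reads such that read density inside planted features is
`enrichment_fold` × the background density (default 8). H3K4me3 features
are 1 kb boxes centred on the TSS of active and bivalent genes; H3K27me3
features extend the gene body of silent and bivalent genes symmetrically
to a width drawn uniformly from 5–20 kb (never narrower than the body, so
a planted domain always covers its promoter — otherwise planted bivalency
would be structurally unrecoverable), plus random intergenic blocks (0.2
per gene, ≥ 2 kb from any gene). Overlapping planted intervals are merged
in the exported truth. Replicate library sizes are Normal(mean, cv × mean)
(default cv 0.1); each replicate emits exactly its drawn size. Expression
is state-anchored (silent 2, bivalent 6, active 10 on log2 scale — 4 log2
units of separation) plus Gaussian noise (default sd 0.25).

What the generator does *not* model: sequence, mappability/GC bias,
fragment-length variation, chromatin input controls, copy-number effects,
and realistic gene-density heterogeneity. Passing tests therefore
demonstrate the pipeline's statistical correctness under a clean Poisson
world, not robustness to real-library artefacts.

## Validation studies and problem sizes

The studies in `chromshift.evaluate` (also recomputed by
`scripts/acceptance.py`) use these designs, sized to run in minutes on one
CPU:

- **Null calibration**: 200 pure-background libraries (5 Mb, 50k reads);
  candidate islands surviving BH at q < 0.01 are counted against the
  nominal rate with a binomial envelope.
- **Recovery**: 20 seeds of a sparse 5 Mb / 100-gene / 200k-read design
  (12 kb minimum spacing keeps planted features separable); median
  per-island Jaccard of planted vs called islands, per mark.
- **Clustering**: 20 seeds of the demo design; success = all four
  replicate pairs merge before any cross-condition merge.
- **Bivalency and retention**: 20 (resp. 5) seeds of a 6 Mb / 200-gene /
  60k-read design with 12 kb spacing, which makes planted states
  geometrically identifiable — a neighbour's broad domain cannot reach an
  unrelated promoter.

The demo design itself (500 genes on 5 Mb) is ~10× denser than a real
genome; its broad-mark footprint covers over half the genome, which
inflates the global background estimate and suppresses weak K27 islands
(see the island-calling limitation above). The demo's promoter-state
counts are therefore reported as qualitative output of the full pipeline,
while the quantitative recovery claims rest on the dedicated sparse
studies.

## Determinism

All generator randomness flows from named `SeedSequence` children of the
study seed; identical config + seed reproduces byte-identical outputs. The
island caller, clustering and all downstream stages are deterministic
functions of their inputs. The pipeline report is reproducible modulo
elapsed-time fields, and `resume: true` reloads the serialized outputs of
the expensive stages (simulation, island calling) instead of recomputing
them; downstream stages are cheap and always recomputed.
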