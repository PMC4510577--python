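"""Island annotation on genomic elements, size distributions, meta-profiles.

Islands are located on functional elements (TSS core, promoter, UTRs, exon,
intron, intergenic) by their midpoint with a fixed precedence; island-length
distributions are summarized as Gaussian kernel densities on the log10
scale; average read-density profiles are computed around TSSs (strand
oriented) and over length-rescaled gene bodies, optionally stratified by
expression extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import gaussian_kde

from .io import DEFAULT_FRAGMENT_SHIFT, GeneModel, GenomeLayout, TagCollection
from .islands import Island

#: Element labels in classification precedence order (highest first).
ELEMENT_PRECEDENCE = ("TSS", "promoter", "5UTR", "3UTR", "exon", "intron", "intergenic")

#: Display order of the distribution (the conventional reporting order).
ELEMENT_ORDER = ("promoter", "5UTR", "exon", "intron", "3UTR", "TSS", "intergenic")

TSS_CORE_HALF = 500          # TSS core: +-500 bp around the TSS
PROMOTER_UPSTREAM = 1000     # promoter: -1000..+500 strand-oriented, minus TSS core
PROMOTER_DOWNSTREAM = 500


@dataclass
class GenomeAnnotation:
    """Per-chromosome interval index of (precedence, label) gene features."""

    trees: dict[str, IntervalTree]

    def label_at(self, chrom: str, pos: int) -> str:
        tree = self.trees.get(chrom)
        if tree is None:
            return "intergenic"
        hits = tree[pos]
        if not hits:
            return "intergenic"
        return min(hits, key=lambda iv: iv.data[0]).data[1]


def _strand_window(tss: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Genomic half-open interval covering [-upstream, +downstream) around a TSS."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream + 1, tss + upstream + 1


def build_annotation(genes: Iterable[GeneModel], layout: GenomeLayout) -> GenomeAnnotation:
    """Index gene features for midpoint classification.

    Precedence (spanning features of lower rank are masked): TSS core >
    promoter > 5'UTR > 3'UTR > exon > intron. UTRs are exonic sequence
    outside the CDS (thick) region, resolved by strand.
    """
    prio = {label: i for i, label in enumerate(ELEMENT_PRECEDENCE)}
    trees: dict[str, IntervalTree] = {name: IntervalTree() for name in layout.names}

    def add(chrom: str, s: int, e: int, label: str) -> None:
        s = max(0, s)
        e = min(layout.length_of(chrom), e)
        if s < e:
            trees[chrom][s:e] = (prio[label], label)

    for g in genes:
        add(g.chrom, g.tss - TSS_CORE_HALF, g.tss + TSS_CORE_HALF, "TSS")
        ps, pe = _strand_window(g.tss, g.strand, PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM)
        add(g.chrom, ps, pe, "promoter")
        add(g.chrom, g.tx_start, g.tx_end, "intron")
        for es, ee in zip(g.exon_starts, g.exon_ends):
            add(g.chrom, es, ee, "exon")
            # UTR = exonic outside the CDS, 5' vs 3' by strand
            if es < g.thick_start:
                utr5 = "5UTR" if g.strand == "+" else "3UTR"
                add(g.chrom, es, min(ee, g.thick_start), utr5)
            if ee > g.thick_end:
                utr3 = "3UTR" if g.strand == "+" else "5UTR"
                add(g.chrom, max(es, g.thick_end), ee, utr3)
    return GenomeAnnotation(trees)


def classify_island(island: Island, annotation: GenomeAnnotation) -> str:
    """Element label at the island midpoint; 'intergenic' when nothing overlaps."""
    midpoint = (island.start + island.end) // 2
    return annotation.label_at(island.chrom, midpoint)


def element_distribution(
    islands: Sequence[Island], annotation: GenomeAnnotation
) -> pd.Series:
    """Fractions of islands per element label (summing to 1)."""
    if not islands:
        raise ValueError("empty island list")
    counts = {label: 0 for label in ELEMENT_ORDER}
    for isl in islands:
        counts[classify_island(isl, annotation)] += 1
    total = len(islands)
    return pd.Series({label: counts[label] / total for label in ELEMENT_ORDER}, name="fraction")


@dataclass
class SizeDensity:
    """Gaussian KDE of island lengths on the log10 scale.

    When all lengths coincide the KDE degenerates and the distribution is
    reported as a point mass at that length.
    """

    grid: np.ndarray          # log10(length) support
    density: np.ndarray
    n_islands: int
    is_point_mass: bool = False

    @property
    def mode_log10(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def size_density(
    islands: Sequence[Island],
    bandwidth: float | str | None = None,
    grid_points: int = 512,
    pad: float = 0.5,
) -> SizeDensity:
    """Kernel density of log10 island lengths, integrating to ~1 on its grid."""
    if len(islands) < 2:
        raise ValueError("need at least 2 islands for a density")
    logl = np.log10([isl.length for isl in islands])
    if np.allclose(logl, logl[0]):
        return SizeDensity(
            grid=np.array([logl[0]]), density=np.array([np.inf]),
            n_islands=len(islands), is_point_mass=True,
        )
    kde = gaussian_kde(logl, bw_method=bandwidth)
    grid = np.linspace(logl.min() - pad, logl.max() + pad, grid_points)
    return SizeDensity(grid=grid, density=kde(grid), n_islands=len(islands))


def select_expression_extremes(
    expression: pd.Series, n: int
) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n genes by expression; ties broken by gene id."""
    if n > len(expression) // 2:
        raise ValueError(f"n={n} exceeds half the table size ({len(expression)})")
    df = expression.rename("value").rename_axis("gene_id").reset_index()
    df = df.sort_values(["value", "gene_id"], ascending=[False, True], kind="mergesort")
    top = df.head(n)["gene_id"].tolist()
    bottom = df.sort_values(["value", "gene_id"], ascending=[True, True], kind="mergesort")
    return top, bottom.head(n)["gene_id"].tolist()


@dataclass
class MetaProfile:
    """Average normalized read density on a relative-coordinate grid.

    ``offsets`` are strand-oriented bp relative to the anchor (negative =
    upstream of transcription); ``density`` is the mean reads-per-million per
    position bin per region.
    """

    offsets: np.ndarray
    density: np.ndarray
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})


def tss_metaprofile(
    tags: TagCollection,
    genes: Sequence[GeneModel],
    gene_ids: Iterable[str] | None = None,
    flank: int = 3000,
    step: int = 50,
    shift: int = DEFAULT_FRAGMENT_SHIFT,
) -> MetaProfile:
    """Strand-oriented average read density around TSSs.

    For each gene, anchored reads within +-flank of the TSS are assigned to
    ``step``-bp offset bins (upstream negative); per-bin counts are scaled
    per million library tags and averaged over genes.
    """
    if flank <= 0 or step <= 0:
        raise ValueError("flank and step must be positive")
    selected = list(genes)
    if gene_ids is not None:
        wanted = set(gene_ids)
        selected = [g for g in selected if g.gene_id in wanted]
    if not selected:
        raise ValueError("empty gene set")

    n_bins = 2 * flank // step
    hist = np.zeros(n_bins, dtype=np.float64)
    anchors = tags.anchors(shift)
    index = tags.layout.index
    # per-chromosome sorted anchors for range queries
    by_chrom: dict[int, np.ndarray] = {}
    for ci in np.unique(tags.chrom):
        by_chrom[int(ci)] = np.sort(anchors[tags.chrom == ci])

    for g in selected:
        ci = index[g.chrom]
        pos = by_chrom.get(ci)
        if pos is None:
            continue
        lo, hi = g.tss - flank, g.tss + flank
        sel = pos[np.searchsorted(pos, lo): np.searchsorted(pos, hi)]
        if sel.size == 0:
            continue
        offset = sel - g.tss if g.strand == "+" else g.tss - sel
        bins = (offset + flank) // step
        np.add.at(hist, np.clip(bins, 0, n_bins - 1), 1.0)

    scale = 1e6 / max(len(tags), 1)
    density = hist * scale / len(selected)
    offsets = -flank + step * np.arange(n_bins) + step / 2.0
    return MetaProfile(offsets=offsets, density=density, n_regions=len(selected))


def genebody_metaprofile(
    tags: TagCollection,
    genes: Sequence[GeneModel],
    gene_ids: Iterable[str] | None = None,
    n_body_bins: int = 100,
    flank: int = 1000,
    flank_bins: int = 10,
    shift: int = DEFAULT_FRAGMENT_SHIFT,
) -> MetaProfile:
    """Average density over gene bodies rescaled to 0-100% of gene length.

    Real-bp flanks are appended at both ends; offsets are reported on a
    relative scale where 0..100 is the gene body and the flanks extend
    beyond it in units of body percent.
    """
    selected = list(genes)
    if gene_ids is not None:
        wanted = set(gene_ids)
        selected = [g for g in selected if g.gene_id in wanted]
    if not selected:
        raise ValueError("empty gene set")

    total_bins = n_body_bins + 2 * flank_bins
    hist = np.zeros(total_bins, dtype=np.float64)
    anchors = tags.anchors(shift)
    index = tags.layout.index
    by_chrom: dict[int, np.ndarray] = {}
    for ci in np.unique(tags.chrom):
        by_chrom[int(ci)] = np.sort(anchors[tags.chrom == ci])

    for g in selected:
        pos = by_chrom.get(index[g.chrom])
        if pos is None:
            continue
        lo, hi = g.tx_start - flank, g.tx_end + flank
        sel = pos[np.searchsorted(pos, lo): np.searchsorted(pos, hi)]
        if sel.size == 0:
            continue
        body = sel[(sel >= g.tx_start) & (sel < g.tx_end)]
        up = sel[sel < g.tx_start]
        down = sel[sel >= g.tx_end]
        frac = (body - g.tx_start) / g.length
        upb = (up - (g.tx_start - flank)) / flank * flank_bins
        downb = (down - g.tx_end) / flank * flank_bins
        if g.strand == "+":
            b_bins = flank_bins + np.floor(frac * n_body_bins)
            u_bins = np.floor(upb)
            d_bins = flank_bins + n_body_bins + np.floor(downb)
        else:
            b_bins = flank_bins + n_body_bins - 1 - np.floor(frac * n_body_bins)
            u_bins = total_bins - 1 - np.floor(upb)
            d_bins = flank_bins - 1 - np.floor(downb)
        allb = np.concatenate([u_bins, b_bins, d_bins]).astype(np.int64)
        np.add.at(hist, np.clip(allb, 0, total_bins - 1), 1.0)

    scale = 1e6 / max(len(tags), 1)
    density = hist * scale / len(selected)
    offsets = np.concatenate(
        [
            np.linspace(-flank_bins, -1, flank_bins) * (100.0 / n_body_bins),
            np.arange(n_body_bins) * (100.0 / n_body_bins) + 50.0 / n_body_bins,
            100 + (np.arange(flank_bins) + 0.5) * (100.0 / n_body_bins),
        ]
    )
    return MetaProfile(offsets=offsets, density=density, n_regions=len(selected))


def write_distribution(dist: pd.Series, path: str | Path) -> None:
    dist.rename_axis("element").to_csv(path, sep="\t", header=True)


def write_profile(profile: MetaProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
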