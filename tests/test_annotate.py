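"""Element classification vs a per-base oracle, size KDEs, meta-profiles."""

import numpy as np
import pytest

from chromshift import (
    GeneModel,
    GenomeLayout,
    Island,
    build_annotation,
    classify_island,
    element_distribution,
    select_expression_extremes,
    size_density,
    tss_metaprofile,
)
from chromshift.annotate import (
    ELEMENT_PRECEDENCE,
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    TSS_CORE_HALF,
)

def toy_genes():
    return [
        # + strand, 3 exons, CDS trimmed inside first/last exon
        GeneModel("gA", "chr1", "+", 20_000, 28_000,
                  (20_000, 23_000, 26_500), (21_000, 24_000, 28_000), 20_400, 27_200),
        # - strand single exon
        GeneModel("gB", "chr1", "-", 40_000, 45_000, (40_000,), (45_000,), 40_800, 44_200),
        # + strand near another gene (overlapping annotations exercise precedence)
        GeneModel("gC", "chr2", "+", 5_000, 12_000, (5_000, 9_000), (6_000, 12_000),
                  5_300, 11_000),
    ]


def toy_layout_big():
    return GenomeLayout(("chr1", "chr2", "chrEmpty"), (60_000, 20_000, 10_000))


def per_base_label_oracle(genes, layout, chrom, pos):
    """Paint every feature of every gene; lowest precedence index wins."""
    best = "intergenic"
    best_rank = ELEMENT_PRECEDENCE.index("intergenic")

    def consider(lo, hi, label):
        nonlocal best, best_rank
        if lo <= pos < hi:
            r = ELEMENT_PRECEDENCE.index(label)
            if r < best_rank:
                best, best_rank = label, r

    for g in genes:
        if g.chrom != chrom:
            continue
        consider(g.tss - TSS_CORE_HALF, g.tss + TSS_CORE_HALF, "TSS")
        if g.strand == "+":
            consider(g.tss - PROMOTER_UPSTREAM, g.tss + PROMOTER_DOWNSTREAM, "promoter")
        else:
            consider(g.tss - PROMOTER_DOWNSTREAM + 1, g.tss + PROMOTER_UPSTREAM + 1, "promoter")
        consider(g.tx_start, g.tx_end, "intron")
        for es, ee in zip(g.exon_starts, g.exon_ends):
            consider(es, ee, "exon")
            if es < g.thick_start:
                consider(es, min(ee, g.thick_start), "5UTR" if g.strand == "+" else "3UTR")
            if ee > g.thick_end:
                consider(max(es, g.thick_end), ee, "3UTR" if g.strand == "+" else "5UTR")
    return best


class TestClassifyIsland:
    def test_known_placements(self):
        genes, layout = toy_genes(), toy_layout_big()
        ann = build_annotation(genes, layout)
        cases = [
            # midpoint in gA exon 2, outside promoter/UTR
            (Island("chr1", 23_200, 23_600, 1, 0.0), "exon"),
            # midpoint in gA intron
            (Island("chr1", 24_500, 25_500, 1, 0.0), "intron"),
            # midpoint at gA TSS core
            (Island("chr1", 19_900, 20_300, 1, 0.0), "TSS"),
            # midpoint upstream of gA TSS, outside the +-500 core
            (Island("chr1", 19_000, 19_400, 1, 0.0), "promoter"),
            # gB is '-': promoter reaches genomically above txEnd
            (Island("chr1", 45_400, 45_800, 1, 0.0), "promoter"),
            # 5'UTR of '-' gene gB sits at the high-coordinate end (exonic > thick_end)
            (Island("chr1", 44_300, 44_400, 1, 0.0), "5UTR"),
            (Island("chr1", 40_100, 40_500, 1, 0.0), "3UTR"),
            (Island("chrEmpty", 100, 600, 1, 0.0), "intergenic"),
        ]
        for island, expected in cases:
            assert classify_island(island, ann) == expected, (island, expected)

    def test_agrees_with_per_base_oracle(self, rng):
        genes, layout = toy_genes(), toy_layout_big()
        ann = build_annotation(genes, layout)
        for _ in range(150):
            ci = int(rng.integers(0, 3))
            chrom = layout.names[ci]
            mid = int(rng.integers(200, layout.lengths[ci] - 200))
            island = Island(chrom, mid - 100, mid + 100, 1, 0.0)
            # midpoint of [mid-100, mid+100) is mid
            assert classify_island(island, ann) == per_base_label_oracle(
                genes, layout, chrom, mid
            )


class TestElementDistribution:
    def test_fractions_sum_to_one_and_arithmetic(self):
        genes, layout = toy_genes(), toy_layout_big()
        ann = build_annotation(genes, layout)
        islands = (
            [Island("chr1", 19_000, 19_400, 1, 0.0)] * 3      # promoter
            + [Island("chr1", 24_500, 25_500, 1, 0.0)]        # intron
        )
        dist = element_distribution(islands, ann)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert dist["promoter"] == pytest.approx(0.75)
        assert dist["intron"] == pytest.approx(0.25)

    def test_empty_chromosome_all_intergenic(self):
        genes, layout = toy_genes(), toy_layout_big()
        ann = build_annotation(genes, layout)
        islands = [Island("chrEmpty", i * 1000, i * 1000 + 200, 1, 0.0) for i in range(5)]
        dist = element_distribution(islands, ann)
        assert dist["intergenic"] == 1.0

    def test_empty_list_rejected(self):
        ann = build_annotation(toy_genes(), toy_layout_big())
        with pytest.raises(ValueError):
            element_distribution([], ann)

    def test_invariant_under_chromosome_renaming(self):
        genes, layout = toy_genes(), toy_layout_big()
        renamed_layout = GenomeLayout(("k1", "k2", "k3"), layout.lengths)
        rename = dict(zip(layout.names, renamed_layout.names))
        renamed_genes = [
            GeneModel(g.gene_id, rename[g.chrom], g.strand, g.tx_start, g.tx_end,
                      g.exon_starts, g.exon_ends, g.thick_start, g.thick_end)
            for g in genes
        ]
        islands = [Island("chr1", 23_200, 23_600, 1, 0.0),
                   Island("chr2", 4_300, 4_500, 1, 0.0)]
        renamed_islands = [Island(rename[i.chrom], i.start, i.end, 1, 0.0) for i in islands]
        d1 = element_distribution(islands, build_annotation(genes, layout))
        d2 = element_distribution(
            renamed_islands, build_annotation(renamed_genes, renamed_layout)
        )
        assert (d1 == d2).all()


class TestSizeDensity:
    def test_equal_lengths_point_mass(self):
        islands = [Island("c", 0, 1000, 1, 0.0), Island("c", 2000, 3000, 1, 0.0)]
        sd = size_density(islands)
        assert sd.is_point_mass and sd.grid[0] == pytest.approx(3.0)

    def test_integrates_to_one(self, rng):
        lengths = rng.integers(400, 20_000, size=200)
        islands = [Island("c", 0, int(l), 1, 0.0) for l in lengths]
        sd = size_density(islands)
        integral = np.trapezoid(sd.density, sd.grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_mode_near_common_scale(self, rng):
        lengths = (10 ** rng.normal(3.5, 0.1, size=500)).astype(int)
        sd = size_density([Island("c", 0, int(l), 1, 0.0) for l in lengths])
        assert abs(sd.mode_log10 - 3.5) < 0.1

    def test_broad_mode_exceeds_focal_mode_on_planted_marks(self):
        from chromshift import FOCAL_PARAMS, BROAD_PARAMS, find_islands
        from chromshift.evaluate import recovery_config
        from chromshift.sim import generate_genome, generate_reads

        cfg = recovery_config(seed=42)
        layout, genes = generate_genome(cfg)
        tags, _ = generate_reads(layout, genes, cfg)
        k4 = find_islands(tags[("CD34pos", "H3K4me3", 0)], layout, FOCAL_PARAMS)
        k27 = find_islands(tags[("CD34pos", "H3K27me3", 0)], layout, BROAD_PARAMS)
        assert size_density(k27).mode_log10 > size_density(k4).mode_log10

    def test_too_few_islands_rejected(self):
        with pytest.raises(ValueError):
            size_density([Island("c", 0, 100, 1, 0.0)])


class TestExpressionExtremes:
    def test_tiny_example(self):
        import pandas as pd

        expr = pd.Series({"a": 5.0, "b": 1.0, "c": 3.0})
        top, bottom = select_expression_extremes(expr, 1)
        assert top == ["a"] and bottom == ["b"]

    def test_disjoint_and_matches_full_sort(self, rng):
        import pandas as pd

        values = rng.normal(size=2000)
        expr = pd.Series(values, index=[f"g{i:04d}" for i in range(2000)])
        top, bottom = select_expression_extremes(expr, 500)
        assert not set(top) & set(bottom)
        order = sorted(expr.index, key=lambda g: (-expr[g], g))
        assert top == order[:500]
        assert bottom == sorted(expr.index, key=lambda g: (expr[g], g))[:500]

    def test_oversized_n_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            select_expression_extremes(pd.Series({"a": 1.0, "b": 2.0}), 2)


class TestTssMetaprofile:
    def test_uniform_background_is_flat(self, tags_factory):
        from chromshift.sim import simulate_background

        layout = GenomeLayout(("chr1",), (2_000_000,))
        tags = simulate_background(layout, 200_000, seed=9)
        genes = [
            GeneModel(f"g{i}", "chr1", "+", p, p + 5000, (p,), (p + 5000,), p + 100, p + 4900)
            for i, p in enumerate(range(100_000, 1_900_000, 90_000))
        ]
        prof = tss_metaprofile(tags, genes, flank=3000, step=100)
        raw = prof.density * prof.n_regions * len(tags) / 1e6  # back to raw counts
        mean = raw.mean()
        z = (raw - mean) / np.sqrt(mean)
        assert np.abs(z).max() < 4.5  # flat within Monte-Carlo fluctuation

    def test_minus_strand_orientation(self, tags_factory):
        layout = GenomeLayout(("chr1",), (100_000,))
        gene = GeneModel("g", "chr1", "-", 40_000, 50_000, (40_000,), (50_000,),
                         41_000, 49_000)
        tss = gene.tss  # 49_999
        # reads whose anchors land 500 bp genomically below txEnd = downstream
        # of the TSS in transcription direction -> offset +500
        anchors = [tss - 500] * 20
        starts = [a - 73 for a in anchors]  # + strand: anchor = start + 73
        tags = tags_factory(layout, [0] * 20, starts)
        prof = tss_metaprofile(tags, [gene], flank=3000, step=50)
        peak_offset = prof.offsets[int(np.argmax(prof.density))]
        assert abs(peak_offset - 500) <= 50

    def test_planted_peaks_maximum_at_tss(self):
        from chromshift.evaluate import recovery_config
        from chromshift.sim import generate_genome, generate_reads

        cfg = recovery_config(seed=3)
        layout, genes = generate_genome(cfg)
        tags, truth = generate_reads(layout, genes, cfg)
        active = [g for g, s in truth.gene_states["CD34pos"].items()
                  if s in ("active", "bivalent")]
        prof = tss_metaprofile(tags[("CD34pos", "H3K4me3", 0)], genes, active)
        peak = prof.offsets[int(np.argmax(prof.density))]
        # planted peaks are 1 kb boxes centred on the TSS: the maximum falls
        # inside the box and the centre dwarfs the flanks
        assert abs(peak) <= 500
        centre = prof.density[np.abs(prof.offsets) < 500].mean()
        flanks = prof.density[np.abs(prof.offsets) > 2000].mean()
        assert centre > 5 * flanks

    def test_strand_symmetry_under_genome_mirroring(self, rng, tags_factory):
        """Mirroring reads and genes across the chromosome reflects nothing:
        strand-oriented profiles are identical."""
        L = 500_000
        layout = GenomeLayout(("chr1",), (L,))
        n = 20_000
        starts = rng.integers(0, L - 36, n)
        strands = rng.integers(0, 2, n)
        tags = tags_factory(layout, [0] * n, starts, strand=strands)
        mirrored_tags = tags_factory(
            layout, [0] * n, L - (starts + 36), strand=1 - strands
        )
        genes, mirrored = [], []
        for i in range(10):
            s = int(rng.integers(10_000, L - 20_000))
            e = s + 8000
            genes.append(GeneModel(f"g{i}", "chr1", "+", s, e, (s,), (e,), s + 10, e - 10))
            mirrored.append(
                GeneModel(f"g{i}", "chr1", "-", L - e, L - s, (L - e,), (L - s,),
                          L - e + 10, L - s - 10)
            )
        p1 = tss_metaprofile(tags, genes, flank=2000, step=50)
        p2 = tss_metaprofile(mirrored_tags, mirrored, flank=2000, step=50)
        np.testing.assert_allclose(p1.density, p2.density)

    def test_empty_gene_set_rejected(self, toy_layout, tags_factory):
        t = tags_factory(toy_layout, [0], [100])
        with pytest.raises(ValueError, match="empty gene set"):
            tss_metaprofile(t, [], None)
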