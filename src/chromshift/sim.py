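"""Synthetic ChIP-seq study generator with planted, exported ground truth.

Emulates the comparative design of a cord-blood HSPC culture study: four
samples (fresh CD34-, fresh CD34+, STF-cultured, STFIA-cultured) x two
histone marks, with replicates. H3K4me3 is planted as focal ~1 kb peaks
centred on the TSS of transcriptionally active and bivalent genes; H3K27me3
as broad multi-kilobase domains over silenced and bivalent gene bodies plus
random intergenic blocks (BLOC-like geometry). Background reads are uniform
Poisson noise; planted reads raise the local read density to
``enrichment_fold`` times background. Replicate library sizes vary with a
configurable coefficient of variation. An expression table correlated with
the planted promoter states of the reference sample (fresh CD34+) is
produced alongside.

Everything is deterministic under a fixed seed, and the planted truth
(island intervals, per-sample gene states, latent expression) is exported so
every downstream stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_READ_LENGTH,
    GeneModel,
    GenomeLayout,
    TagCollection,
    write_chrom_sizes,
    write_expression_table,
    write_gene_models,
    write_tags,
)

SAMPLES = ("CD34neg", "CD34pos", "STF", "STFIA")
#: Expression is defined relative to the fresh CD34+ sample.
REFERENCE_SAMPLE = "CD34pos"
MARKS = ("H3K4me3", "H3K27me3")
STATES = ("active", "silent", "bivalent")

#: Latent log2 expression per promoter state (4 log2 units of separation).
EXPRESSION_STATE_MEANS = {"silent": 2.0, "bivalent": 6.0, "active": 10.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    The defaults describe the demo design: a 5 Mb two-chromosome genome with
    500 genes, 40% active / 15% bivalent / 45% silent in the reference
    sample, 30% of gene states reassigned per non-reference condition,
    8-fold enrichment over background, two replicates of ~50k reads each.
    """

    n_chroms: int = 2
    chrom_length: int = 2_500_000
    n_genes: int = 500
    frac_active: float = 0.4
    frac_bivalent: float = 0.15
    k4_peak_width: int = 1000
    k27_domain_width_range: tuple[int, int] = (5000, 20000)
    reads_per_sample: int = 50_000
    background_rate: float = 0.005  # reads per bp, used when reads_per_sample is None
    enrichment_fold: float = 8.0
    n_replicates: int = 2
    library_size_cv: float = 0.1
    expression_noise_sd: float = 0.25
    state_shift_frac: float = 0.3
    bivalent_retention: float | None = None
    gene_length_range: tuple[int, int] = (2000, 10000)
    min_gene_gap: int = 1000
    read_length: int = DEFAULT_READ_LENGTH
    intergenic_block_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "reads_per_sample", "n_replicates",
                     "k4_peak_width", "read_length"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0 <= self.frac_active <= 1:
            raise ValueError("frac_active must be in [0, 1]")
        if not 0 <= self.frac_bivalent <= 1 - self.frac_active:
            raise ValueError("frac_active + frac_bivalent must not exceed 1")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        lo, hi = self.k27_domain_width_range
        if not 0 < lo <= hi:
            raise ValueError("invalid k27_domain_width_range")
        if lo <= self.k4_peak_width:
            raise ValueError(
                "k27_domain_width_range must start above k4_peak_width "
                "(broad domains must dominate focal peaks)"
            )
        if self.library_size_cv < 0 or self.expression_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if not 0 <= self.state_shift_frac <= 1:
            raise ValueError("state_shift_frac must be in [0, 1]")
        if self.bivalent_retention is not None and not 0 <= self.bivalent_retention <= 1:
            raise ValueError("bivalent_retention must be in [0, 1]")
        widest = max(hi, self.k4_peak_width, self.gene_length_range[1])
        if self.chrom_length < 10 * widest:
            raise ValueError("chrom_length must be >= 10x the widest planted feature")

    @property
    def frac_silent(self) -> float:
        return 1.0 - self.frac_active - self.frac_bivalent


@dataclass
class GroundTruth:
    """Planted truth exported next to the simulated reads.

    planted_islands
        (sample, mark) -> list of merged, disjoint (chrom, start, end).
    gene_states
        sample -> {gene id -> state in {active, silent, bivalent}}.
    expression_truth
        gene id -> latent (noise-free) log2 expression in the reference sample.
    """

    planted_islands: dict[tuple[str, str], list[tuple[str, int, int]]]
    gene_states: dict[str, dict[str, str]]
    expression_truth: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_islands": {
                f"{s}|{m}": [[c, int(a), int(b)] for c, a, b in v]
                for (s, m), v in self.planted_islands.items()
            },
            "gene_states": self.gene_states,
            "expression_truth": {k: float(v) for k, v in self.expression_truth.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        planted = {
            tuple(k.split("|")): [(c, int(a), int(b)) for c, a, b in v]
            for k, v in obj["planted_islands"].items()
        }
        return cls(planted, obj["gene_states"], obj["expression_truth"])


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> tuple[GenomeLayout, list[GeneModel]]:
    """Place non-overlapping gene models uniformly at random on both strands.

    Genes are spaced by at least ``config.min_gene_gap`` bp; leftover
    intergenic space is distributed uniformly at random among the gaps.
    Every gene gets 1-5 exons and a CDS (thick) region so UTR annotation is
    well defined downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple([config.chrom_length] * config.n_chroms),
    )
    if config.n_genes == 0:
        return layout, []

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    # distribute genes over chromosomes proportionally to length, then check fit
    chrom_of = rng.integers(0, config.n_chroms, size=config.n_genes)
    for _ in range(100):
        ok = True
        for ci in range(config.n_chroms):
            need = lengths[chrom_of == ci].sum() + (
                (chrom_of == ci).sum() + 1
            ) * config.min_gene_gap
            if need > config.chrom_length:
                ok = False
        if ok:
            break
        chrom_of = rng.integers(0, config.n_chroms, size=config.n_genes)
    else:
        raise ValueError("n_genes x minimal gene footprint exceeds genome size")

    genes: list[GeneModel] = []
    gid = 0
    for ci in range(config.n_chroms):
        idx = np.flatnonzero(chrom_of == ci)
        if idx.size == 0:
            continue
        lens = lengths[idx]
        k = idx.size
        slack = config.chrom_length - int(lens.sum()) - (k + 1) * config.min_gene_gap
        # uniform partition of the slack among the k+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        extra = np.diff(np.concatenate(([0], cuts, [slack])))
        pos = 0
        for j in range(k):
            pos += config.min_gene_gap + int(extra[j])
            start = pos
            end = start + int(lens[j])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(f"gene{gid:05d}", layout.names[ci], strand, start, end, rng))
            gid += 1
    return layout, genes


def _make_gene(
    name: str, chrom: str, strand: str, start: int, end: int, rng: np.random.Generator
) -> GeneModel:
    length = end - start
    n_exons = int(rng.integers(1, 6))
    n_exons = min(n_exons, max(1, (length - 1) // 2))
    if n_exons == 1:
        ex_starts, ex_ends = (start,), (end,)
    else:
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate(([0], cuts, [length])) + start
        ex_starts = tuple(int(bounds[i]) for i in range(0, 2 * n_exons, 2))
        ex_ends = tuple(int(bounds[i + 1]) for i in range(0, 2 * n_exons, 2))
    # CDS: trim ~20% off the first and last exon (strand-agnostic is fine here)
    thick_start = ex_starts[0] + max(1, (ex_ends[0] - ex_starts[0]) // 5)
    thick_end = ex_ends[-1] - max(1, (ex_ends[-1] - ex_starts[-1]) // 5)
    if thick_start >= thick_end:
        thick_start, thick_end = ex_starts[0], ex_ends[-1]
    return GeneModel(name, chrom, strand, start, end, ex_starts, ex_ends, thick_start, thick_end)


# ---------------------------------------------------------------------------
# Gene states across samples
# ---------------------------------------------------------------------------

def assign_gene_states(
    genes: list[GeneModel], config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Assign each gene a state per sample.

    The reference sample gets frac_active/frac_bivalent/frac_silent exact
    proportions; each other sample reassigns ``state_shift_frac`` of genes to
    a state redrawn from those proportions. When ``bivalent_retention`` is
    set, exactly that fraction of reference-bivalent genes stays bivalent in
    each non-reference sample and the remainder resolves to active or silent
    (equal split), planting a known retained-bivalent fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(genes)
    n_active = int(round(config.frac_active * n))
    n_biv = int(round(config.frac_bivalent * n))
    base = np.array(
        ["active"] * n_active + ["bivalent"] * n_biv + ["silent"] * (n - n_active - n_biv),
        dtype=object,
    )
    rng.shuffle(base)
    states = {REFERENCE_SAMPLE: base}
    probs = np.array([config.frac_active, config.frac_bivalent, config.frac_silent])
    probs = probs / probs.sum() if probs.sum() > 0 else np.array([1 / 3] * 3)
    choices = np.array(["active", "bivalent", "silent"], dtype=object)

    for sample in SAMPLES:
        if sample == REFERENCE_SAMPLE:
            continue
        s = base.copy()
        if config.bivalent_retention is not None:
            biv_idx = np.flatnonzero(base == "bivalent")
            n_keep = int(round(config.bivalent_retention * biv_idx.size))
            keep = rng.choice(biv_idx, size=n_keep, replace=False)
            resolve = np.setdiff1d(biv_idx, keep)
            s[resolve] = rng.choice(["active", "silent"], size=resolve.size)
            others = np.setdiff1d(np.arange(n), biv_idx)
        else:
            others = np.arange(n)
        n_shift = int(round(config.state_shift_frac * others.size))
        if n_shift > 0:
            shifted = rng.choice(others, size=n_shift, replace=False)
            s[shifted] = rng.choice(choices, size=n_shift, p=probs)
        states[sample] = s
    return states


# ---------------------------------------------------------------------------
# Planted features and read generation
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for c, s, e in sorted(ivals):
        if out and out[-1][0] == c and s <= out[-1][2]:
            out[-1] = (c, out[-1][1], max(out[-1][2], e))
        else:
            out.append((c, s, e))
    return out


def _planted_features(
    layout: GenomeLayout,
    genes: list[GeneModel],
    states: np.ndarray,
    mark: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    feats: list[tuple[str, int, int]] = []
    if mark == "H3K4me3":
        half = config.k4_peak_width // 2
        for g, st in zip(genes, states):
            if st in ("active", "bivalent"):
                s = max(0, g.tss - half)
                e = min(layout.length_of(g.chrom), g.tss + config.k4_peak_width - half)
                feats.append((g.chrom, int(s), int(e)))
    else:
        lo, hi = config.k27_domain_width_range
        for g, st in zip(genes, states):
            if st in ("silent", "bivalent"):
                width = max(int(rng.integers(lo, hi + 1)), g.length)
                ext = (width - g.length) // 2
                s = max(0, g.tx_start - ext)
                e = min(layout.length_of(g.chrom), g.tx_end + ext)
                feats.append((g.chrom, int(s), int(e)))
        feats.extend(_intergenic_blocks(layout, genes, config, rng))
    return _merge_intervals(feats)


def _intergenic_blocks(
    layout: GenomeLayout,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
    margin: int = 2000,
) -> list[tuple[str, int, int]]:
    """Random H3K27me3 blocks in intergenic space, >= margin bp from any gene."""
    n_blocks = int(round(config.intergenic_block_frac * len(genes)))
    if n_blocks == 0:
        return []
    by_chrom: dict[str, list[tuple[int, int]]] = {name: [] for name in layout.names}
    for g in genes:
        by_chrom[g.chrom].append((g.tx_start - margin, g.tx_end + margin))
    lo, hi = config.k27_domain_width_range
    blocks: list[tuple[str, int, int]] = []
    attempts = 0
    while len(blocks) < n_blocks and attempts < 50 * n_blocks:
        attempts += 1
        ci = int(rng.integers(0, len(layout)))
        width = int(rng.integers(lo, hi + 1))
        length = layout.lengths[ci]
        if width >= length:
            continue
        s = int(rng.integers(0, length - width))
        e = s + width
        name = layout.names[ci]
        if any(s < ge and gs < e for gs, ge in by_chrom[name]):
            continue
        if any(c == name and s < be and bs < e for c, bs, be in blocks):
            continue
        blocks.append((name, s, e))
    return blocks


def _uniform_reads(
    layout: GenomeLayout, n_reads: int, rng: np.random.Generator, read_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly placed read (chrom index, start) pairs across the genome."""
    offsets = np.concatenate(([0], np.cumsum(layout.lengths_array)))
    pos = rng.integers(0, layout.total_length, size=n_reads)
    ci = np.searchsorted(offsets, pos, side="right") - 1
    local = pos - offsets[ci]
    local = np.minimum(local, layout.lengths_array[ci] - read_length)
    return ci, np.maximum(local, 0)


def simulate_background(
    layout: GenomeLayout,
    n_reads: int,
    seed: int,
    read_length: int = DEFAULT_READ_LENGTH,
    sample: str | None = None,
    mark: str | None = None,
) -> TagCollection:
    """Pure uniform-background library with no planted enrichment.

    The null substrate for island-caller calibration studies.
    """
    rng = np.random.default_rng(seed)
    ci, starts = _uniform_reads(layout, n_reads, rng, read_length)
    strand = rng.integers(0, 2, size=n_reads).astype(np.int8)
    order = np.lexsort((starts, ci))
    return TagCollection(
        layout, ci[order].astype(np.int32), starts[order],
        (starts + read_length)[order], strand[order], sample=sample, mark=mark,
    )


def _sample_reads(
    layout: GenomeLayout,
    features: list[tuple[str, int, int]],
    n_reads: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample: str,
    mark: str,
) -> TagCollection:
    """Draw ``n_reads`` reads: a background/planted mixture.

    The planted fraction is chosen so read density inside planted features is
    ``enrichment_fold`` times the uniform background density. With
    ``background_rate == 0`` (or no genome outside features) every read is
    planted.
    """
    G = layout.total_length
    F = sum(e - s for _, s, e in features)
    fold = config.enrichment_fold
    if F == 0:
        p_planted = 0.0
    elif config.background_rate == 0 or F >= G:
        p_planted = 1.0
    else:
        p_planted = (fold - 1) * F / (G + (fold - 1) * F)
    n_planted = int(rng.binomial(n_reads, p_planted))
    n_bg = n_reads - n_planted
    rl = config.read_length

    chrom_idx = np.zeros(0, dtype=np.int64)
    starts = np.zeros(0, dtype=np.int64)
    if n_bg:
        chrom_idx, starts = _uniform_reads(layout, n_bg, rng, rl)
    if n_planted:
        widths = np.array([e - s for _, s, e in features], dtype=np.int64)
        fi = rng.choice(len(features), size=n_planted, p=widths / widths.sum())
        index = layout.index
        f_chrom = np.array([index[c] for c, _, _ in features], dtype=np.int64)
        f_start = np.array([s for _, s, _ in features], dtype=np.int64)
        # read fully inside the feature where the feature allows it
        span = np.maximum(widths[fi] - rl, 1)
        local = f_start[fi] + (rng.random(n_planted) * span).astype(np.int64)
        local = np.minimum(local, layout.lengths_array[f_chrom[fi]] - rl)
        chrom_idx = np.concatenate([chrom_idx, f_chrom[fi]])
        starts = np.concatenate([starts, local])

    starts = np.maximum(starts, 0)
    strand = rng.integers(0, 2, size=n_reads).astype(np.int8)
    order = np.lexsort((starts, chrom_idx))
    return TagCollection(
        layout,
        chrom_idx[order].astype(np.int32),
        starts[order],
        (starts + rl)[order],
        strand[order],
        sample=sample,
        mark=mark,
    )


def generate_reads(
    layout: GenomeLayout,
    genes: list[GeneModel],
    config: SimulationConfig,
    gene_states: Mapping[str, np.ndarray] | None = None,
) -> tuple[dict[tuple[str, str, int], TagCollection], GroundTruth]:
    """Simulate reads for every sample x mark x replicate.

    Returns the tag collections keyed by (sample, mark, replicate index) and
    the exported :class:`GroundTruth`. Replicates of one sample/mark share
    the planted features and differ by library size and read placement.
    """
    if config.enrichment_fold <= 1:
        raise ValueError("enrichment_fold must exceed 1")
    if gene_states is None:
        gene_states = assign_gene_states(genes, config)

    feature_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    tags: dict[tuple[str, str, int], TagCollection] = {}
    planted: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    for s_i, sample in enumerate(SAMPLES):
        states = gene_states[sample]
        for m_i, mark in enumerate(MARKS):
            feats = _planted_features(layout, genes, states, mark, config, feature_rng)
            planted[(sample, mark)] = feats
            for rep in range(config.n_replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 4, s_i, m_i, rep])
                )
                if config.reads_per_sample is not None:
                    mean = config.reads_per_sample
                else:
                    mean = config.background_rate * layout.total_length
                lib = max(1, int(round(rng.normal(mean, config.library_size_cv * mean))))
                tags[(sample, mark, rep)] = _sample_reads(
                    layout, feats, lib, config, rng, sample, mark
                )

    expr_truth = {
        g.gene_id: EXPRESSION_STATE_MEANS[st]
        for g, st in zip(genes, gene_states[REFERENCE_SAMPLE])
    }
    truth = GroundTruth(
        planted_islands=planted,
        gene_states={
            s: {g.gene_id: str(st) for g, st in zip(genes, gene_states[s])} for s in SAMPLES
        },
        expression_truth=expr_truth,
    )
    return tags, truth


def generate_expression(
    gene_states: Mapping[str, str] | pd.Series, config: SimulationConfig
) -> pd.Series:
    """Noisy log2 expression table for the reference sample's gene states.

    Active genes sit high, silent low, bivalent in between, with Gaussian
    noise of ``expression_noise_sd`` log2 units.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    items = list(gene_states.items())
    if not items:
        return pd.Series(dtype=float, name="expression")
    ids = [k for k, _ in items]
    means = np.array([EXPRESSION_STATE_MEANS[v] for _, v in items])
    noise = rng.normal(0.0, config.expression_noise_sd, size=len(items))
    return pd.Series(means + noise, index=pd.Index(ids, name="gene_id"), name="expression")


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    tags: dict[tuple[str, str, int], TagCollection]
    truth: GroundTruth
    expression: pd.Series


def simulate(config: SimulationConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full generator and optionally write all outputs to ``outdir``."""
    layout, genes = generate_genome(config)
    tags, truth = generate_reads(layout, genes, config)
    expression = generate_expression(truth.gene_states[REFERENCE_SAMPLE], config)
    result = SimResult(config, layout, genes, tags, truth, expression)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(layout, out / "genome.chrom.sizes")
        write_gene_models(genes, out / "genes.bed12")
        write_expression_table(expression, out / "expression.tsv")
        truth.to_json(out / "ground_truth.json")
        for (sample, mark, rep), t in tags.items():
            write_tags(t, out / f"{sample}.{mark}.rep{rep + 1}.bed")
    return result
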