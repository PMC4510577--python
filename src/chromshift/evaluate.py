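"""Scoring of pipeline output against the generator's planted ground truth.

Every analysis stage of the package can be exercised on synthetic data with
exported truth; this module houses the standard property studies used for
validation: false-call calibration of the island caller on pure background,
planted-domain recovery (per-island Jaccard), replicate-versus-condition
clustering fidelity, planted-bivalency recovery, and recovery of a planted
bivalent-retention fraction in the co-occupancy dynamics map.

Each ``*_study`` function builds its own study design, runs the actual
package code path end to end, and returns measured quantities; nothing in
here short-circuits the pipeline.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np

from .io import GenomeLayout, TagCollection, filter_redundant_tags, merge_replicates
from .islands import (
    BROAD_PARAMS,
    Island,
    IslandCallingParams,
    call_islands,
    count_windows,
    find_islands,
    score_significance,
)
from .bincluster import Dendrogram, bin_genome, normalize, ward_cluster
from .promoters import (
    bivalency_states,
    cooccupancy_dynamics,
    enriched_promoter_sets,
    promoter_windows,
)
from .sim import (
    MARKS,
    REFERENCE_SAMPLE,
    SAMPLES,
    SimulationConfig,
    generate_genome,
    generate_reads,
    simulate_background,
)

#: Island parameters for recovering ~1 kb focal peaks with high boundary
#: fidelity: 50 bp windows keep the grid-quantization of a 1 kb feature
#: under 10%, the 100 bp gap bridges single-window dropouts, and the strict
#: eligibility tail keeps background windows from extending island edges.
RECOVERY_FOCAL_PARAMS = IslandCallingParams(
    window_size=50, gap_size=100, eligibility_p0=0.01
)

#: Broad domains (>= 5 kb) tolerate 200 bp granularity; the 600 bp gap
#: bridges local dips inside a domain.
RECOVERY_BROAD_PARAMS = BROAD_PARAMS


# ---------------------------------------------------------------------------
# Primitive scores
# ---------------------------------------------------------------------------

def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def planted_recovery_jaccards(
    planted: Sequence[tuple[str, int, int]], islands: Sequence[Island]
) -> np.ndarray:
    """Best-overlap Jaccard of each planted interval against called islands."""
    by_chrom: dict[str, list[Island]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    out = np.zeros(len(planted))
    for i, (chrom, s, e) in enumerate(planted):
        best = 0.0
        for isl in by_chrom.get(chrom, []):
            if isl.end > s and isl.start < e:
                best = max(best, interval_jaccard((s, e), (isl.start, isl.end)))
        out[i] = best
    return out


def bivalency_confusion(
    truth_states: Mapping[str, str], called_bivalent: set[str]
) -> tuple[float, float]:
    """(sensitivity, precision) of bivalent calls against planted states."""
    truth_biv = {g for g, st in truth_states.items() if st == "bivalent"}
    tp = len(truth_biv & called_bivalent)
    sens = tp / len(truth_biv) if truth_biv else float("nan")
    prec = tp / len(called_bivalent) if called_bivalent else float("nan")
    return sens, prec


def replicate_pairs_first(dendrogram: Dendrogram, condition_of: Mapping[str, str]) -> bool:
    """True when the first merges are exactly the within-condition replicate pairs."""
    conditions = set(condition_of.values())
    n = len(dendrogram.labels)
    for i in range(len(conditions)):
        a, b = int(dendrogram.merges[i, 0]), int(dendrogram.merges[i, 1])
        if a >= n or b >= n:
            return False
        if condition_of[dendrogram.labels[a]] != condition_of[dendrogram.labels[b]]:
            return False
    return True


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

def calibration_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (2_500_000, 2_500_000))


def recovery_config(seed: int) -> SimulationConfig:
    """Sparse 5 Mb genome (100 genes) so planted features stay well separated."""
    return SimulationConfig(
        n_chroms=2, chrom_length=2_500_000, n_genes=100,
        reads_per_sample=200_000, n_replicates=1, enrichment_fold=8.0,
        min_gene_gap=12_000, seed=seed,
    )


def demo_config(seed: int) -> SimulationConfig:
    """The demo design: 5 Mb, 500 genes, 4 conditions x 2 marks x 2 replicates."""
    return SimulationConfig(seed=seed)


def bivalency_config(seed: int, bivalent_retention: float | None = None) -> SimulationConfig:
    """6 Mb, 200 genes spaced >= 12 kb so planted states are geometrically
    identifiable (no broad domain of one gene reaching a neighbour's promoter)."""
    return SimulationConfig(
        n_chroms=2, chrom_length=3_000_000, n_genes=200,
        reads_per_sample=60_000, n_replicates=2, enrichment_fold=8.0,
        min_gene_gap=12_000, bivalent_retention=bivalent_retention, seed=seed,
    )


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

def fdr_calibration_study(
    n_sims: int = 200,
    reads: int = 50_000,
    seed: int = 0,
    params: IslandCallingParams = BROAD_PARAMS,
) -> dict[str, float]:
    """Island false-call rate on pure background.

    Simulates ``n_sims`` uniform-background libraries on a 5 Mb genome,
    assembles candidate islands and counts how many survive the
    Benjamini-Hochberg filter; under the null the surviving fraction should
    not exceed the nominal FDR beyond binomial error.
    """
    layout = calibration_layout()
    candidates = 0
    passing = 0
    ss = np.random.SeedSequence([seed, 11])
    child_seeds = ss.generate_state(n_sims)
    for s in child_seeds:
        tags = simulate_background(layout, reads, int(s % (2**31)))
        windows = count_windows(tags, layout, params)
        cand = call_islands(windows, params, n_tags=len(tags))
        kept = score_significance(cand, params, n_tags=len(tags), layout=layout)
        candidates += len(cand)
        passing += len(kept)
    rate = passing / candidates if candidates else 0.0
    bound = params.fdr_threshold + 1.96 * np.sqrt(
        params.fdr_threshold * (1 - params.fdr_threshold) / max(candidates, 1)
    )
    return {
        "n_sims": n_sims, "candidates": candidates, "passing": passing,
        "rate": rate, "binomial_upper_bound": float(bound),
    }


def recovery_study(n_seeds: int = 20, base_seed: int = 0) -> dict[str, float]:
    """Median per-island Jaccard of planted focal and broad features."""
    jaccards: dict[str, list[float]] = {"H3K4me3": [], "H3K27me3": []}
    params = {"H3K4me3": RECOVERY_FOCAL_PARAMS, "H3K27me3": RECOVERY_BROAD_PARAMS}
    for i in range(n_seeds):
        cfg = recovery_config(seed=base_seed * 1000 + i)
        layout, genes = generate_genome(cfg)
        tags, truth = generate_reads(layout, genes, cfg)
        for mark in MARKS:
            t = filter_redundant_tags(
                tags[(REFERENCE_SAMPLE, mark, 0)], max_per_position=1
            )
            islands = find_islands(t, layout, params[mark])
            j = planted_recovery_jaccards(
                truth.planted_islands[(REFERENCE_SAMPLE, mark)], islands
            )
            jaccards[mark].extend(j.tolist())
    return {
        "focal_median_jaccard": float(np.median(jaccards["H3K4me3"])),
        "broad_median_jaccard": float(np.median(jaccards["H3K27me3"])),
        "n_focal": len(jaccards["H3K4me3"]),
        "n_broad": len(jaccards["H3K27me3"]),
    }


def replicate_profiles(
    tags: Mapping[tuple[str, str, int], TagCollection],
    layout: GenomeLayout,
    samples: Sequence[str],
    n_replicates: int,
    bin_size: int = 500,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """log2cpm bin profiles per replicate, rows stacked across both marks.

    Each condition replicate is one column characterized by its binned
    signal for both histone marks (each mark normalized by its own library
    size).
    """
    labels = [f"{s}.rep{r + 1}" for s in samples for r in range(n_replicates)]
    condition_of = {f"{s}.rep{r + 1}": s for s in samples for r in range(n_replicates)}
    blocks = []
    for mark in MARKS:
        collections = [tags[(s, mark, r)] for s in samples for r in range(n_replicates)]
        bm = normalize(bin_genome(collections, layout, bin_size, labels=labels), "log2cpm")
        blocks.append(bm.values)
    return np.vstack(blocks), labels, condition_of


def clustering_study(n_seeds: int = 20, base_seed: int = 0) -> dict[str, float]:
    """Fraction of seeds in which Ward joins every replicate pair before any
    cross-condition merge.

    One dendrogram per seed over the 4 conditions x 2 replicates, each
    replicate profiled by its 500 bp log2cpm bins across both marks.
    """
    from scipy.cluster.hierarchy import linkage

    successes = 0
    for i in range(n_seeds):
        cfg = demo_config(seed=base_seed * 1000 + i)
        layout, genes = generate_genome(cfg)
        tags, _ = generate_reads(layout, genes, cfg)
        X, labels, condition_of = replicate_profiles(
            tags, layout, SAMPLES, cfg.n_replicates
        )
        dend = Dendrogram(linkage(X.T, method="ward"), labels)
        successes += replicate_pairs_first(dend, condition_of)
    return {"n_seeds": n_seeds, "successes": successes, "rate": successes / n_seeds}


def _called_states(cfg: SimulationConfig, samples: Sequence[str]):
    """Run the island -> enrichment-set -> state path for the given samples."""
    layout, genes = generate_genome(cfg)
    tags, truth = generate_reads(layout, genes, cfg)
    windows = promoter_windows(genes, layout)
    params = {"H3K4me3": IslandCallingParams(window_size=200, gap_size=200),
              "H3K27me3": BROAD_PARAMS}
    islands = {}
    for sample in samples:
        for mark in MARKS:
            merged = filter_redundant_tags(
                merge_replicates([tags[(sample, mark, r)] for r in range(cfg.n_replicates)])
            )
            islands[(sample, mark)] = find_islands(merged, layout, params[mark])
    k4 = enriched_promoter_sets({s: islands[(s, "H3K4me3")] for s in samples}, windows)
    k27 = enriched_promoter_sets({s: islands[(s, "H3K27me3")] for s in samples}, windows)
    states = bivalency_states(k4, k27, [g.gene_id for g in genes])
    return states, truth


def bivalency_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> dict[str, float]:
    """Median sensitivity/precision of planted-bivalent recovery (reference sample)."""
    sens_list, prec_list = [], []
    for i in range(n_seeds):
        cfg = bivalency_config(seed=base_seed * 1000 + i)
        states, truth = _called_states(cfg, [REFERENCE_SAMPLE])
        called = set(states.index[states[REFERENCE_SAMPLE] == "bivalent"])
        sens, prec = bivalency_confusion(truth.gene_states[REFERENCE_SAMPLE], called)
        sens_list.append(sens)
        prec_list.append(prec)
    return {
        "n_seeds": n_seeds,
        "median_sensitivity": float(np.median(sens_list)),
        "median_precision": float(np.median(prec_list)),
    }


def retention_study(
    retention: float, n_seeds: int = 5, base_seed: int = 0
) -> dict[str, float]:
    """Recovered retained-bivalent fraction when the generator plants one.

    The generator keeps ``retention`` of reference-bivalent genes bivalent in
    every other condition; the pipeline's co-occupancy dynamics map should
    report a retained fraction close to it for the reference -> STF pair.
    """
    measured = []
    for i in range(n_seeds):
        cfg = bivalency_config(seed=base_seed * 1000 + i, bivalent_retention=retention)
        states, _ = _called_states(cfg, [REFERENCE_SAMPLE, "STF"])
        cmap = cooccupancy_dynamics(states)
        measured.append(cmap.retained_fraction[(REFERENCE_SAMPLE, "STF")])
    return {
        "planted": retention,
        "n_seeds": n_seeds,
        "median_retained_fraction": float(np.median(measured)),
    }
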