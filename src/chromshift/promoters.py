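"""Promoter-level mark quantification, enrichment sets, bivalency, dynamics.

Promoters are strand-oriented windows from -1000 bp to +500 bp around each
TSS. Anchored reads are counted per window and library-normalized; a
promoter is *enriched* for a mark when its window overlaps a significant
island by at least 1 bp (optionally a minimum overlap fraction). The
four-way state per gene and sample — none / K4only / K27only / bivalent —
is exactly the set algebra of the two per-mark enrichment sets; a promoter
carrying both H3K4me3 and H3K27me3 is *bivalent*. Co-occupancy dynamics
restrict to genes bivalent in at least one sample and tally, per sample
pair, how reference-bivalent promoters resolve (retained bivalent, resolved
to K4, resolved to K27, lost).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_FRAGMENT_SHIFT, GeneModel, GenomeLayout, TagCollection
from .islands import Island

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500

BIVALENCY_STATES = ("none", "K4only", "K27only", "bivalent")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented promoter interval of one transcript."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def promoter_windows(
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[PromoterWindow]:
    """Windows covering [-upstream, +downstream) around each TSS.

    A '+' strand gene with TSS t gets [t-1000, t+500); a '-' strand gene the
    reflected [t-499, t+1001). Windows are clipped to chromosome bounds.
    """
    windows = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
        else:
            s, e = g.tss - downstream + 1, g.tss + upstream + 1
        s = max(0, s)
        e = min(layout.length_of(g.chrom), e)
        windows.append(PromoterWindow(g.gene_id, g.chrom, int(s), int(e), g.strand))
    return windows


def count_promoter_reads(
    tags: TagCollection,
    windows: Sequence[PromoterWindow],
    shift: int = DEFAULT_FRAGMENT_SHIFT,
    normalize: bool = False,
) -> pd.Series:
    """Anchored-read counts per promoter window (cpm when ``normalize``)."""
    anchors = tags.anchors(shift) if len(tags) else np.zeros(0, dtype=np.int64)
    index = tags.layout.index
    by_chrom: dict[int, np.ndarray] = {}
    for ci in np.unique(tags.chrom):
        by_chrom[int(ci)] = np.sort(anchors[tags.chrom == ci])
    counts = np.zeros(len(windows), dtype=np.float64)
    for i, w in enumerate(windows):
        pos = by_chrom.get(index[w.chrom])
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, w.end) - np.searchsorted(pos, w.start)
    if normalize and len(tags):
        counts = counts * 1e6 / len(tags)
    return pd.Series(counts, index=pd.Index([w.gene_id for w in windows], name="gene_id"))


def promoter_log2fc(
    counts_a: pd.Series,
    counts_b: pd.Series,
    pseudocount: float = 1.0,
    expression_a: pd.Series | None = None,
    expression_b: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2((cpm_a + c) / (cpm_b + c)), ranked descending.

    ``counts_a``/``counts_b`` must be cpm-normalized; the pseudocount bounds
    fold changes for zero-count promoters. When both expression tables are
    given, the analogous expression log2FC is carried alongside (gene
    identity preserved).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not counts_a.index.equals(counts_b.index):
        counts_b = counts_b.reindex(counts_a.index)
        if counts_b.isna().any():
            raise ValueError("gene sets of the two samples differ")
    lfc = np.log2((counts_a + pseudocount) / (counts_b + pseudocount))
    df = pd.DataFrame({"log2fc": lfc})
    if expression_a is not None and expression_b is not None:
        ea = expression_a.reindex(df.index)
        eb = expression_b.reindex(df.index)
        df["expression_log2fc"] = ea - eb  # expression tables are log2 scale
    df = df.sort_values(["log2fc"], ascending=False, kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def enriched_promoter_sets(
    islands_by_sample: Mapping[str, Sequence[Island]],
    windows: Sequence[PromoterWindow],
    min_overlap_frac: float = 0.0,
) -> dict[str, set[str]]:
    """Per-sample sets of promoters overlapping >=1 significant island.

    Enrichment requires at least 1 bp of overlap, or at least
    ``min_overlap_frac`` of the window when that is positive. With multiple
    windows per gene (multiple annotated TSSs), any enriched transcript
    window marks the gene.
    """
    out: dict[str, set[str]] = {}
    for sample, islands in islands_by_sample.items():
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[Island]] = {}
        for isl in islands:
            grouped.setdefault(isl.chrom, []).append(isl)
        for chrom, isls in grouped.items():
            isls.sort(key=lambda x: x.start)
            by_chrom[chrom] = (
                np.array([i.start for i in isls], dtype=np.int64),
                np.array([i.end for i in isls], dtype=np.int64),
            )
        enriched: set[str] = set()
        for w in windows:
            if w.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[w.chrom]
            # disjoint sorted islands: candidates whose start precedes w.end
            hi = np.searchsorted(starts, w.end)
            lo = np.searchsorted(ends, w.start, side="right")
            if lo >= hi:
                continue
            overlap = int(
                np.sum(np.minimum(ends[lo:hi], w.end) - np.maximum(starts[lo:hi], w.start))
            )
            need = max(1, int(np.ceil(min_overlap_frac * (w.end - w.start))))
            if overlap >= need:
                enriched.add(w.gene_id)
        out[sample] = enriched
    return out


def venn_partition(sets: Mapping[str, set[str]]) -> dict[tuple[bool, ...], int]:
    """Counts of every membership combination across the given sample sets.

    Keys are membership tuples in the order of ``sets``; the all-False cell
    is omitted. Cells are disjoint and sum to the union cardinality.
    """
    names = list(sets)
    union: set[str] = set().union(*sets.values()) if sets else set()
    partition: dict[tuple[bool, ...], int] = {
        combo: 0
        for combo in itertools.product([False, True], repeat=len(names))
        if any(combo)
    }
    for g in union:
        combo = tuple(g in sets[n] for n in names)
        partition[combo] += 1
    return partition


def bivalency_states(
    k4_sets: Mapping[str, set[str]],
    k27_sets: Mapping[str, set[str]],
    all_genes: Iterable[str],
) -> pd.DataFrame:
    """Four-way promoter state per gene x sample.

    bivalent <=> in both the K4 and K27 enrichment set of that sample; no
    independent thresholding enters.
    """
    samples = list(k4_sets)
    if list(k27_sets) != samples:
        raise ValueError("K4 and K27 sets must cover the same samples")
    genes = list(all_genes)
    data = {}
    for s in samples:
        k4, k27 = k4_sets[s], k27_sets[s]
        data[s] = [
            "bivalent" if (g in k4 and g in k27)
            else "K4only" if g in k4
            else "K27only" if g in k27
            else "none"
            for g in genes
        ]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def state_counts(states: pd.DataFrame) -> pd.DataFrame:
    """Per-sample counts of each of the four states (columns sum to n genes)."""
    return pd.DataFrame(
        {s: states[s].value_counts().reindex(BIVALENCY_STATES, fill_value=0)
         for s in states.columns}
    )


@dataclass
class CooccupancyMap:
    """Bivalency co-occupancy dynamics across samples.

    ``states`` is restricted to genes bivalent in >=1 sample (each row has at
    least one bivalent entry). ``transitions[(a, b)]`` tallies, over genes
    bivalent in sample ``a``, their state in sample ``b`` as retained /
    resolved_K4 / resolved_K27 / lost; ``retained_fraction[(a, b)]`` is the
    retained share.
    """

    states: pd.DataFrame
    bivalent_counts: pd.Series
    transitions: dict[tuple[str, str], dict[str, int]]
    retained_fraction: dict[tuple[str, str], float]


TRANSITION_CLASSES = {
    "bivalent": "retained",
    "K4only": "resolved_K4",
    "K27only": "resolved_K27",
    "none": "lost",
}


def cooccupancy_dynamics(states: pd.DataFrame) -> CooccupancyMap:
    """Build the co-occupancy dynamics map from per-sample state assignments."""
    if states.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    ever_bivalent = (states == "bivalent").any(axis=1)
    sub = states.loc[ever_bivalent]
    bivalent_counts = (states == "bivalent").sum(axis=0)

    transitions: dict[tuple[str, str], dict[str, int]] = {}
    retained: dict[tuple[str, str], float] = {}
    samples = list(states.columns)
    for a in samples:
        for b in samples:
            if a == b:
                continue
            biv_a = sub.index[sub[a] == "bivalent"]
            tally = {"retained": 0, "resolved_K4": 0, "resolved_K27": 0, "lost": 0}
            for st in sub.loc[biv_a, b]:
                tally[TRANSITION_CLASSES[st]] += 1
            transitions[(a, b)] = tally
            retained[(a, b)] = (
                tally["retained"] / len(biv_a) if len(biv_a) else float("nan")
            )
    return CooccupancyMap(sub, bivalent_counts, transitions, retained)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_states(states: pd.DataFrame, path: str | Path) -> None:
    states.to_csv(path, sep="\t")


def write_venn(partition: Mapping[tuple[bool, ...], int], names: Sequence[str],
               path: str | Path) -> None:
    obj = {
        "+".join(n for n, m in zip(names, combo) if m): count
        for combo, count in partition.items()
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def write_transitions(cmap: CooccupancyMap, path: str | Path) -> None:
    rows = []
    for (a, b), tally in cmap.transitions.items():
        rows.append(
            {"from": a, "to": b, **tally, "retained_fraction": cmap.retained_fraction[(a, b)]}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
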