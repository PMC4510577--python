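"""SICER-style enriched-island calling under a Poisson background.

The genome is tiled with non-overlapping ``w``-bp windows; anchored reads are
counted per window. A window is *eligible* when its count reaches the smallest
integer ``l0`` whose Poisson upper tail (at the genome-wide background rate
``lambda = n_tags * w / effective_genome_length``) falls below ``p0``. An
*island* is a maximal run of eligible windows in which consecutive eligible
windows are separated by at most ``g`` bp of ineligible windows; the
ineligible gap windows are included in the island span. The island score is
the sum over eligible windows of ``-ln P(X = count; lambda)``; island
significance is the Poisson upper tail of the island's total read count given
the background expectation over its span, corrected genome-wide with
Benjamini-Hochberg.

A small gap (``g = w``) suits focal marks such as H3K4me3; a larger gap
(``g = 3w``) bridges the local dips inside multi-kilobase broad domains
(BLOCs) typical of H3K27me3. No control/input library is assumed; an optional
control mode replaces the background expectation by the scaled control count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .io import DEFAULT_FRAGMENT_SHIFT, GenomeLayout, TagCollection

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandCallingParams:
    """Window/gap geometry and significance thresholds for island calling.

    window_size
        Tiling window width in bp (w).
    gap_size
        Maximum ineligible gap bridged within an island, in bp; must be a
        multiple of ``window_size`` (0 disables gap bridging).
    eligibility_p0
        Poisson upper-tail probability below which a window count becomes
        eligible.
    fdr_threshold
        Benjamini-Hochberg q-value cutoff for reported islands.
    effective_genome_fraction
        Fraction of the genome assumed mappable when computing the background
        rate.
    """

    window_size: int = 200
    gap_size: int = 200
    eligibility_p0: float = 0.2
    fdr_threshold: float = 0.01
    effective_genome_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.gap_size < 0 or self.gap_size % self.window_size != 0:
            raise ValueError("gap_size must be a non-negative multiple of window_size")
        if not 0 < self.eligibility_p0 < 1:
            raise ValueError("eligibility_p0 must be in (0, 1)")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")


#: Conventional parameterizations for focal (H3K4me3-like) and broad
#: (H3K27me3-like) marks.
FOCAL_PARAMS = IslandCallingParams(window_size=200, gap_size=200)
BROAD_PARAMS = IslandCallingParams(window_size=200, gap_size=600)


@dataclass
class WindowVector:
    """Per-chromosome arrays of read counts in non-overlapping windows."""

    layout: GenomeLayout
    window_size: int
    counts: list[np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts))

    def n_windows(self, chrom_index: int) -> int:
        return len(self.counts[chrom_index])


@dataclass
class Island:
    """A called enriched region.

    ``score`` is in -ln-probability units; ``p_value``/``fdr_q`` are filled by
    :func:`score_significance`.
    """

    chrom: str
    start: int
    end: int
    read_count: int
    score: float
    p_value: float = float("nan")
    fdr_q: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def count_windows(
    tags: TagCollection,
    layout: GenomeLayout,
    params: IslandCallingParams,
    shift: int = DEFAULT_FRAGMENT_SHIFT,
) -> WindowVector:
    """Count anchored reads per window; each read increments exactly one window."""
    w = params.window_size
    anchors = tags.anchors(shift) if len(tags) else np.zeros(0, dtype=np.int64)
    counts = []
    for ci, length in enumerate(layout.lengths):
        n_win = -(-length // w)
        pos = anchors[tags.chrom == ci]
        counts.append(np.bincount(pos // w, minlength=n_win).astype(np.int64))
    return WindowVector(layout, w, counts)


def background_lambda(n_tags: int, effective_genome_length: float, window_size: int) -> float:
    """Genome-wide Poisson rate per window."""
    if effective_genome_length <= 0:
        raise ValueError("effective genome length must be positive")
    lam = n_tags * window_size / effective_genome_length
    if lam <= 0:
        raise ValueError("background rate must be positive (no tags?)")
    return lam


def eligibility_threshold(
    n_tags: int, effective_genome_length: float, params: IslandCallingParams
) -> int:
    """Smallest integer l0 with Poisson upper tail P(X >= l0; lambda) < p0.

    Always at least 1, so zero-count windows are never eligible.
    """
    if n_tags <= 0:
        raise ValueError("n_tags must be positive")
    lam = background_lambda(n_tags, effective_genome_length, params.window_size)
    # P(X >= l0) = poisson.sf(l0 - 1); increase l0 until the tail drops below p0
    l0 = 1
    while poisson.sf(l0 - 1, lam) >= params.eligibility_p0:
        l0 += 1
    return l0


def call_islands(
    windows: WindowVector, params: IslandCallingParams, n_tags: int
) -> list[Island]:
    """Assemble maximal gap-bridged runs of eligible windows into islands.

    Islands begin and end on eligible windows; interior ineligible windows
    (within the gap allowance) contribute their reads to ``read_count`` but
    not to ``score``. Islands are disjoint and separated by more than
    ``gap_size`` of ineligible windows.
    """
    egl = params.effective_genome_fraction * windows.layout.total_length
    lam = background_lambda(n_tags, egl, params.window_size)
    l0 = eligibility_threshold(n_tags, egl, params)
    w = params.window_size
    gap_w = params.gap_size // w

    islands: list[Island] = []
    for ci, counts in enumerate(windows.counts):
        chrom = windows.layout.names[ci]
        chrom_len = windows.layout.lengths[ci]
        eligible = np.flatnonzero(counts >= l0)
        if eligible.size == 0:
            continue
        # split runs where consecutive eligible windows are > gap_w apart
        breaks = np.flatnonzero(np.diff(eligible) > gap_w + 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [eligible.size - 1]))
        cum = np.concatenate(([0], np.cumsum(counts)))
        logpmf_cache: dict[int, float] = {}
        for rs, re_ in zip(run_starts, run_ends):
            first, last = int(eligible[rs]), int(eligible[re_])
            total = int(cum[last + 1] - cum[first])
            score = 0.0
            for k in map(int, counts[eligible[rs : re_ + 1]]):
                if k not in logpmf_cache:
                    logpmf_cache[k] = float(poisson.logpmf(k, lam))
                score -= logpmf_cache[k]
            islands.append(
                Island(
                    chrom=chrom,
                    start=first * w,
                    end=min((last + 1) * w, chrom_len),
                    read_count=total,
                    score=score,
                )
            )
    return islands


def score_significance(
    islands: Sequence[Island],
    params: IslandCallingParams,
    n_tags: int,
    layout: GenomeLayout,
    control: WindowVector | None = None,
    control_n_tags: int | None = None,
) -> list[Island]:
    """Fill p-values and BH q-values; drop islands with q >= fdr_threshold.

    No-control mode: the expectation for an island spanning ``k`` windows is
    ``k * lambda`` (a truncated terminal window still counts as one standard
    window in the expectation — a documented approximation). Control mode:
    the expectation is the library-size-scaled control count over the same
    span (floored at one standard window's background rate to avoid zero
    expectations).
    """
    if not islands:
        return []
    w = params.window_size
    egl = params.effective_genome_fraction * layout.total_length
    lam = background_lambda(n_tags, egl, w)

    expectations = np.empty(len(islands))
    for i, isl in enumerate(islands):
        n_win = -(-(isl.end - isl.start) // w)
        if control is None:
            expectations[i] = lam * n_win
        else:
            if control.layout != layout or control.window_size != w:
                raise ValueError("control WindowVector layout/window mismatch")
            if control_n_tags is None:
                control_n_tags = control.total
            ci = layout.index[isl.chrom]
            ctrl = control.counts[ci][isl.start // w : (isl.end + w - 1) // w].sum()
            expectations[i] = max(ctrl * n_tags / control_n_tags, lam)

    counts = np.array([isl.read_count for isl in islands])
    pvals = poisson.sf(counts - 1, expectations)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    out = []
    for isl, p, q in zip(islands, pvals, qvals):
        if q < params.fdr_threshold:
            out.append(replace(isl, p_value=float(p), fdr_q=float(q)))
    return out


def find_islands(
    tags: TagCollection,
    layout: GenomeLayout,
    params: IslandCallingParams,
    shift: int = DEFAULT_FRAGMENT_SHIFT,
) -> list[Island]:
    """End-to-end: count windows, assemble candidate islands, score and filter."""
    windows = count_windows(tags, layout, params, shift=shift)
    candidates = call_islands(windows, params, n_tags=len(tags))
    return score_significance(candidates, params, n_tags=len(tags), layout=layout)


def genome_fraction_covered(islands: Sequence[Island], layout: GenomeLayout) -> float:
    """Total island length / total genome length. Islands must be disjoint."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    covered = 0
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping islands on {chrom}: [{s1},{e1}) and [{s2},{e2})")
        covered += sum(e - s for s, e in ivals)
    return covered / layout.total_length


def write_islands(islands: Sequence[Island], path: str | Path) -> None:
    """BED6+ output: chrom, start, end, name, score, strand, read_count, p, q."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands, start=1):
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland_{i}\t"
                f"{isl.score:.4f}\t.\t{isl.read_count}\t{isl.p_value:.6g}\t{isl.fdr_q:.6g}\n"
            )


def read_islands(path: str | Path) -> list[Island]:
    islands = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        islands.append(
            Island(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                score=float(f[4]),
                read_count=int(f[6]),
                p_value=float(f[7]),
                fdr_q=float(f[8]),
            )
        )
    return islands
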