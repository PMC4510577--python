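"""Genome-wide fixed-bin quantification, replicate QC and Ward clustering.

The entire genome is partitioned into fixed-width bins (500 bp by default)
and anchored reads are counted per bin per sample. Counts are library-size
normalized (cpm, optionally log2(cpm+1)); replicate agreement is assessed by
Pearson correlation of the log2cpm columns and between-sample structure by
unsupervised hierarchical clustering with Ward's minimum-variance linkage on
Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .io import DEFAULT_FRAGMENT_SHIFT, GenomeLayout, TagCollection


@dataclass
class BinMatrix:
    """bins x samples matrix of per-bin read counts (or normalized values)."""

    layout: GenomeLayout
    bin_size: int
    chrom: np.ndarray  # per-bin chromosome index
    start: np.ndarray
    end: np.ndarray
    values: np.ndarray  # (n_bins, n_samples)
    samples: list[str]
    library_sizes: np.ndarray
    norm: str = "raw"

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[0])

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.layout.names, dtype=object)
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "chrom", names[self.chrom])
        df.insert(1, "start", self.start)
        df.insert(2, "end", self.end)
        return df


def bin_genome(
    collections: Sequence[TagCollection],
    layout: GenomeLayout,
    bin_size: int = 500,
    shift: int = DEFAULT_FRAGMENT_SHIFT,
    labels: Sequence[str] | None = None,
) -> BinMatrix:
    """Raw per-bin anchored-read counts for each collection.

    Bins tile every chromosome from 0; the final per-chromosome bin is
    truncated at the chromosome end. Column sums equal library sizes.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if labels is None:
        labels = [
            c.sample if c.sample is not None else f"sample{i}"
            for i, c in enumerate(collections)
        ]
    n_bins_per_chrom = [-(-length // bin_size) for length in layout.lengths]
    offsets = np.concatenate(([0], np.cumsum(n_bins_per_chrom)))
    n_bins = int(offsets[-1])

    chrom = np.concatenate(
        [np.full(nb, ci, dtype=np.int32) for ci, nb in enumerate(n_bins_per_chrom)]
    )
    start = np.concatenate(
        [np.arange(nb, dtype=np.int64) * bin_size for nb in n_bins_per_chrom]
    )
    end = np.minimum(start + bin_size, layout.lengths_array[chrom])

    values = np.zeros((n_bins, len(collections)), dtype=np.int64)
    lib = np.zeros(len(collections), dtype=np.int64)
    for j, tags in enumerate(collections):
        if len(tags) == 0:
            raise ValueError(f"sample {labels[j]!r} has zero tags; cannot normalize")
        anchors = tags.anchors(shift)
        flat = offsets[tags.chrom] + anchors // bin_size
        values[:, j] = np.bincount(flat, minlength=n_bins)
        lib[j] = len(tags)
    return BinMatrix(layout, bin_size, chrom, start, end, values, list(labels), lib, "raw")


def normalize(matrix: BinMatrix, mode: str = "log2cpm") -> BinMatrix:
    """cpm = count * 1e6 / library size; log2cpm = log2(cpm + 1)."""
    if matrix.norm != "raw":
        raise ValueError(f"matrix already normalized ({matrix.norm})")
    if mode not in ("cpm", "log2cpm"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    cpm = matrix.values * (1e6 / matrix.library_sizes)
    values = np.log2(cpm + 1.0) if mode == "log2cpm" else cpm
    return replace(matrix, values=values, norm=mode)


def sample_correlation(matrix: BinMatrix, method: str = "pearson") -> pd.DataFrame:
    """Symmetric between-sample correlation matrix with unit diagonal."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.values
    if np.any(X.std(axis=0) == 0):
        bad = [s for s, sd in zip(matrix.samples, X.std(axis=0)) if sd == 0]
        raise ValueError(f"constant column(s): correlation undefined for {bad}")
    if method == "pearson":
        corr = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        ranks = np.apply_along_axis(lambda c: pd.Series(c).rank().to_numpy(), 0, X)
        corr = np.corrcoef(ranks, rowvar=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)


@dataclass
class Dendrogram:
    """Agglomerative merge list in scipy linkage form plus leaf labels."""

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        n = len(self.labels)

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            a, b, h, _ = self.merges[node - n]
            return f"({render(int(a))},{render(int(b))}):{h:.6g}"

        return render(2 * n - 2) + ";"

    def leaf_partitions(self) -> list[frozenset[str]]:
        """The set of leaves under each internal node (topology fingerprint)."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for i, (a, b, _, _) in enumerate(self.merges):
            members[n + i] = members[int(a)] | members[int(b)]
            out.append(members[n + i])
        return out


def ward_cluster(matrix: BinMatrix) -> Dendrogram:
    """Ward minimum-variance hierarchical clustering of samples.

    Samples are points in bin space (Euclidean distance on log2cpm columns);
    merges greedily minimize the within-cluster variance increase.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.norm == "raw":
        raise ValueError("cluster on normalized (log2cpm) values, not raw counts")
    Z = linkage(matrix.values.T, method="ward")
    return Dendrogram(Z, list(matrix.samples))


def write_bin_matrix(matrix: BinMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def write_correlation(corr: pd.DataFrame, path: str | Path) -> None:
    corr.to_csv(path, sep="\t")


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")
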