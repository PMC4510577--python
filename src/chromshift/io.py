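"""Genomic file IO and tag (aligned read) handling.

All coordinates are 0-based, half-open (BED convention), everywhere. The raw
substrate of every counting operation is a :class:`TagCollection`: per-sample
aligned-read records held as numpy arrays for vectorised downstream counting.

Formats handled here: ``chrom.sizes`` (two-column text), BED3/BED6 reads,
BED12 gene models, bedGraph tracks, TSV expression tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chromshift")

#: 5' end shifted this many bp toward 3' approximates the fragment midpoint
#: for unpaired ChIP-seq reads (half of a ~146 bp nucleosomal fragment).
DEFAULT_FRAGMENT_SHIFT = 73

#: Simulated/assumed sequencing read length in bp.
DEFAULT_READ_LENGTH = 36

STRAND_SYMBOLS = ("+", "-")


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names in layout")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.names) != len(self.lengths):
            raise ValueError("names/lengths mismatch")

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __len__(self) -> int:
        return len(self.names)

    def length_of(self, name: str) -> int:
        return self.lengths[self.index[name]]

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=np.int64)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a two-column whitespace-delimited chrom.sizes file.

    File order is preserved. Duplicate names, non-positive lengths and
    malformed lines are errors. An empty file yields an empty (valid) layout.
    """
    names: list[str] = []
    lengths: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            length = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
        if length <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive length for {parts[0]}")
        names.append(parts[0])
        lengths.append(length)
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.names, layout.lengths):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Tag collections
# ---------------------------------------------------------------------------

@dataclass
class TagCollection:
    """Aligned-read records for one sample/mark, as parallel numpy arrays.

    ``chrom`` holds integer indices into ``layout.names``; ``strand`` is 0 for
    '+' and 1 for '-'.
    """

    layout: GenomeLayout
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    sample: str | None = None
    mark: str | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=np.int8)

    def __len__(self) -> int:
        return int(self.chrom.shape[0])

    def validate(self) -> None:
        if len(self) == 0:
            return
        lens = self.layout.lengths_array
        if self.chrom.min() < 0 or self.chrom.max() >= len(self.layout):
            raise ValueError("chromosome index out of range")
        bad = (self.start < 0) | (self.start >= self.end) | (self.end > lens[self.chrom])
        if bad.any():
            raise ValueError(f"{int(bad.sum())} records violate coordinate invariants")

    def five_prime(self) -> np.ndarray:
        """Strand-resolved 5' end of each read (a genomic position)."""
        return np.where(self.strand == 0, self.start, self.end - 1)

    def anchors(self, shift: int = DEFAULT_FRAGMENT_SHIFT) -> np.ndarray:
        """Genomic anchor used for counting: 5' end shifted toward 3'.

        Clipped to chromosome bounds so every read contributes exactly once.
        """
        pos = self.five_prime() + np.where(self.strand == 0, shift, -shift)
        upper = self.layout.lengths_array[self.chrom] - 1
        return np.clip(pos, 0, upper)

    def sorted(self) -> "TagCollection":
        order = np.lexsort((self.strand, self.end, self.start, self.chrom))
        return replace(
            self,
            chrom=self.chrom[order],
            start=self.start[order],
            end=self.end[order],
            strand=self.strand[order],
        )

    def subset(self, mask: np.ndarray) -> "TagCollection":
        return replace(
            self,
            chrom=self.chrom[mask],
            start=self.start[mask],
            end=self.end[mask],
            strand=self.strand[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.layout.names, dtype=object)
        return pd.DataFrame(
            {
                "chrom": names[self.chrom],
                "start": self.start,
                "end": self.end,
                "strand": np.asarray(STRAND_SYMBOLS, dtype=object)[self.strand],
            }
        )


def empty_tags(layout: GenomeLayout, sample: str | None = None, mark: str | None = None) -> TagCollection:
    z = np.zeros(0, dtype=np.int64)
    return TagCollection(layout, z, z, z, z, sample=sample, mark=mark)


def read_tags(
    path: str | Path,
    layout: GenomeLayout,
    sample: str | None = None,
    mark: str | None = None,
    max_reject_frac: float = 0.01,
) -> TagCollection:
    """Read aligned reads from BED6 (or BED3; strand then defaults to '+').

    Records on unknown chromosomes or outside chromosome bounds are rejected
    and counted; the run aborts if more than ``max_reject_frac`` of records
    are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return empty_tags(layout, sample, mark)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    chrom_names = df.iloc[:, 0].to_numpy(dtype=object)
    start = df.iloc[:, 1].to_numpy(dtype=np.int64)
    end = df.iloc[:, 2].to_numpy(dtype=np.int64)
    if df.shape[1] >= 6:
        strand = np.where(df.iloc[:, 5].to_numpy(dtype=object) == "-", 1, 0).astype(np.int8)
    else:
        strand = np.zeros(len(df), dtype=np.int8)

    index = layout.index
    chrom = np.array([index.get(c, -1) for c in chrom_names], dtype=np.int32)
    lens = layout.lengths_array
    known = chrom >= 0
    ok = known.copy()
    ok[known] &= (start[known] >= 0) & (start[known] < end[known]) & (
        end[known] <= lens[chrom[known]]
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d/%d records", path, n_rejected, len(ok))
        if n_rejected > max_reject_frac * len(ok):
            raise ValueError(
                f"{path}: {n_rejected}/{len(ok)} records rejected "
                f"(> {max_reject_frac:.0%} threshold)"
            )
    logger.info("%s: read %d tags", path, int(ok.sum()))
    return TagCollection(
        layout, chrom[ok], start[ok], end[ok], strand[ok], sample=sample, mark=mark
    )


def write_tags(tags: TagCollection, path: str | Path) -> None:
    """Write a TagCollection as BED6 (name='.', score=0)."""
    names = np.asarray(tags.layout.names, dtype=object)
    strands = np.asarray(STRAND_SYMBOLS, dtype=object)
    with open(path, "w") as fh:
        for c, s, e, st in zip(tags.chrom, tags.start, tags.end, tags.strand):
            fh.write(f"{names[c]}\t{s}\t{e}\t.\t0\t{strands[st]}\n")


def merge_replicates(collections: Sequence[TagCollection]) -> TagCollection:
    """Concatenate replicate TagCollections of the same sample and mark."""
    if not collections:
        raise ValueError("no collections to merge")
    first = collections[0]
    for c in collections[1:]:
        if (c.sample, c.mark) != (first.sample, first.mark):
            raise ValueError(
                f"label mismatch: ({c.sample},{c.mark}) vs ({first.sample},{first.mark})"
            )
        if c.layout != first.layout:
            raise ValueError("layout mismatch between replicates")
    return TagCollection(
        first.layout,
        np.concatenate([c.chrom for c in collections]),
        np.concatenate([c.start for c in collections]),
        np.concatenate([c.end for c in collections]),
        np.concatenate([c.strand for c in collections]),
        sample=first.sample,
        mark=first.mark,
    )


def filter_redundant_tags(tags: TagCollection, max_per_position: int = 1) -> TagCollection:
    """Keep at most ``max_per_position`` reads per (chrom, 5' position, strand).

    The result is independent of input order (records are sorted first).
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    if len(tags) == 0:
        return tags
    t = tags.sorted()
    five = t.five_prime()
    keys = np.stack([t.chrom.astype(np.int64), five, t.strand.astype(np.int64)])
    # group boundaries on the sorted key triple
    new_group = np.ones(len(t), dtype=bool)
    same = np.all(keys[:, 1:] == keys[:, :-1], axis=0)
    new_group[1:] = ~same
    group_id = np.cumsum(new_group) - 1
    # rank within group
    group_starts = np.flatnonzero(new_group)
    rank = np.arange(len(t)) - group_starts[group_id]
    return t.subset(rank < max_per_position)


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One transcript model with strand-resolved TSS/TES.

    ``exon_starts``/``exon_ends`` are absolute genomic coordinates.
    ``thick_start``/``thick_end`` delimit the CDS; exonic sequence 5' of the
    CDS is the 5'UTR and 3' of it the 3'UTR.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    thick_start: int
    thick_end: int

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: txStart must be < txEnd")
        if self.strand not in STRAND_SYMBOLS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside transcript")

    @property
    def tss(self) -> int:
        """Transcription start site: txStart on '+', txEnd-1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


def read_gene_models(path: str | Path, layout: GenomeLayout | None = None) -> list[GeneModel]:
    """Read transcript models from BED12."""
    genes: list[GeneModel] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
            raise ValueError(f"{path}:{lineno}: blockCount mismatch")
        ex_starts = tuple(start + o for o in offsets)
        ex_ends = tuple(s + sz for s, sz in zip(ex_starts, sizes))
        if layout is not None:
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if end > layout.length_of(chrom):
                raise ValueError(f"{path}:{lineno}: {name} extends past {chrom} end")
        genes.append(
            GeneModel(name, chrom, strand, start, end, ex_starts, ex_ends, thick_start, thick_end)
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offsets = ",".join(str(s - g.tx_start) for s in g.exon_starts)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.thick_start}\t{g.thick_end}\t0\t{len(g.exon_starts)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Tracks and tables
# ---------------------------------------------------------------------------

def make_track(tags: TagCollection, layout: GenomeLayout, window: int = 200) -> pd.DataFrame:
    """Fixed-width read-count track (bedGraph rows, zero windows omitted).

    A read is assigned to the window containing its 5' end. Windows tile each
    chromosome from 0; the last window is truncated at the chromosome end.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    five = tags.five_prime() if len(tags) else np.zeros(0, dtype=np.int64)
    for ci, (name, length) in enumerate(zip(layout.names, layout.lengths)):
        n_win = -(-length // window)
        pos = five[tags.chrom == ci]
        if pos.size == 0:
            continue
        counts = np.bincount(pos // window, minlength=n_win)
        nz = np.flatnonzero(counts)
        for w in nz:
            rows.append((name, int(w * window), int(min((w + 1) * window, length)), int(counts[w])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def write_track(
    tags: TagCollection, layout: GenomeLayout, path: str | Path, window: int = 200
) -> pd.DataFrame:
    track = make_track(tags, layout, window)
    track.to_csv(path, sep="\t", header=False, index=False)
    return track


def read_expression_table(path: str | Path) -> pd.Series:
    """TSV of gene id -> expression value (one row per gene; header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    if isinstance(df.iloc[0, 1], str):  # header row
        df = df.iloc[1:]
    return pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str), name="expression"
    )


def write_expression_table(expr: pd.Series, path: str | Path) -> None:
    expr.rename("expression").rename_axis("gene_id").to_csv(path, sep="\t", header=True)
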