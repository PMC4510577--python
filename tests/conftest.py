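import numpy as np
import pytest

from chromshift import GenomeLayout, TagCollection


@pytest.fixture
def toy_layout():
    return GenomeLayout(("chr1", "chr2"), (10_000, 5_000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tags(layout, chrom, start, strand=None, read_length=36, sample=None, mark=None):
    """Build a TagCollection from plain lists (helper shared across tests)."""
    chrom = np.asarray(chrom, dtype=np.int32)
    start = np.asarray(start, dtype=np.int64)
    if strand is None:
        strand = np.zeros(len(start), dtype=np.int8)
    return TagCollection(
        layout, chrom, start, start + read_length, np.asarray(strand, dtype=np.int8),
        sample=sample, mark=mark,
    )


@pytest.fixture
def tags_factory():
    return make_tags
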