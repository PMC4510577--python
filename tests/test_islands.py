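"""Island calling against independent oracles and its stated invariants."""

import math

import numpy as np
import pytest

from chromshift import (
    GenomeLayout,
    Island,
    IslandCallingParams,
    WindowVector,
    call_islands,
    count_windows,
    eligibility_threshold,
    genome_fraction_covered,
    score_significance,
)
from chromshift.islands import read_islands, write_islands

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def poisson_tail_brute(l0: int, lam: float, kmax: int = 400) -> float:
    """P(X >= l0) by direct term-by-term summation of the Poisson pmf."""
    total = 0.0
    for k in range(l0):
        total += math.exp(-lam) * lam**k / math.factorial(k)
    return 1.0 - total


def eligibility_brute(lam: float, p0: float) -> int:
    l0 = 1
    while poisson_tail_brute(l0, lam) >= p0:
        l0 += 1
    return l0


def islands_by_union_find(counts, w, gap_w, l0, lam, chrom, chrom_len):
    """Exhaustive reference: union eligible windows within gap_w + 1 of each
    other (all pairs), then report each component as one island."""
    eligible = [i for i, c in enumerate(counts) if c >= l0]
    parent = {i: i for i in eligible}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in eligible:
        for j in eligible:
            if i < j and j - i <= gap_w + 1:
                parent[find(j)] = find(i)
    groups = {}
    for i in eligible:
        groups.setdefault(find(i), []).append(i)
    islands = []
    for members in sorted(groups.values()):
        first, last = min(members), max(members)
        total = int(sum(counts[first:last + 1]))
        score = -sum(
            math.log(math.exp(-lam) * lam**counts[k] / math.factorial(int(counts[k])))
            for k in members
        )
        islands.append(
            Island(chrom, first * w, min((last + 1) * w, chrom_len), total, score)
        )
    return islands


def params_for_lambda(lam: float, n_windows: int, w: int = 200, **kw) -> tuple:
    """Layout and tag count realizing a given per-window background rate."""
    p = IslandCallingParams(window_size=w, effective_genome_fraction=1.0, **kw)
    layout = GenomeLayout(("chr1",), (n_windows * w,))
    n_tags = int(round(lam * n_windows))
    return p, layout, n_tags


# ---------------------------------------------------------------------------
# Window counting
# ---------------------------------------------------------------------------

class TestCountWindows:
    def test_zero_tags_all_zero(self, toy_layout, tags_factory):
        t = tags_factory(toy_layout, [], [])
        wv = count_windows(t, toy_layout, IslandCallingParams())
        assert wv.total == 0

    def test_anchor_assigns_single_window(self, toy_layout, tags_factory):
        # + read with 5' at 377: anchor 377 + 73 = 450 -> window [400, 600)
        t = tags_factory(toy_layout, [0], [377])
        wv = count_windows(t, toy_layout, IslandCallingParams())
        assert wv.counts[0][2] == 1 and wv.total == 1

    def test_conservation_random_tags(self, toy_layout, rng, tags_factory):
        n = 10_000
        chrom = rng.integers(0, 2, n)
        start = np.minimum(
            rng.integers(0, 9000, n), np.where(chrom == 1, 4000, 9000)
        )
        t = tags_factory(toy_layout, chrom, start, strand=rng.integers(0, 2, n))
        wv = count_windows(t, toy_layout, IslandCallingParams())
        assert wv.total == n


# ---------------------------------------------------------------------------
# Eligibility threshold
# ---------------------------------------------------------------------------

class TestEligibility:
    def test_small_lambda_example(self):
        # P(X>=1; 0.1) = 1 - exp(-0.1) ~ 0.0952 < 0.2 -> l0 = 1
        p, layout, n_tags = params_for_lambda(0.1, 1000, eligibility_p0=0.2)
        assert eligibility_threshold(n_tags, layout.total_length, p) == 1

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("p0", [0.3, 0.2, 0.05, 0.01])
    def test_matches_brute_force_tail_summation(self, lam, p0):
        p, layout, n_tags = params_for_lambda(lam, 10_000, eligibility_p0=p0)
        lam_actual = n_tags * p.window_size / layout.total_length
        assert eligibility_threshold(n_tags, layout.total_length, p) == eligibility_brute(
            lam_actual, p0
        )

    def test_permissive_p0_limit(self):
        p, layout, n_tags = params_for_lambda(2.0, 1000, eligibility_p0=0.999999)
        assert eligibility_threshold(n_tags, layout.total_length, p) == 1

    def test_decreasing_p0_never_decreases_l0(self):
        prev = 0
        for p0 in (0.5, 0.2, 0.05, 0.01, 0.001):
            p, layout, n_tags = params_for_lambda(2.0, 1000, eligibility_p0=p0)
            l0 = eligibility_threshold(n_tags, layout.total_length, p)
            assert l0 >= prev
            prev = l0


# ---------------------------------------------------------------------------
# Island assembly
# ---------------------------------------------------------------------------

def _call(counts, gap_size, w=200, p0=0.2):
    n = len(counts)
    p, layout, _ = params_for_lambda(1.0, n, w=w, eligibility_p0=p0)
    p = IslandCallingParams(window_size=w, gap_size=gap_size,
                            eligibility_p0=p0, effective_genome_fraction=1.0)
    wv = WindowVector(layout, w, [np.asarray(counts, dtype=np.int64)])
    n_tags = max(int(sum(counts)), 1)
    return call_islands(wv, p, n_tags), layout, n_tags


class TestCallIslands:
    def test_all_zero_vector(self):
        islands, _, _ = _call([0] * 50, gap_size=200)
        assert islands == []

    def test_single_eligible_window(self):
        counts = [0] * 50
        counts[10] = 30
        islands, _, _ = _call(counts, gap_size=0)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (2000, 2200)

    def test_gap_separation_splits_and_bridges(self):
        # two eligible runs; separated by gap_w + 1 ineligible windows -> two
        # islands; separated by <= gap_w -> one island
        counts = [0] * 50
        for i in (10, 11):
            counts[i] = 40
        for i in (14, 15):
            counts[i] = 40
        two, _, _ = _call(counts, gap_size=200)  # gap of 2 windows > 1
        assert len(two) == 2
        one, _, _ = _call(counts, gap_size=600)  # 3-window bridge >= 2
        assert len(one) == 1
        assert (one[0].start, one[0].end) == (2000, 3200)
        # gap windows contribute reads to the island count
        assert one[0].read_count == 160

    def test_increasing_gap_never_increases_island_count(self, rng):
        for _ in range(20):
            counts = rng.poisson(1.0, size=80)
            counts[rng.integers(0, 80, size=8)] += 8
            prev = None
            for g in (0, 200, 400, 600, 1200):
                islands, _, _ = _call(counts.tolist(), gap_size=g)
                if prev is not None:
                    assert len(islands) <= prev
                prev = len(islands)

    def test_deterministic(self, rng):
        counts = rng.poisson(2.0, size=100).tolist()
        a, _, _ = _call(counts, gap_size=400)
        b, _, _ = _call(counts, gap_size=400)
        assert a == b

    def test_matches_union_find_reference(self, rng):
        """Exhaustive cross-check on random vectors (different algorithm)."""
        w = 200
        for trial in range(60):
            n = int(rng.integers(5, 101))
            counts = rng.poisson(1.5, size=n)
            counts[rng.integers(0, n, size=max(1, n // 8))] += 10
            gap = int(rng.choice([0, w, 3 * w]))
            islands, layout, n_tags = _call(counts.tolist(), gap_size=gap)
            lam = n_tags * w / layout.total_length
            l0 = eligibility_brute(lam, 0.2)
            ref = islands_by_union_find(
                counts.tolist(), w, gap // w, l0, lam, "chr1", layout.total_length
            )
            assert [(i.start, i.end, i.read_count) for i in islands] == [
                (i.start, i.end, i.read_count) for i in ref
            ]
            np.testing.assert_allclose(
                [i.score for i in islands], [i.score for i in ref], rtol=1e-9
            )


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

class TestSignificance:
    def test_count_at_expectation_not_significant(self):
        # lambda = 2 per window, island of 10 windows with count 20 = expectation
        p, layout, n_tags = params_for_lambda(2.0, 1000)
        isl = Island("chr1", 0, 2000, read_count=20, score=1.0)
        keep_all = IslandCallingParams(effective_genome_fraction=1.0, fdr_threshold=1.0)
        out = score_significance([isl], keep_all, n_tags, layout)
        assert 0.4 < out[0].p_value < 0.6  # brute tail: P(X>=20; 20) ~ 0.53
        assert abs(out[0].p_value - poisson_tail_brute(20, 20.0)) < 1e-9
        strict = IslandCallingParams(effective_genome_fraction=1.0, fdr_threshold=0.01)
        assert score_significance([isl], strict, n_tags, layout) == []

    def test_strong_island_highly_significant(self):
        p, layout, n_tags = params_for_lambda(2.0, 1000)
        isl = Island("chr1", 0, 200, read_count=20, score=1.0)  # 10x expectation 2
        params = IslandCallingParams(effective_genome_fraction=1.0)
        out = score_significance([isl], params, n_tags, layout)
        assert out and out[0].p_value < 1e-9
        assert abs(out[0].p_value - poisson_tail_brute(20, 2.0)) < 1e-12

    def test_empty_input(self, toy_layout):
        assert score_significance([], IslandCallingParams(), 100, toy_layout) == []


class TestGenomeFraction:
    def test_no_islands(self, toy_layout):
        assert genome_fraction_covered([], toy_layout) == 0.0

    def test_full_coverage(self):
        layout = GenomeLayout(("c",), (1000,))
        assert genome_fraction_covered([Island("c", 0, 1000, 1, 0.0)], layout) == 1.0

    def test_ten_kilobases_on_megabase(self):
        layout = GenomeLayout(("c",), (1_000_000,))
        islands = [Island("c", i * 10_000, i * 10_000 + 1000, 1, 0.0) for i in range(10)]
        assert genome_fraction_covered(islands, layout) == pytest.approx(0.01)

    def test_overlap_rejected(self):
        layout = GenomeLayout(("c",), (10_000,))
        islands = [Island("c", 0, 500, 1, 0.0), Island("c", 400, 900, 1, 0.0)]
        with pytest.raises(ValueError, match="overlapping"):
            genome_fraction_covered(islands, layout)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=30), min_size=3, max_size=60),
        gap_w=st.integers(min_value=0, max_value=3),
    )
    def test_island_spans_cover_all_eligible_windows(counts, gap_w):
        """Property: every eligible window lies inside exactly one island, and
        islands begin/end on eligible windows separated by > gap outside."""
        if sum(counts) == 0:
            return
        islands, layout, n_tags = _call(counts, gap_size=gap_w * 200)
        lam = n_tags * 200 / layout.total_length
        l0 = eligibility_brute(lam, 0.2)
        eligible = [i for i, c in enumerate(counts) if c >= l0]
        covered = []
        for isl in islands:
            first, last = isl.start // 200, (isl.end - 1) // 200
            assert first in eligible and last in eligible
            covered.extend(i for i in eligible if first <= i <= last)
        assert sorted(covered) == eligible
except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_island_bed_round_trip(tmp_path):
    islands = [
        Island("chr1", 200, 1400, 57, 33.5, 1.2e-10, 4.5e-9),
        Island("chr2", 0, 600, 12, 8.25, 0.002, 0.0099),
    ]
    p = tmp_path / "islands.bed"
    write_islands(islands, p)
    back = read_islands(p)
    assert [(i.chrom, i.start, i.end, i.read_count) for i in back] == [
        (i.chrom, i.start, i.end, i.read_count) for i in islands
    ]
    np.testing.assert_allclose([i.p_value for i in back], [i.p_value for i in islands])
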