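"""Interval algebra: merging, overlap, TSS distances, context, shuffling."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from chromdyn.errors import InvalidParameterError, PlacementError, ValidationError
from chromdyn.genome import GeneModel, Genome
from chromdyn.intervals import (
    GenomicInterval,
    IntervalSet,
    annotate_genomic_context,
    distance_to_nearest_tss,
    merge_intervals,
    overlaps_any,
    partition_by_tss_distance,
    shuffle_intervals,
)


def iv(chrom, s, e):
    return GenomicInterval(chrom, s, e)


def test_interval_validation_rejects_empty_and_negative():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", -1, 5)


@pytest.mark.parametrize(
    "intervals, gap, expected",
    [
        ([(0, 10), (5, 20)], 0, [(0, 20)]),
        ([(0, 10), (15, 20)], 5, [(0, 20)]),
        ([(0, 10), (16, 20)], 5, [(0, 10), (16, 20)]),
        ([(0, 10), (10, 20)], 0, [(0, 20)]),
    ],
)
def test_merge_examples(intervals, gap, expected):
    s = IntervalSet([iv("chr1", a, b) for a, b in intervals])
    out = merge_intervals(s, gap)
    assert [(v.start, v.end) for v in out] == expected


def test_merge_empty_and_negative_gap():
    assert len(merge_intervals(IntervalSet([]), 0)) == 0
    with pytest.raises(InvalidParameterError):
        merge_intervals(IntervalSet([]), -1)


@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 300)), min_size=1, max_size=40
    ),
    st.integers(0, 50),
)
def test_merge_idempotent_and_separated(pairs, gap):
    s = IntervalSet([iv("chr1", a, a + w) for a, w in pairs])
    once = merge_intervals(s, gap)
    twice = merge_intervals(once, gap)
    assert [(v.start, v.end) for v in once] == [(v.start, v.end) for v in twice]
    for a, b in zip(once, list(once)[1:]):
        assert b.start - a.end > gap
    # coverage union preserved
    cover = set()
    for a, w in pairs:
        cover.update(range(a, a + w))
    merged_cover = set()
    for v in once:
        merged_cover.update(range(v.start, v.end))
    assert cover <= merged_cover


def test_overlaps_any_trivial_cases(rng):
    ref = IntervalSet([iv("chr1", 100, 200), iv("chr1", 500, 600)])
    flags, frac = overlaps_any(ref, ref)
    assert frac == 1.0
    disjoint = IntervalSet([iv("chr1", 300, 400), iv("chr2", 100, 200)])
    _, frac0 = overlaps_any(disjoint, ref)
    assert frac0 == 0.0


def test_overlaps_any_one_bp_touch_counts():
    ref = IntervalSet([iv("chr1", 100, 200)])
    q = IntervalSet(
        [
            iv("chr1", 199, 250),  # 1 bp overlap
            iv("chr1", 200, 250),  # adjacent, no overlap (half-open)
            iv("chr1", 50, 101),  # 1 bp overlap
            iv("chr1", 0, 40),
        ]
    )
    flags, frac = overlaps_any(q, ref)
    assert list(flags) == [True, False, True, False]
    assert frac == 0.5


def test_overlaps_any_matches_bruteforce_and_is_symmetric(rng):
    def rand_set(n):
        starts = rng.integers(0, 10_000, n)
        lens = rng.integers(1, 500, n)
        return IntervalSet([iv("chr1", int(s), int(s + l)) for s, l in zip(starts, lens)])

    q, r = rand_set(50), rand_set(40)
    flags, _ = overlaps_any(q, r)
    brute = [any(a.overlaps(b) for b in r) for a in q]
    assert list(flags) == brute
    # symmetry of the pairwise predicate
    for a in q:
        for b in r:
            assert a.overlaps(b) == b.overlaps(a)


def _gene(gid, chrom, tss, strand="+"):
    exons = [(tss, tss + 100)] if strand == "+" else [(tss - 100, tss)]
    return GeneModel(gid, chrom, strand, tss, exons)


def test_distance_examples():
    genes = [_gene("g1", "chr1", 3600)]
    d, gid = distance_to_nearest_tss(IntervalSet([iv("chr1", 1000, 1100)]), genes)[0]
    assert (d, gid) == (2500, "g1")
    d0, _ = distance_to_nearest_tss(IntervalSet([iv("chr1", 3500, 3700)]), genes)[0]
    assert d0 == 0
    with pytest.raises(InvalidParameterError):
        distance_to_nearest_tss(IntervalSet([iv("chr1", 0, 10)]), [])


def test_distance_tie_breaks_to_smaller_gene_id():
    genes = [_gene("gB", "chr1", 900), _gene("gA", "chr1", 1600)]
    # interval [1000,1500): gB gap = 100, gA gap = 100 -> tie -> gA
    d, gid = distance_to_nearest_tss(IntervalSet([iv("chr1", 1000, 1500)]), genes)[0]
    assert d == 100 and gid == "gA"


def test_distance_matches_bruteforce(rng):
    genes = [_gene(f"g{i:02d}", "chr1", int(t)) for i, t in
             enumerate(sorted(rng.integers(200, 99_000, 30)))]
    ivs = IntervalSet(
        [iv("chr1", int(s), int(s) + int(w)) for s, w in
         zip(rng.integers(0, 99_000, 50), rng.integers(1, 800, 50))]
    )
    got = distance_to_nearest_tss(ivs, genes)
    for interval, (d, gid) in zip(ivs, got):
        def edge_dist(t):
            if t < interval.start:
                return interval.start - t
            if t >= interval.end:
                return t - interval.end
            return 0
        dmin = min(edge_dist(g.tss) for g in genes)
        winners = sorted(g.gene_id for g in genes if edge_dist(g.tss) == dmin)
        assert d == dmin and gid == winners[0]


def test_partition_boundary_and_law(rng):
    genes = [_gene("g1", "chr1", 10_000)]
    ivs = IntervalSet(
        [
            iv("chr1", 6400, 7500),  # distance 2500 -> proximal
            iv("chr1", 6399, 7499),  # distance 2501 -> distal
            iv("chr1", 9000, 11_000),  # contains TSS
        ]
    )
    prox, dist = partition_by_tss_distance(ivs, genes, cutoff=2500)
    assert len(prox) == 2 and len(dist) == 1
    assert len(prox) + len(dist) == len(ivs)
    prox_set = {v.as_tuple() for v in prox}
    dist_set = {v.as_tuple() for v in dist}
    assert prox_set.isdisjoint(dist_set)


def test_annotate_context_precedence_and_counts(rng):
    g = GeneModel(
        "g1", "chr1", "+", 50_000,
        exons=[(50_000, 50_500), (52_000, 52_500), (60_000, 61_000)],
    )
    ivs = IntervalSet(
        [
            iv("chr1", 49_900, 50_100),  # midpoint at promoter (and exon)
            iv("chr1", 59_990, 60_100),  # exon midpoint, > 2.5 kb from TSS
            iv("chr1", 55_000, 55_100),  # intron
            iv("chr1", 80_000, 80_100),  # intergenic
        ]
    )
    labels, counts = annotate_genomic_context(ivs, [g])
    assert labels == ["promoter", "exon", "intron", "intergenic"]
    assert sum(counts.values()) == len(ivs)

    # random fixture vs brute force
    starts = rng.integers(0, 90_000, 100)
    fixture = IntervalSet([iv("chr1", int(s), int(s) + 150 + int(s) % 70) for s in starts])
    labels, _ = annotate_genomic_context(fixture, [g])
    for interval, lab in zip(fixture, labels):
        mid = interval.midpoint
        if abs(mid - g.tss) <= 2500:
            want = "promoter"
        elif any(s <= mid < e for s, e in g.exons):
            want = "exon"
        elif g.span[0] <= mid < g.span[1]:
            want = "intron"
        else:
            want = "intergenic"
        assert lab == want


class TestShuffle:
    genome = Genome(("chr1", "chr2"), (100_000, 50_000))

    def test_preserves_chrom_and_length_multiset(self, rng):
        ivs = IntervalSet(
            [iv("chr1", 0, 500), iv("chr1", 700, 1800), iv("chr2", 10, 400)]
        )
        out = shuffle_intervals(ivs, self.genome, seed=5)
        assert [v.chrom for v in out] == [v.chrom for v in ivs]
        assert sorted(len(v) for v in out) == sorted(len(v) for v in ivs)
        for v in out:
            assert 0 <= v.start < v.end <= self.genome.size_of(v.chrom)

    def test_deterministic_given_seed(self):
        ivs = IntervalSet([iv("chr1", 0, 500)])
        a = shuffle_intervals(ivs, self.genome, seed=7)
        b = shuffle_intervals(ivs, self.genome, seed=7)
        assert [v.as_tuple() for v in a] == [v.as_tuple() for v in b]

    def test_forced_placement_single_slot(self):
        genome = Genome(("chr1",), (1000,))
        excluded = IntervalSet([iv("chr1", 0, 400), iv("chr1", 500, 1000)])
        out = shuffle_intervals(
            IntervalSet([iv("chr1", 0, 100)]), genome, excluded, seed=0
        )
        assert out[0].as_tuple() == ("chr1", 400, 500)

    def test_infeasible_placement_raises(self):
        genome = Genome(("chr1",), (1000,))
        excluded = IntervalSet([iv("chr1", 0, 1000)])
        with pytest.raises(PlacementError):
            shuffle_intervals(
                IntervalSet([iv("chr1", 0, 100)]), genome, excluded, seed=0
            )

    def test_start_uniform_without_exclusions(self):
        genome = Genome(("chr1",), (10_000,))
        ivs = IntervalSet([iv("chr1", 0, 1000)])
        rng = np.random.default_rng(42)
        starts = [
            shuffle_intervals(ivs, genome, seed=rng)[0].start for _ in range(3000)
        ]
        # start ~ Uniform{0..9000}
        ks = stats.kstest(np.array(starts) / 9000.0, "uniform")
        assert ks.pvalue > 0.01


def test_bed_roundtrip(tmp_path):
    s = IntervalSet(
        [
            GenomicInterval("chr1", 0, 10, name="a", score=1.5, strand="+"),
            GenomicInterval("chr2", 5, 9),
        ]
    )
    path = tmp_path / "x.bed"
    s.to_bed(path)
    back = IntervalSet.from_bed(path)
    assert [v.as_tuple() for v in back] == [v.as_tuple() for v in s]
    assert back[0].name == "a" and back[0].strand == "+"


def test_bed_reader_reports_line_numbers(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t0\t10\nchr1\tfoo\t20\n")
    with pytest.raises(ValidationError, match="bad.bed:2"):
        IntervalSet.from_bed(path)


def test_overlap_fraction_matches_pyranges_oracle(rng):
    pyranges = pytest.importorskip("pyranges")
    import pandas as pd

    starts_q = rng.integers(0, 50_000, 60)
    starts_r = rng.integers(0, 50_000, 40)
    q = IntervalSet([iv("chr1", int(s), int(s) + 300 + int(s) % 101) for s in starts_q])
    r = IntervalSet([iv("chr1", int(s), int(s) + 200 + int(s) % 89) for s in starts_r])
    flags, frac = overlaps_any(q, r)
    pq = pyranges.PyRanges(
        pd.DataFrame(
            {"Chromosome": "chr1", "Start": [v.start for v in q], "End": [v.end for v in q]}
        )
    )
    pr = pyranges.PyRanges(
        pd.DataFrame(
            {"Chromosome": "chr1", "Start": [v.start for v in r], "End": [v.end for v in r]}
        )
    )
    hits = pq.overlap(pr)
    expected = {(int(s), int(e)) for s, e in zip(hits.df["Start"], hits.df["End"])}
    got = {(v.start, v.end) for v, f in zip(q, flags) if f}
    assert got == expected
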